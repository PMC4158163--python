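"""Symmetric bifurcating airway-tree geometry.

The tree spans 25 conduits: the endotracheal tube (ETT) at generation -1,
the trachea at generation 0, and bronchial generations 1 through 23. Each
generation n >= 1 contains 2**n identical parallel branches. Generations
listed singly in the reference morphometry carry their tabulated diameter
and length; range-specified spans (5-16 and 17-22) are filled by geometric
interpolation between the tabulated endpoints, reflecting the
multiplicative taper of airway morphometry.

A patient-specific dimensionless multiplier ``alpha`` uniformly rescales
every diameter (lengths are untouched); ``alpha = 1`` is the general,
population-average tree.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

GEN_MIN = -1
GEN_MAX = 23
N_GENERATIONS = GEN_MAX - GEN_MIN + 1

ALPHA_MIN = 0.45
ALPHA_MAX = 1.50

_GEOMETRY_RESOURCE = "airway_geometry.csv"


@dataclass(frozen=True)
class AirwayGeneration:
    """One generation of the airway tree.

    Attributes
    ----------
    n : int
        Generation index; -1 is the ETT, 0 the trachea, 23 the deepest
        bronchial generation.
    diameter : float
        Branch diameter in mm.
    length : float
        Branch length in mm.
    """

    n: int
    diameter: float
    length: float

    def __post_init__(self) -> None:
        if not GEN_MIN <= self.n <= GEN_MAX:
            raise ValueError(f"generation index {self.n} outside [{GEN_MIN}, {GEN_MAX}]")
        if not self.diameter > 0:
            raise ValueError(f"diameter must be positive, got {self.diameter}")
        if not self.length > 0:
            raise ValueError(f"length must be positive, got {self.length}")


@dataclass(frozen=True)
class AirwayTree:
    """Ordered airway generations from the ETT (n = -1) to generation 23."""

    generations: tuple[AirwayGeneration, ...]
    alpha: float = 1.0

    def __post_init__(self) -> None:
        if len(self.generations) != N_GENERATIONS:
            raise ValueError(
                f"tree must have {N_GENERATIONS} generations, got {len(self.generations)}"
            )
        for i, g in enumerate(self.generations):
            if g.n != GEN_MIN + i:
                raise ValueError("generation indices must run consecutively from -1 to 23")
        # bronchial taper: the ETT (a clinical tube) is exempt
        d = [g.diameter for g in self.generations[1:]]
        if any(b > a + 1e-12 for a, b in zip(d, d[1:])):
            raise ValueError("diameters must be non-increasing from the trachea inward")
        if not ALPHA_MIN <= self.alpha <= ALPHA_MAX:
            raise ValueError(
                f"alpha {self.alpha} outside [{ALPHA_MIN}, {ALPHA_MAX}]"
            )

    def __len__(self) -> int:
        return N_GENERATIONS

    def __getitem__(self, n: int) -> AirwayGeneration:
        """Generation by anatomical index n (-1..23), not list position."""
        if not GEN_MIN <= n <= GEN_MAX:
            raise IndexError(f"generation index {n} outside [{GEN_MIN}, {GEN_MAX}]")
        return self.generations[n - GEN_MIN]

    @property
    def indices(self) -> np.ndarray:
        return np.array([g.n for g in self.generations])

    @property
    def diameters_mm(self) -> np.ndarray:
        return np.array([g.diameter for g in self.generations])

    @property
    def lengths_mm(self) -> np.ndarray:
        return np.array([g.length for g in self.generations])


def interpolate_span(start_value: float, end_value: float, count: int) -> list[float]:
    """Fill a range-specified span with a geometric progression.

    Returns ``count`` values running from ``start_value`` to ``end_value``
    inclusive, log-linearly spaced, so consecutive ratios are constant.

    >>> interpolate_span(3.50, 0.60, 12)[0]
    3.5
    """
    if count < 2:
        raise ValueError(f"count must be >= 2, got {count}")
    if not (start_value > 0 and end_value > 0):
        raise ValueError("span endpoints must be strictly positive")
    return list(np.geomspace(start_value, end_value, count))


# Printed reference morphometry: singly listed generations and span endpoints.
# (generation or (first, last), diameter or (d_first, d_last) mm, length mm)
_TABLE_ROWS: tuple = (
    (-1, 9.0, 330.0),          # ETT
    (0, 18.0, 120.0),          # trachea
    (1, 12.20, 48.0),
    (2, 8.30, 19.0),
    (3, 5.60, 8.0),
    (4, 4.50, 13.0),
    ((5, 16), (3.50, 0.60), (10.70, 1.70)),
    ((17, 22), (0.57, 0.43), (1.50, 0.63)),
    (23, 0.40, 0.50),
)


def _expand_rows(rows: Iterable) -> list[AirwayGeneration]:
    gens: list[AirwayGeneration] = []
    for n, d, length in rows:
        if isinstance(n, tuple):
            first, last = n
            count = last - first + 1
            ds = interpolate_span(d[0], d[1], count)
            ls = interpolate_span(length[0], length[1], count)
            gens.extend(
                AirwayGeneration(first + i, ds[i], ls[i]) for i in range(count)
            )
        else:
            gens.append(AirwayGeneration(int(n), float(d), float(length)))
    return gens


def build_default_tree() -> AirwayTree:
    """Construct the general (alpha = 1) 25-generation airway tree.

    Dimensions are held constant within a breath; the ETT is a 9 mm x
    330 mm tube, the trachea 18 mm x 120 mm, and the bronchial span
    tapers down to 0.40 mm x 0.50 mm at generation 23.
    """
    return AirwayTree(tuple(_expand_rows(_TABLE_ROWS)), alpha=1.0)


def scale_tree(tree: AirwayTree, alpha: float) -> AirwayTree:
    """Uniformly rescale every diameter (ETT included) by ``alpha``.

    Lengths are unchanged and scalings compose: the result's ``alpha``
    field is ``tree.alpha * alpha``, so scaling by ``alpha`` then
    ``1/alpha`` (both within bounds) recovers the original tree. Because
    each per-generation pressure drop carries D**-4, the whole-tree drop
    scales exactly as alpha**-4.
    """
    if not ALPHA_MIN <= alpha <= ALPHA_MAX:
        raise ValueError(f"alpha {alpha} outside [{ALPHA_MIN}, {ALPHA_MAX}]")
    gens = tuple(
        AirwayGeneration(g.n, g.diameter * alpha, g.length)
        for g in tree.generations
    )
    return AirwayTree(gens, alpha=tree.alpha * alpha)


def unscaled(tree: AirwayTree) -> AirwayTree:
    """The alpha = 1 reference geometry underlying a (possibly scaled) tree."""
    if tree.alpha == 1.0:
        return tree
    gens = tuple(
        AirwayGeneration(g.n, g.diameter / tree.alpha, g.length)
        for g in tree.generations
    )
    return AirwayTree(gens, alpha=1.0)


def per_branch_flow(q_total: float, n: int) -> float:
    """Flow carried by one branch of generation ``n`` given inlet flow.

    The ETT (n = -1) and trachea (n = 0) are single conduits carrying the
    full inlet flow; each bifurcation halves the per-branch flow, so
    generation n >= 1 carries ``q_total / 2**n`` per branch. Sign (i.e.
    breath phase) is preserved. Units follow the input.
    """
    if not GEN_MIN <= n <= GEN_MAX:
        raise ValueError(f"generation index {n} outside [{GEN_MIN}, {GEN_MAX}]")
    if n <= 0:
        return q_total
    return q_total / 2.0**n


def branch_flow_divisors(indices: Sequence[int] | np.ndarray) -> np.ndarray:
    """Vector of 2**max(n, 0) for generation indices (flow-split factors)."""
    n = np.asarray(indices)
    return 2.0 ** np.maximum(n, 0)


def save_geometry_csv(tree: AirwayTree, path: str | Path) -> None:
    """Write the expanded per-generation table (generation, diameter_mm, length_mm)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["generation", "diameter_mm", "length_mm"])
        for g in tree.generations:
            w.writerow([g.n, f"{g.diameter:.9g}", f"{g.length:.9g}"])


def _parse_geometry_text(text: str) -> AirwayTree:
    reader = csv.DictReader(io.StringIO(text))
    required = {"generation", "diameter_mm", "length_mm"}
    if reader.fieldnames is None or not required <= set(reader.fieldnames):
        missing = sorted(required - set(reader.fieldnames or []))
        raise ValueError(f"geometry table missing column(s): {', '.join(missing)}")

    def parse_field(s: str) -> float | tuple[float, float]:
        s = s.strip()
        # a '-' past the first character separates span endpoints
        cut = s.find("-", 1)
        if cut > 0:
            return float(s[:cut]), float(s[cut + 1 :])
        return float(s)

    rows = []
    for rec in reader:
        n = parse_field(rec["generation"])
        if isinstance(n, tuple):
            n = (int(n[0]), int(n[1]))
        else:
            n = int(n)
        rows.append((n, parse_field(rec["diameter_mm"]), parse_field(rec["length_mm"])))
    return AirwayTree(tuple(_expand_rows(rows)), alpha=1.0)


def load_geometry_csv(path: str | Path) -> AirwayTree:
    """Load a geometry table; span rows like ``5-16, 3.50-0.60, ...`` are expanded."""
    return _parse_geometry_text(Path(path).read_text())


def load_packaged_geometry() -> AirwayTree:
    """The packaged reference morphometry (identical to build_default_tree)."""
    text = resources.files("abmps.data").joinpath(_GEOMETRY_RESOURCE).read_text()
    return _parse_geometry_text(text)
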