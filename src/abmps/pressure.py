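"""Per-generation airway pressure drops: Poiseuille resistance and minor loss.

For each generation the model evaluates two laminar-flow terms at the
per-branch flow Q_n:

* Poiseuille (major head-loss) drop, 128 mu L Q_n / (pi D^4) — identical to
  substituting the laminar friction factor f = 64/Re into the Darcy-Weisbach
  major-loss expression;
* minor (bifurcation) head loss, (8 K_L rho / pi^2) Q_n |Q_n| / D^4, signed
  so the loss always opposes the flow direction.

Parallel branches of one generation are pressure-equivalent, so the drop
across a generation is the drop along a single branch; the total drop down
the tree is the sum over generations -1 (ETT) through 23. Because every
summand carries D^-4, scaling all diameters by alpha divides the total by
alpha^4 exactly.

Inputs are in clinical units (mm, L/s); outputs in cmH2O. Internally
everything is converted to SI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import (
    DEFAULT_CONSTANTS,
    PA_PER_CMH2O,
    RE_LAMINAR_LIMIT,
    ModelConstants,
)
from .geometry import AirwayGeneration, AirwayTree, branch_flow_divisors

__all__ = [
    "GenerationFlowState",
    "PressureDropProfile",
    "poiseuille_drop",
    "minor_loss_drop",
    "total_drop",
    "drop_waveform",
    "generation_resistance",
    "reynolds_profile",
    "lumped_coefficients",
]


@dataclass(frozen=True)
class GenerationFlowState:
    """Kinematic state of one branch at a given inlet flow."""

    n: int
    q_branch: float  # m^3/s, signed
    velocity: float  # m/s, mean, signed
    reynolds: float  # dimensionless, >= 0
    friction_factor: float  # laminar 64/Re; inf at zero flow
    laminar: bool  # Re < 2000


@dataclass(frozen=True)
class PressureDropProfile:
    """Per-generation and total pressure drop for one inlet flow (cmH2O)."""

    generations: np.ndarray  # generation indices, -1..23
    poiseuille: np.ndarray  # cmH2O per generation
    minor: np.ndarray  # cmH2O per generation
    alpha: float

    @property
    def per_generation(self) -> np.ndarray:
        return self.poiseuille + self.minor

    @property
    def total(self) -> float:
        return float(np.sum(self.poiseuille) + np.sum(self.minor))


def _check_geometry(diameter_mm: float) -> None:
    if diameter_mm <= 0:
        raise ValueError(f"branch diameter must be positive, got {diameter_mm} mm")


def poiseuille_drop(
    generation: AirwayGeneration,
    q_branch: float,
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> float:
    """Poiseuille pressure drop along one branch, cmH2O.

    ``q_branch`` is the per-branch flow in L/s (signed). Antisymmetric in
    the flow: reversing the flow reverses the drop.
    """
    _check_geometry(generation.diameter)
    d = generation.diameter * 1e-3
    length = generation.length * 1e-3
    q = q_branch * 1e-3
    dp_pa = 128.0 * constants.mu * length * q / (np.pi * d**4)
    return dp_pa / PA_PER_CMH2O


def minor_loss_drop(
    generation: AirwayGeneration,
    q_branch: float,
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> float:
    """Minor (bifurcation) head loss for one branch, cmH2O.

    Quadratic in flow; implemented as Q|Q| so the loss opposes the flow
    direction (negative during expiration).
    """
    _check_geometry(generation.diameter)
    d = generation.diameter * 1e-3
    q = q_branch * 1e-3
    dp_pa = (8.0 * constants.k_l * constants.rho / np.pi**2) * q * abs(q) / d**4
    return dp_pa / PA_PER_CMH2O


def _si_arrays(tree: AirwayTree) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    d = tree.diameters_mm * 1e-3
    length = tree.lengths_mm * 1e-3
    split = branch_flow_divisors(tree.indices)
    return d, length, split


def lumped_coefficients(
    tree: AirwayTree, constants: ModelConstants = DEFAULT_CONSTANTS
) -> tuple[float, float]:
    """Whole-tree lumped coefficients (a, b) with drop = a*Q + b*Q|Q|.

    ``a`` is the linear Poiseuille resistance in cmH2O/(L/s); ``b`` the
    quadratic minor-loss coefficient in cmH2O/(L/s)^2. Useful for closed-form
    work with the single-compartment lung (e.g. passive expiration).
    """
    d, length, split = _si_arrays(tree)
    a_pa = np.sum(128.0 * constants.mu * length / (np.pi * d**4 * split))
    b_pa = np.sum(8.0 * constants.k_l * constants.rho / (np.pi**2 * d**4 * split**2))
    a = a_pa * 1e-3 / PA_PER_CMH2O  # per (L/s)
    b = b_pa * 1e-6 / PA_PER_CMH2O  # per (L/s)^2
    return float(a), float(b)


def total_drop(
    tree: AirwayTree,
    q_total: float,
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> PressureDropProfile:
    """Pressure drop ETT-to-periphery at inlet flow ``q_total`` (L/s)."""
    d, length, split = _si_arrays(tree)
    q = (q_total * 1e-3) / split
    pois = 128.0 * constants.mu * length * q / (np.pi * d**4) / PA_PER_CMH2O
    minor = (
        (8.0 * constants.k_l * constants.rho / np.pi**2) * q * np.abs(q) / d**4
    ) / PA_PER_CMH2O
    return PressureDropProfile(
        generations=tree.indices, poiseuille=pois, minor=minor, alpha=tree.alpha
    )


def drop_waveform(
    tree: AirwayTree,
    flow: np.ndarray,
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> np.ndarray:
    """Total drop (cmH2O) evaluated sample-wise over a flow series (L/s)."""
    q = np.asarray(flow, dtype=float)
    if q.size == 0:
        raise ValueError("flow series is empty")
    if not np.all(np.isfinite(q)):
        raise ValueError("flow series contains non-finite samples")
    a, b = lumped_coefficients(tree, constants)
    return a * q + b * q * np.abs(q)


def generation_resistance(
    tree: AirwayTree,
    q_total: float,
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> np.ndarray:
    """Per-generation resistance dP_n / Q_total in cmH2O*s/L.

    Flow-dependent through the minor-loss term, so it must be quoted at a
    stated inlet flow.
    """
    if q_total == 0:
        raise ZeroDivisionError(
            "resistance is undefined at zero flow; report the Poiseuille-only "
            "(linear) resistance via lumped_coefficients with k_l = 0 instead"
        )
    profile = total_drop(tree, q_total, constants)
    return profile.per_generation / q_total


def reynolds_profile(
    tree: AirwayTree,
    q_total: float,
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> list[GenerationFlowState]:
    """Per-generation velocity, Reynolds number and laminar flag.

    Re = rho V D / mu with V = 4 Q_n / (pi D^2) at the per-branch flow; the
    model assumes laminar flow (Re < 2000) and only flags, never corrects,
    departures from it.
    """
    d, _, split = _si_arrays(tree)
    q = (q_total * 1e-3) / split
    v = 4.0 * q / (np.pi * d**2)
    re = constants.rho * np.abs(v) * d / constants.mu
    out = []
    for n, qi, vi, ri in zip(tree.indices, q, v, re):
        f = 64.0 / ri if ri > 0 else np.inf
        out.append(
            GenerationFlowState(
                n=int(n),
                q_branch=float(qi),
                velocity=float(vi),
                reynolds=float(ri),
                friction_factor=float(f),
                laminar=bool(ri < RE_LAMINAR_LIMIT),
            )
        )
    return out


def profile_table(
    tree: AirwayTree,
    q_total: float,
    constants: ModelConstants = DEFAULT_CONSTANTS,
):
    """Per-generation breakdown as a pandas DataFrame (for export/CLI)."""
    import pandas as pd

    prof = total_drop(tree, q_total, constants)
    states = reynolds_profile(tree, q_total, constants)
    r = (
        prof.per_generation / q_total
        if q_total != 0
        else np.full(len(prof.generations), np.nan)
    )
    return pd.DataFrame(
        {
            "generation": prof.generations,
            "diameter_mm": tree.diameters_mm,
            "length_mm": tree.lengths_mm,
            "q_branch_Lps": [s.q_branch * 1e3 for s in states],
            "reynolds": [s.reynolds for s in states],
            "laminar": [s.laminar for s in states],
            "dp_poiseuille_cmH2O": prof.poiseuille,
            "dp_minor_cmH2O": prof.minor,
            "resistance_cmH2O_s_per_L": r,
        }
    )
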