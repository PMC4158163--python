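"""Patient-specific airway-diameter multiplier: model and fit results.

The patient-specific branching model rescales every airway diameter of the
general tree by a single multiplier alpha in [0.45, 1.50]. Since each
pressure-drop summand carries D^-4, the whole-tree drop at any flow scales
exactly as alpha^-4:

    dP_ps(Q) = dP_general(Q) / alpha**4.

alpha is identified by matching the area under the model's inspiratory
pressure-drop curve (AUC, cmH2O*s) to the AUC of the dynostatic-algorithm
drop, the accepted alveolar-pressure surrogate. Minimising the absolute
percentage error between the two AUCs therefore has the closed form

    alpha = (AUC_general / AUC_DSA) ** (1/4),

clamped to the physiological bounds. A pointwise per-sample alpha series
(fourth root of the drop ratio at each inspiratory sample) is retained as a
diagnostic of how uniform the identified multiplier is across the breath.

`AirwayBranchingModel` holds one breath plus the tree and gas constants;
`fit()` returns an `AlphaFitResults` carrying the estimate, a dispersion-
based uncertainty, the AUCs that justify it, and a `summary()` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .constants import DEFAULT_CONSTANTS, ModelConstants
from .dsa import DEFAULT_N_ISOVOLUMES, Breath, DSAResult, dsa_drop_series, integrate_volume
from .geometry import (
    ALPHA_MAX,
    ALPHA_MIN,
    AirwayTree,
    build_default_tree,
    scale_tree,
    unscaled,
)
from .pressure import drop_waveform

__all__ = [
    "AirwayBranchingModel",
    "AlphaFitResults",
    "auc",
    "alpha_closed_form",
    "alpha_pointwise",
    "ape",
    "fit_alpha",
]

#: Minimum dynostatic drop (cmH2O) for a sample to enter the pointwise series.
DP_DSA_GUARD = 0.05


def auc(series: np.ndarray, time: np.ndarray) -> float:
    """Trapezoidal area under a pressure series over time (cmH2O*s)."""
    series = np.asarray(series, dtype=float)
    time = np.asarray(time, dtype=float)
    if series.shape != time.shape:
        raise ValueError("series and time must have equal length")
    if series.size < 2:
        raise ValueError("AUC needs at least 2 samples")
    if np.any(np.diff(time) <= 0):
        raise ValueError("time must be strictly increasing")
    return float(np.trapezoid(series, time))


def alpha_closed_form(auc_abm1: float, auc_dsa: float) -> float:
    """Diameter multiplier matching the general-tree AUC to the DSA AUC.

    Returns (auc_abm1 / auc_dsa) ** (1/4), clamped to [0.45, 1.50].
    """
    if auc_abm1 <= 0 or auc_dsa <= 0:
        raise ValueError("both AUCs must be strictly positive")
    raw = (auc_abm1 / auc_dsa) ** 0.25
    return float(min(max(raw, ALPHA_MIN), ALPHA_MAX))


def ape(auc_model: float, auc_ref: float) -> float:
    """Absolute percentage error between a model AUC and a reference AUC."""
    if auc_ref == 0:
        raise ValueError("reference AUC must be nonzero")
    return 100.0 * abs(auc_model - auc_ref) / abs(auc_ref)


def alpha_pointwise(
    dp_dsa: np.ndarray,
    tree: AirwayTree,
    flow: np.ndarray,
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> np.ndarray:
    """Per-sample alpha estimate: fourth root of dP_general / dP_DSA.

    Samples with dP_DSA below the guard (where the fourth root amplifies
    noise) are returned as NaN. Raises if every sample is masked.
    """
    dp_dsa = np.asarray(dp_dsa, dtype=float)
    flow = np.asarray(flow, dtype=float)
    if dp_dsa.shape != flow.shape:
        raise ValueError("dp_dsa and flow must have equal length")
    dp_model = drop_waveform(unscaled(tree), flow, constants)
    out = np.full_like(dp_dsa, np.nan)
    ok = (dp_dsa > DP_DSA_GUARD) & (dp_model > 0)
    out[ok] = (dp_model[ok] / dp_dsa[ok]) ** 0.25
    if not np.any(ok):
        raise ValueError("no usable samples: every dynostatic drop is below the guard")
    return out


@dataclass(frozen=True)
class AlphaFitResults:
    """Identified diameter multiplier with its supporting evidence.

    alpha_se is a dispersion-based uncertainty: the scaled median absolute
    deviation of the pointwise alpha series divided by sqrt(n of usable
    samples). It measures how uniformly a single multiplier explains the
    breath, not sampling error of a statistical estimator.
    """

    alpha: float
    alpha_se: float
    auc_abm1: float
    auc_dsa: float
    auc_abmps: float
    ape: float
    clamped: bool
    dsa: DSAResult
    alpha_pointwise: np.ndarray
    model: "AirwayBranchingModel" = field(repr=False)

    @property
    def fitted_tree(self) -> AirwayTree:
        return scale_tree(self.model.tree, self.alpha)

    def drop_series(self) -> np.ndarray:
        """Fitted-model inspiratory pressure drop on the DSA time base."""
        t, _, q, _ = self.model.breath.inspiration()
        return drop_waveform(self.fitted_tree, q, self.model.constants)

    def summary(self) -> str:
        lines = [
            "Patient-specific airway branching model fit",
            "=" * 47,
            f"{'diameter multiplier alpha':<34}{self.alpha:>10.4f}",
            f"{'alpha dispersion (pointwise SE)':<34}{self.alpha_se:>10.4f}",
            f"{'clamped at bound':<34}{str(self.clamped):>10}",
            f"{'AUC general tree (cmH2O*s)':<34}{self.auc_abm1:>10.4f}",
            f"{'AUC dynostatic drop (cmH2O*s)':<34}{self.auc_dsa:>10.4f}",
            f"{'AUC fitted model (cmH2O*s)':<34}{self.auc_abmps:>10.4f}",
            f"{'APE model vs DSA (%)':<34}{self.ape:>10.4f}",
            f"{'isovolume points excluded':<34}{self.dsa.excluded_fraction:>10.2%}",
            "=" * 47,
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Overlay the DSA drop and the fitted/general model drops vs time."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.dsa.time_insp
        q = self.model.breath.inspiration()[2]
        ax.plot(t, self.dsa.dp_dsa, label="dynostatic drop")
        ax.plot(t, self.drop_series(), label=f"fitted tree (alpha={self.alpha:.2f})")
        ax.plot(
            t,
            drop_waveform(self.model.tree, q, self.model.constants),
            label="general tree (alpha=1)",
            ls="--",
        )
        ax.set_xlabel("time (s)")
        ax.set_ylabel("pressure drop (cmH2O)")
        ax.legend()
        return ax


class AirwayBranchingModel:
    """One breath plus the airway tree whose diameters are to be rescaled.

    Parameters
    ----------
    breath : Breath
        Segmented breath (time, airway pressure, signed flow, volume).
    tree : AirwayTree, optional
        Reference geometry; defaults to the general 25-generation tree.
        Any prior diameter scaling is undone before fitting.
    constants : ModelConstants, optional
        Gas properties and minor-loss coefficient.
    """

    def __init__(
        self,
        breath: Breath,
        tree: Optional[AirwayTree] = None,
        constants: ModelConstants = DEFAULT_CONSTANTS,
    ):
        self.breath = breath
        self.tree = unscaled(tree) if tree is not None else build_default_tree()
        self.constants = constants

    @classmethod
    def from_dataframe(cls, df, tree=None, constants=DEFAULT_CONSTANTS):
        """Build from a DataFrame with columns time_s, pressure_cmH2O, flow_Lps
        (volume_L optional; integrated with drift correction if absent)."""
        required = ["time_s", "pressure_cmH2O", "flow_Lps"]
        for col in required:
            if col not in df.columns:
                raise ValueError(f"waveform table missing column: {col}")
        t = df["time_s"].to_numpy(dtype=float)
        p = df["pressure_cmH2O"].to_numpy(dtype=float)
        q = df["flow_Lps"].to_numpy(dtype=float)
        if "volume_L" in df.columns:
            v = df["volume_L"].to_numpy(dtype=float)
        else:
            v = integrate_volume(q, t, drift_correct=True)
        return cls(Breath(t, p, q, v), tree=tree, constants=constants)

    def fit(self, n_isovolumes: int = DEFAULT_N_ISOVOLUMES) -> AlphaFitResults:
        """Identify alpha by AUC matching against the dynostatic drop."""
        dsa_res = dsa_drop_series(self.breath, n_isovolumes)
        t_i, _, q_i, _ = self.breath.inspiration()

        auc_dsa = auc(dsa_res.dp_dsa, t_i)
        if auc_dsa <= 0:
            raise ValueError(
                f"dynostatic AUC is non-positive ({auc_dsa:.4g} cmH2O*s); "
                "no alpha estimate is possible for this breath"
            )
        dp1 = drop_waveform(self.tree, q_i, self.constants)
        auc1 = auc(dp1, t_i)

        raw = (auc1 / auc_dsa) ** 0.25
        alpha = alpha_closed_form(auc1, auc_dsa)
        clamped = not np.isclose(raw, alpha)
        auc_ps = auc1 / alpha**4

        try:
            pw = alpha_pointwise(dsa_res.dp_dsa, self.tree, q_i, self.constants)
        except ValueError:
            pw = np.full_like(dsa_res.dp_dsa, np.nan)
        valid = pw[np.isfinite(pw)]
        if valid.size:
            mad = np.median(np.abs(valid - np.median(valid)))
            se = 1.4826 * mad / np.sqrt(valid.size)
        else:
            se = np.nan

        return AlphaFitResults(
            alpha=alpha,
            alpha_se=float(se),
            auc_abm1=auc1,
            auc_dsa=auc_dsa,
            auc_abmps=auc_ps,
            ape=ape(auc_ps, auc_dsa),
            clamped=bool(clamped),
            dsa=dsa_res,
            alpha_pointwise=pw,
            model=self,
        )


def fit_alpha(
    breath: Breath,
    tree: Optional[AirwayTree] = None,
    constants: ModelConstants = DEFAULT_CONSTANTS,
    n_isovolumes: int = DEFAULT_N_ISOVOLUMES,
) -> AlphaFitResults:
    """Functional shorthand for ``AirwayBranchingModel(breath, ...).fit()``."""
    return AirwayBranchingModel(breath, tree=tree, constants=constants).fit(n_isovolumes)
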