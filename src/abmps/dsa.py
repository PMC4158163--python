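"""Dynostatic algorithm (DSA): alveolar-pressure surrogate at isovolume.

The DSA assumes airway resistance is identical during inspiration and
expiration at the same lung volume. At an isovolume — a volume visited by
both limbs of the breath — equating R_insp = (P_insp - P_dyn)/Q_insp with
R_exp = (P_exp - P_dyn)/Q_exp gives the dynostatic pressure

    P_dyn = (P_insp Q_exp - P_exp Q_insp) / (Q_exp - Q_insp),

a flow-weighted average of the two airway-opening pressures that serves as
the alveolar-pressure estimate. The inspiratory airway pressure drop is
then dP_DSA = P_insp - P_dyn, reported here on the inspiration time base so
it can be integrated over time.

With signed flow (inspiration positive, expiration negative) the
denominator is bounded away from zero except near the phase boundaries;
samples with |Q_exp - Q_insp| below a guard threshold are excluded and
filled by linear interpolation in volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Denominator guard for the isovolume pressure formula, L/s.
FLOW_GUARD_LPS = 0.02

#: Default number of isovolume grid points.
DEFAULT_N_ISOVOLUMES = 100


@dataclass(frozen=True)
class Breath:
    """One segmented breath: airway-opening pressure and signed flow.

    time is in s (strictly increasing), pressure in cmH2O, flow in L/s
    (inspiration positive), volume in L above end-expiration.
    """

    time: np.ndarray
    pressure: np.ndarray
    flow: np.ndarray
    volume: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.time)
        if not (len(self.pressure) == len(self.flow) == len(self.volume) == n):
            raise ValueError("time, pressure, flow and volume must have equal length")
        if n < 4:
            raise ValueError("a breath needs at least 4 samples")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if not (np.any(self.flow > 0) and np.any(self.flow < 0)):
            raise ValueError("breath must contain both inspiratory and expiratory flow")

    @property
    def i_end_inspiration(self) -> int:
        """Index of end-inspiration, taken at the volume maximum."""
        return int(np.argmax(self.volume))

    def inspiration(self) -> tuple[np.ndarray, ...]:
        # the volume maximum may fall on the first expiratory sample; keep
        # only the leading samples with positive (inspiratory) flow
        i = self.i_end_inspiration
        while i > 0 and self.flow[i] <= 0:
            i -= 1
        return (
            self.time[: i + 1],
            self.pressure[: i + 1],
            self.flow[: i + 1],
            self.volume[: i + 1],
        )

    def expiration(self) -> tuple[np.ndarray, ...]:
        i = self.i_end_inspiration
        return (
            self.time[i:],
            self.pressure[i:],
            self.flow[i:],
            self.volume[i:],
        )


@dataclass(frozen=True)
class DSAResult:
    """Dynostatic pressure on an isovolume grid plus the inspiratory drop."""

    isovolumes: np.ndarray  # L
    p_dyn: np.ndarray  # cmH2O, on the isovolume grid
    time_insp: np.ndarray  # s, inspiration time base
    dp_dsa: np.ndarray  # cmH2O, on time_insp
    excluded_fraction: float  # share of grid points rejected by the flow guard


def integrate_volume(
    flow: np.ndarray, time: np.ndarray, drift_correct: bool = True
) -> np.ndarray:
    """Cumulative trapezoidal volume (L) from flow (L/s).

    Intervals where the flow reverses sign use the pre-reversal flow
    (left-endpoint rule) instead of the trapezoid: a ventilator's phase
    switch is an abrupt valve event, and interpolating linearly through it
    fabricates a large spurious volume increment at 50 Hz sampling.

    With ``drift_correct`` a linear ramp is subtracted so the last sample
    returns to zero — integration noise and limb asymmetry otherwise leave
    the loop open.
    """
    flow = np.asarray(flow, dtype=float)
    time = np.asarray(time, dtype=float)
    if flow.shape != time.shape:
        raise ValueError("flow and time must have equal length")
    if flow.size and np.any(np.diff(time) <= 0):
        raise ValueError("time must be strictly increasing")
    if flow.size == 0:
        return np.array([])
    dt = np.diff(time)
    inc = 0.5 * (flow[:-1] + flow[1:]) * dt
    reversal = flow[:-1] * flow[1:] < 0
    inc[reversal] = flow[:-1][reversal] * dt[reversal]
    vol = np.concatenate([[0.0], np.cumsum(inc)])
    if drift_correct and vol.size > 1 and time[-1] > time[0]:
        vol = vol - vol[-1] * (time - time[0]) / (time[-1] - time[0])
    return vol


def dynostatic_pressure(p_insp, q_insp, p_exp, q_exp):
    """Dynostatic pressure at isovolume; scalars or arrays.

    Flows are signed (q_insp > 0, q_exp < 0). Raises for a scalar
    denominator inside the guard; array callers mask first.
    """
    denom = np.asarray(q_exp, dtype=float) - np.asarray(q_insp, dtype=float)
    if denom.ndim == 0 and abs(float(denom)) < FLOW_GUARD_LPS:
        raise ValueError(
            f"|q_exp - q_insp| = {abs(float(denom)):.4f} L/s is inside the "
            f"guard band ({FLOW_GUARD_LPS} L/s); exclude or interpolate this sample"
        )
    out = (np.asarray(p_insp) * q_exp - np.asarray(p_exp) * q_insp) / denom
    return float(out) if out.ndim == 0 else out


def isovolume_pairs(breath: Breath, n_points: int = DEFAULT_N_ISOVOLUMES):
    """Interpolate (P, Q) on both limbs at a shared volume grid.

    Returns ``(v_grid, p_insp, q_insp, p_exp, q_exp)`` over the volume range
    common to inspiration and expiration. The grid is uniform in volume and
    avoids the exact limb endpoints, where flow passes through zero.
    """
    if n_points < 2:
        raise ValueError(f"n_points must be >= 2, got {n_points}")
    _, p_i, q_i, v_i = breath.inspiration()
    _, p_e, q_e, v_e = breath.expiration()

    # monotone parameterisation of each limb by volume
    v_i_m = np.maximum.accumulate(v_i)
    v_e_rev = np.minimum.accumulate(v_e)[::-1]  # expiration reversed: increasing
    p_e_rev, q_e_rev = p_e[::-1], q_e[::-1]

    lo = max(v_i_m[0], v_e_rev[0])
    hi = min(v_i_m[-1], v_e_rev[-1])
    if hi <= lo:
        raise ValueError("inspiratory and expiratory volume ranges do not overlap")
    # stay off the extreme ends where one limb's flow vanishes
    pad = 0.005 * (hi - lo)
    grid = np.linspace(lo + pad, hi - pad, n_points)

    p_insp = np.interp(grid, v_i_m, p_i)
    q_insp = np.interp(grid, v_i_m, q_i)
    p_exp = np.interp(grid, v_e_rev, p_e_rev)
    q_exp = np.interp(grid, v_e_rev, q_e_rev)
    return grid, p_insp, q_insp, p_exp, q_exp


def dsa_drop_series(breath: Breath, n_points: int = DEFAULT_N_ISOVOLUMES) -> DSAResult:
    """Dynostatic pressure and inspiratory pressure-drop series for a breath.

    P_dyn is evaluated on the isovolume grid; guarded points (denominator
    inside the flow guard) are filled by linear interpolation in volume.
    dP_DSA = P_insp - P_dyn is mapped back onto the inspiration time base
    through the inspiratory volume-time relation.
    """
    grid, p_i, q_i, p_e, q_e = isovolume_pairs(breath, n_points)

    denom = q_e - q_i
    ok = np.abs(denom) >= FLOW_GUARD_LPS
    if not np.any(ok):
        raise ValueError("all isovolume samples fall inside the flow guard band")
    p_dyn = np.empty_like(grid)
    p_dyn[ok] = (p_i[ok] * q_e[ok] - p_e[ok] * q_i[ok]) / denom[ok]
    if not np.all(ok):
        p_dyn[~ok] = np.interp(grid[~ok], grid[ok], p_dyn[ok])
    excluded = 1.0 - float(np.count_nonzero(ok)) / len(grid)

    t_i, p_insp_t, _, v_insp_t = breath.inspiration()
    v_m = np.maximum.accumulate(v_insp_t)
    p_dyn_t = np.interp(v_m, grid, p_dyn)
    dp = p_insp_t - p_dyn_t

    return DSAResult(
        isovolumes=grid,
        p_dyn=p_dyn,
        time_insp=t_i,
        dp_dsa=dp,
        excluded_fraction=excluded,
    )
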