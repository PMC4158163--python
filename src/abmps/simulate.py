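"""Synthetic ventilator breaths from a single-compartment branching-tree lung.

The generator emulates volume-controlled SIMV breaths: a decreasing-ramp
inspiratory flow profile delivering a set tidal volume, followed by passive
expiration against the ventilator's PEEP. Airway-opening pressure during
inspiration is

    P_ao(t) = PEEP + E * V(t) + dP_tree(Q(t)),

with E the linear compartment elastance and dP_tree the branching-tree drop
at the generator's true diameter multiplier. During passive expiration the
opening is held at PEEP and the stored elastic pressure drives flow through
the same tree: E*V = a*|Q| + b*|Q|^2, with (a, b) the tree's lumped linear
and minor-loss coefficients — solved analytically per step and integrated
by explicit substepping.

Because the generator shares the tree pressure-drop code with the fitter,
a noiseless breath at known alpha is an exact parameter-recovery oracle; a
deliberately mismatched minor-loss coefficient (generator k_l != fitter
k_l) probes robustness to that shared-model assumption.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import DEFAULT_CONSTANTS, ModelConstants
from .dsa import Breath, integrate_volume
from .geometry import AirwayTree, build_default_tree, scale_tree
from .pressure import lumped_coefficients

__all__ = [
    "SynthConfig",
    "WaveformRecord",
    "generate_breath",
    "generate_record",
    "segment_breaths",
    "read_waveform_csv",
    "write_waveform_csv",
]

#: Default flow threshold for inspiration-onset detection, L/s.
SEGMENT_FLOW_THRESHOLD = 0.05


@dataclass(frozen=True)
class SynthConfig:
    """Scenario for one synthetic breath train.

    Defaults mirror the ventilation conditions of the source cohort:
    volume control with tidal volumes of 0.4-0.6 L, PEEP of 5/10/15 cmH2O
    and a decreasing inspiratory flow profile. ``flow_profile`` is the
    ratio of end-inspiratory to peak flow (0 = triangle, 1 = square).
    """

    peep: float = 10.0  # cmH2O
    elastance: float = 30.0  # cmH2O/L
    alpha_true: float = 1.0
    tidal_volume: float = 0.5  # L
    inspiratory_time: float = 1.0  # s
    expiratory_time: float = 3.0  # s
    flow_profile: float = 0.25
    k_l: float = DEFAULT_CONSTANTS.k_l
    noise_sd: float = 0.0  # cmH2O, Gaussian, pressure channel
    seed: int = 0
    sample_rate: float = 50.0  # Hz

    def __post_init__(self) -> None:
        if not 0.2 <= self.tidal_volume <= 1.0:
            raise ValueError(
                f"tidal_volume must be in [0.2, 1.0] L, got {self.tidal_volume}"
            )
        if self.peep < 0:
            raise ValueError(f"peep must be non-negative, got {self.peep}")
        if not 0.0 <= self.flow_profile <= 1.0:
            raise ValueError(
                f"flow_profile must be in [0, 1], got {self.flow_profile}"
            )
        for name in ("elastance", "inspiratory_time", "expiratory_time", "sample_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be non-negative, got {self.noise_sd}")

    def constants(self, base: ModelConstants = DEFAULT_CONSTANTS) -> ModelConstants:
        return ModelConstants(mu=base.mu, rho=base.rho, k_l=self.k_l)


@dataclass(frozen=True)
class WaveformRecord:
    """Continuous multi-breath waveform with known inspiration onsets.

    ``volume`` may be None when the source did not provide a volume
    channel; consumers then integrate flow per breath.
    """

    time: np.ndarray
    pressure: np.ndarray
    flow: np.ndarray
    volume: np.ndarray | None
    boundaries: np.ndarray  # sample indices of inspiration onsets

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries)
        if b.size and np.any(np.diff(b) <= 0):
            raise ValueError("breath boundaries must be strictly increasing")


def _expiratory_flow(v: float, a: float, b: float, elastance: float) -> float:
    """Passive expiratory flow magnitude from E*V = a*Q + b*Q^2 (Q >= 0)."""
    drive = elastance * v
    if drive <= 0:
        return 0.0
    if b <= 0:
        return drive / a
    return (-a + np.sqrt(a * a + 4.0 * b * drive)) / (2.0 * b)


def generate_breath(
    config: SynthConfig,
    tree: AirwayTree | None = None,
    constants: ModelConstants | None = None,
) -> Breath:
    """Simulate one breath. Same config and seed give bit-identical output."""
    tree = tree if tree is not None else build_default_tree()
    constants = constants if constants is not None else config.constants()
    scaled = scale_tree(tree, config.alpha_true)
    a, b = lumped_coefficients(scaled, constants)

    dt = 1.0 / config.sample_rate
    t_i = config.inspiratory_time
    r = config.flow_profile
    # decreasing ramp q(t) = q_peak * (1 - (1 - r) t / T_i), integral = V_T
    q_peak = 2.0 * config.tidal_volume / (t_i * (1.0 + r))

    n_insp = max(int(round(t_i * config.sample_rate)), 2)
    n_exp = max(int(round(config.expiratory_time * config.sample_rate)), 2)
    time = np.arange(n_insp + n_exp) * dt

    ti = time[:n_insp]
    q_insp = q_peak * (1.0 - (1.0 - r) * ti / t_i)
    v_insp = q_peak * (ti - (1.0 - r) * ti**2 / (2.0 * t_i))
    p_insp = config.peep + config.elastance * v_insp + a * q_insp + b * q_insp**2

    # passive expiration: explicit substepping keeps fast (large-alpha) trees stable
    n_sub = 20
    dts = dt / n_sub
    v = config.tidal_volume  # inspiration delivers exactly V_T by t = T_i
    q_exp = np.empty(n_exp)
    v_exp = np.empty(n_exp)
    for k in range(n_exp):
        q = _expiratory_flow(v, a, b, config.elastance)
        q_exp[k] = -q
        v_exp[k] = v
        for _ in range(n_sub):
            v = max(v - _expiratory_flow(v, a, b, config.elastance) * dts, 0.0)
    p_exp = np.full(n_exp, config.peep)

    pressure = np.concatenate([p_insp, p_exp])
    flow = np.concatenate([q_insp, q_exp])
    volume = np.concatenate([v_insp, v_exp])

    if config.noise_sd > 0:
        rng = np.random.default_rng(config.seed)
        pressure = pressure + rng.normal(0.0, config.noise_sd, pressure.shape)

    return Breath(time=time, pressure=pressure, flow=flow, volume=volume)


def generate_record(
    config: SynthConfig,
    n_breaths: int = 3,
    tree: AirwayTree | None = None,
    constants: ModelConstants | None = None,
) -> WaveformRecord:
    """Concatenate ``n_breaths`` identical-scenario breaths into one record.

    Per-breath noise draws differ (seed offset by breath index) so repeated
    breaths are realisations, not copies.
    """
    if n_breaths < 1:
        raise ValueError("n_breaths must be >= 1")
    times, pressures, flows, volumes, bounds = [], [], [], [], []
    t0 = 0.0
    idx = 0
    for i in range(n_breaths):
        cfg = SynthConfig(**{**asdict(config), "seed": config.seed + i})
        br = generate_breath(cfg, tree=tree, constants=constants)
        times.append(br.time + t0)
        pressures.append(br.pressure)
        flows.append(br.flow)
        volumes.append(br.volume)
        bounds.append(idx)
        idx += len(br.time)
        t0 += br.time[-1] + (br.time[1] - br.time[0])
    return WaveformRecord(
        time=np.concatenate(times),
        pressure=np.concatenate(pressures),
        flow=np.concatenate(flows),
        volume=np.concatenate(volumes),
        boundaries=np.array(bounds, dtype=int),
    )


def segment_breaths(
    record: WaveformRecord, flow_threshold: float = SEGMENT_FLOW_THRESHOLD
) -> list[Breath]:
    """Split a record into breaths at inspiration onsets.

    An onset is an upward crossing of +threshold whose preceding samples
    are expiratory or near-zero. Breaths run onset-to-onset; the trailing
    partial segment after the last onset is kept only if it contains a full
    cycle (both phases). A volume channel on the record is preserved and
    re-zeroed per breath; without one, volume is integrated per breath.
    """
    flow = np.asarray(record.flow, dtype=float)
    if flow.size == 0:
        return []
    above = flow >= flow_threshold
    onsets = []
    armed = True  # start of record counts as preceded by no inspiration
    for i in range(flow.size):
        if above[i] and armed:
            onsets.append(i)
            armed = False
        elif not armed and flow[i] < 0:
            armed = True  # expiration seen: re-arm for the next breath
    breaths: list[Breath] = []
    edges = onsets + [flow.size]
    for s, e in zip(edges[:-1], edges[1:]):
        t = record.time[s:e]
        q = flow[s:e]
        if len(t) < 4 or not (np.any(q > 0) and np.any(q < 0)):
            continue  # trailing partial or degenerate segment
        if record.volume is not None:
            v = record.volume[s:e] - record.volume[s]
        else:
            v = integrate_volume(q, t, drift_correct=True)
        breaths.append(Breath(time=t - t[0], pressure=record.pressure[s:e], flow=q, volume=v))
    return breaths


def write_waveform_csv(record: WaveformRecord, path: str | Path) -> None:
    cols = {
        "time_s": record.time,
        "pressure_cmH2O": record.pressure,
        "flow_Lps": record.flow,
    }
    if record.volume is not None:
        cols["volume_L"] = record.volume
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.9g")


def read_waveform_csv(path: str | Path) -> WaveformRecord:
    """Read a waveform CSV; a volume column is preserved, never recomputed.

    Without a volume column the record carries volume = None and consumers
    (e.g. segment_breaths) integrate flow per breath.
    """
    df = pd.read_csv(path)
    for col in ("time_s", "pressure_cmH2O", "flow_Lps"):
        if col not in df.columns:
            raise ValueError(f"waveform file missing required column: {col}")
    t = df["time_s"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("time_s must be strictly increasing")
    q = df["flow_Lps"].to_numpy(dtype=float)
    v = df["volume_L"].to_numpy(dtype=float) if "volume_L" in df.columns else None
    return WaveformRecord(
        time=t,
        pressure=df["pressure_cmH2O"].to_numpy(dtype=float),
        flow=q,
        volume=v,
        boundaries=np.array([0], dtype=int),
    )


def write_sidecar(config: SynthConfig, path: str | Path, extra: dict | None = None) -> None:
    """Ground-truth JSON next to a simulated waveform (alpha_true included)."""
    payload = {"generator": asdict(config)}
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
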