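"""Physical constants and unit conversions.

All internal pressure-drop computation is done in SI units (m, m^3/s, Pa);
the public API speaks the clinical units of ventilator waveforms
(mm, L/s, cmH2O).
"""

from __future__ import annotations

from dataclasses import dataclass

#: Pascals per centimetre of water (conventional cmH2O at 4 degC).
PA_PER_CMH2O: float = 98.0665

#: Litres per cubic metre.
L_PER_M3: float = 1000.0

#: Millimetres per metre.
MM_PER_M: float = 1000.0

#: Reynolds number above which flow is no longer treated as laminar.
RE_LAMINAR_LIMIT: float = 2000.0


@dataclass(frozen=True)
class ModelConstants:
    """Gas properties and loss coefficient of the branching-tree model.

    Parameters
    ----------
    mu : float
        Dynamic viscosity of air in Pa*s. Default 1.9e-5.
    rho : float
        Air density in kg/m^3. Default 1.25.
    k_l : float
        Dimensionless minor (bifurcation) loss coefficient. Default 2.0.
        Set to 0 for a purely linear (Poiseuille) tree.
    """

    mu: float = 1.9e-5
    rho: float = 1.25
    k_l: float = 2.0

    def __post_init__(self) -> None:
        if not self.mu > 0:
            raise ValueError(f"mu must be strictly positive, got {self.mu}")
        if not self.rho > 0:
            raise ValueError(f"rho must be strictly positive, got {self.rho}")
        if self.k_l < 0:
            raise ValueError(f"k_l must be non-negative, got {self.k_l}")


#: Default air properties shared across the package.
DEFAULT_CONSTANTS = ModelConstants()


def cmh2o_to_pa(p: float) -> float:
    return p * PA_PER_CMH2O


def pa_to_cmh2o(p: float) -> float:
    return p / PA_PER_CMH2O


def lps_to_m3s(q: float) -> float:
    return q / L_PER_M3


def mm_to_m(x: float) -> float:
    return x / MM_PER_M
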