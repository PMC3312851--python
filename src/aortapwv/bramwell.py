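"""Bramwell-Hill model: distensibility, wave speed and pulse pressure.

The model links the propagation speed of the systolic wave to vessel wall
compliance:

    PWV = (rho * D)^(-1/2)

with rho the blood density and D the distensibility, estimated from the
relative luminal area change over the local pulse pressure:

    D = dA / (A_min * dP)

Areas enter as mm^2 (the ratio dA/A_min is dimensionless); pulse pressure is
given in clinical mmHg and converted internally to Pa (1 mmHg = 133.322 Pa),
so D is carried in Pa^-1.  The model can be applied inversely to estimate the
local pulse pressure from a measured PWV and area distension.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import DomainError

__all__ = [
    "MMHG_TO_PA",
    "BloodConstants",
    "DistensibilityResult",
    "distensibility",
    "theoretical_pwv",
    "pwv_from_distensibility",
    "pulse_pressure_from_pwv",
]

#: Pascal per mmHg.
MMHG_TO_PA = 133.322


@dataclass(frozen=True)
class BloodConstants:
    """Physical constants; blood density defaults to 1059 kg/m^3."""

    rho: float = 1059.0

    def __post_init__(self) -> None:
        if self.rho <= 0:
            raise DomainError("blood density must be > 0")


@dataclass(frozen=True)
class DistensibilityResult:
    """Area distension, pulse pressure and the derived distensibility."""

    delta_A_mm2: float
    A_min_mm2: float
    delta_P_mmHg: float
    D_per_Pa: float

    @property
    def D_per_mmHg(self) -> float:
        return self.D_per_Pa * MMHG_TO_PA

    @property
    def D_per_mmHg_e3(self) -> float:
        """Distensibility in the conventional 10^-3 mmHg^-1 display units."""
        return self.D_per_mmHg * 1e3


def distensibility(
    delta_A_mm2: float, A_min_mm2: float, delta_P_mmHg: float
) -> DistensibilityResult:
    """Distensibility D = (dA / A_min) / dP, returned in Pa^-1.

    Raises
    ------
    DomainError
        Non-positive minimal area or pulse pressure, or negative dA.
    """
    if A_min_mm2 <= 0:
        raise DomainError("A_min_mm2 must be > 0")
    if delta_P_mmHg <= 0:
        raise DomainError("delta_P_mmHg must be > 0")
    if delta_A_mm2 < 0:
        raise DomainError("delta_A_mm2 must be >= 0")
    d = (delta_A_mm2 / A_min_mm2) / (delta_P_mmHg * MMHG_TO_PA)
    return DistensibilityResult(
        delta_A_mm2=float(delta_A_mm2),
        A_min_mm2=float(A_min_mm2),
        delta_P_mmHg=float(delta_P_mmHg),
        D_per_Pa=float(d),
    )


def pwv_from_distensibility(
    d_per_pa: float, constants: BloodConstants = BloodConstants()
) -> float:
    """PWV in m/s from a distensibility in Pa^-1: (rho * D)^(-1/2)."""
    if d_per_pa <= 0:
        raise DomainError("distensibility must be > 0 (zero implies infinite PWV)")
    return (constants.rho * d_per_pa) ** -0.5


def theoretical_pwv(
    d: DistensibilityResult, constants: BloodConstants = BloodConstants()
) -> float:
    """Modeled PWV from a distensibility result (m/s)."""
    return pwv_from_distensibility(d.D_per_Pa, constants)


def pulse_pressure_from_pwv(
    pwv_m_per_s: float,
    delta_A_mm2: float,
    A_min_mm2: float,
    constants: BloodConstants = BloodConstants(),
) -> float:
    """Local pulse pressure (mmHg) implied by a PWV and an area distension.

    Algebraic inverse of the model: dP = rho * PWV^2 * (dA / A_min),
    converted back from Pa to mmHg.
    """
    if pwv_m_per_s <= 0 or delta_A_mm2 <= 0 or A_min_mm2 <= 0:
        raise DomainError("all arguments must be positive")
    dp_pa = constants.rho * pwv_m_per_s**2 * (delta_A_mm2 / A_min_mm2)
    return dp_pa / MMHG_TO_PA
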