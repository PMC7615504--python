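"""Moist-air state conversions.

Every heat stress index in this package is a function of a single
atmospheric state (dry-bulb temperature, humidity, wind, radiant
temperature, pressure).  This module defines that state container and the
psychrometric conversions the indices share: saturation vapour pressure,
actual vapour pressure, specific humidity and dewpoint.

Saturation vapour pressure uses Buck's (1981) curve over liquid water.
The choice is isolated behind :func:`saturation_vapour_pressure` so an
alternative fit (e.g. Bolton) could be swapped without touching any index.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

__all__ = [
    "AirState",
    "DomainError",
    "SupersaturationError",
    "saturation_vapour_pressure",
    "vapour_pressure",
    "specific_humidity",
    "rh_from_specific_humidity",
    "dewpoint",
    "STANDARD_PRESSURE_KPA",
]

#: Default station pressure (kPa).  Sea-level standard atmosphere.
STANDARD_PRESSURE_KPA = 101.325

# Buck (1981) ew2 coefficients, liquid water, e in kPa, T in degC.
_BUCK_A = 0.61121
_BUCK_B = 17.502
_BUCK_C = 240.97

_T_MIN, _T_MAX = -40.0, 60.0


class DomainError(ValueError):
    """An input lies outside the physical domain of a conversion."""


class SupersaturationError(DomainError):
    """A specific humidity implies relative humidity above 100 %."""


@dataclass(frozen=True)
class AirState:
    """One atmospheric condition.

    Parameters
    ----------
    t_c : float
        Dry-bulb air temperature, degC.
    rh_pct : float
        Relative humidity on the 0-100 % scale.
    wind_ms : float
        10 m wind speed, m/s.  Defaults to 0.5 m/s, the fixed assumption
        used throughout the index comparisons.
    tmrt_c : float or None
        Mean radiant temperature, degC.  ``None`` (the default) means the
        radiant temperature tracks the air temperature, so perturbing
        ``t_c`` moves the radiant temperature with it.
    p_kpa : float
        Station pressure, kPa.
    """

    t_c: float
    rh_pct: float
    wind_ms: float = 0.5
    tmrt_c: float | None = None
    p_kpa: float = STANDARD_PRESSURE_KPA

    def __post_init__(self) -> None:
        if not 0.0 <= self.rh_pct <= 100.0:
            raise DomainError(f"rh_pct={self.rh_pct} outside [0, 100]")
        if not self.wind_ms > 0.0:
            raise DomainError(f"wind_ms={self.wind_ms} must be positive")
        if not self.p_kpa > 0.0:
            raise DomainError(f"p_kpa={self.p_kpa} must be positive")

    @property
    def tmrt(self) -> float:
        """Effective mean radiant temperature (degC)."""
        return self.t_c if self.tmrt_c is None else self.tmrt_c

    def shift(self, dt: float = 0.0, dh: float = 0.0) -> "AirState":
        """Return a copy displaced by ``dt`` degC and ``dh`` % RH.

        An unspecified radiant temperature keeps tracking the shifted air
        temperature; an explicit one stays fixed.
        """
        return replace(self, t_c=self.t_c + dt, rh_pct=self.rh_pct + dh)


def saturation_vapour_pressure(t_c: float) -> float:
    """Saturation vapour pressure over liquid water (kPa), Buck 1981.

    Strictly positive and strictly increasing on the supported range
    [-40, 60] degC.
    """
    if not _T_MIN <= t_c <= _T_MAX:
        raise DomainError(
            f"t_c={t_c} outside supported range [{_T_MIN}, {_T_MAX}] degC"
        )
    return _BUCK_A * math.exp(_BUCK_B * t_c / (_BUCK_C + t_c))


def vapour_pressure(t_c: float, rh_pct: float) -> float:
    """Actual vapour pressure e = (rh/100) * esat(T), in kPa."""
    if not 0.0 <= rh_pct <= 100.0:
        raise DomainError(f"rh_pct={rh_pct} outside [0, 100]")
    return (rh_pct / 100.0) * saturation_vapour_pressure(t_c)


def specific_humidity(
    t_c: float, rh_pct: float, p_kpa: float = STANDARD_PRESSURE_KPA
) -> float:
    """Specific humidity q (kg water vapour per kg moist air).

    q = 0.622 e / (p - 0.378 e).  Inverse of
    :func:`rh_from_specific_humidity` at the same temperature and pressure.
    """
    e = vapour_pressure(t_c, rh_pct)
    if e >= p_kpa:
        raise DomainError(f"vapour pressure {e} kPa >= total pressure {p_kpa} kPa")
    return 0.622 * e / (p_kpa - 0.378 * e)


def rh_from_specific_humidity(
    q: float, t_c: float, p_kpa: float = STANDARD_PRESSURE_KPA
) -> float:
    """Relative humidity (%) implied by specific humidity q at (T, p).

    Raises :class:`SupersaturationError` if the implied relative humidity
    exceeds 100 % (beyond numerical round-off); never silently clips.
    """
    if q < 0.0:
        raise DomainError(f"q={q} must be non-negative")
    e = q * p_kpa / (0.622 + 0.378 * q)
    rh = 100.0 * e / saturation_vapour_pressure(t_c)
    if rh > 100.0:
        if rh <= 100.0 + 1e-9:
            return 100.0
        raise SupersaturationError(
            f"q={q} at T={t_c} degC, p={p_kpa} kPa implies rh={rh:.2f} % > 100 %"
        )
    return rh


def dewpoint(t_c: float, rh_pct: float) -> float:
    """Dewpoint temperature (degC): the T at which esat equals e(T, rh).

    Uses the exact analytic inverse of the Buck curve.  Undefined at zero
    humidity; equals the air temperature at saturation.
    """
    if rh_pct <= 0.0:
        raise DomainError("dewpoint undefined at zero relative humidity")
    e = vapour_pressure(t_c, rh_pct)
    x = math.log(e / _BUCK_A)
    return _BUCK_C * x / (_BUCK_B - x)
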