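"""Heat stress index evaluators.

Each index is a pure mapping from an :class:`~heatsens.psychro.AirState`
to an :class:`IndexValue` carrying an explicit defined/undefined contract:
an evaluator never extrapolates silently outside its published validity
range, it flags the state instead.  All indices here are on degC-like
scales but are *not* mutually comparable; comparing their humidity
sensitivity is the job of :mod:`heatsens.variational`.

Indices
-------
WBT
    Thermodynamic wet-bulb temperature, obtained by inverting Bolton's
    equivalent potential temperature (the quantity conserved under
    adiabatic saturation), following Davies-Jones.
HI
    NOAA's heat index (Rothfusz regression with the low/high humidity
    adjustments and the below-80 degF simple-average branch).
HUMIDEX
    Meteorological Service of Canada humidex.
AT
    Steadman's shaded apparent temperature, with wind but no radiation.
UTCI
    Universal thermal climate index, 6th-order polynomial approximation
    with the published validity limits applied.
WBGT_INDOOR
    Wet-bulb globe temperature without the radiation (black-globe) term,
    a wind-dependent blend of WBT and air temperature.
SWBGT
    Simplified WBGT, a linear temperature / vapour-pressure form.
TS_MORA
    WBT plus a humidity-dependent offset, 4.5 * (1 - h^2) degC with h the
    fractional relative humidity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

from scipy.optimize import brentq

from ._utci_coeffs import COEFFS as _UTCI_COEFFS
from ._utci_coeffs import EXPONENTS as _UTCI_EXPONENTS
from .psychro import (
    AirState,
    dewpoint,
    saturation_vapour_pressure,
    vapour_pressure,
)

__all__ = [
    "IndexValue",
    "IndexEvaluator",
    "REGISTRY",
    "get_index",
    "index_names",
    "wbt",
    "heat_index",
    "humidex",
    "apparent_temperature",
    "utci",
    "wbgt_indoor",
    "swbgt",
    "ts_mora",
    "UTCI_VP_LIMIT_KPA",
    "UTCI_T_LIMIT_C",
]

# UTCI polynomial validity box (Broede et al. reference conditions).
UTCI_T_LIMIT_C = 50.0
UTCI_T_LOWER_C = -50.0
UTCI_VP_LIMIT_KPA = 5.0
UTCI_WIND_RANGE_MS = (0.5, 17.0)
UTCI_DTMRT_RANGE_K = (-30.0, 70.0)

_WBT_TOL_C = 0.01


@dataclass(frozen=True)
class IndexValue:
    """Result of evaluating one index at one atmospheric state."""

    value: float
    defined: bool = True
    reason: str | None = None

    @staticmethod
    def undefined(reason: str) -> "IndexValue":
        return IndexValue(value=math.nan, defined=False, reason=reason)


IndexEvaluator = Callable[[AirState], IndexValue]


# ---------------------------------------------------------------------------
# Wet-bulb temperature
# ---------------------------------------------------------------------------

def _theta_e(t_c: float, e_kpa: float, p_kpa: float) -> float:
    """Bolton (1980) equivalent potential temperature (K).

    Uses the lifting-condensation-level temperature form; exact enough
    that inverting it reproduces the thermodynamic wet-bulb temperature
    to well under the 0.01 degC solver tolerance.
    """
    tk = t_c + 273.15
    e_hpa = e_kpa * 10.0
    p_hpa = p_kpa * 10.0
    r = 0.622 * e_hpa / (p_hpa - e_hpa)  # mixing ratio, kg/kg
    if e_hpa > 0.0:
        t_lcl = 2840.0 / (3.5 * math.log(tk) - math.log(e_hpa) - 4.805) + 55.0
    else:
        t_lcl = tk  # irrelevant: the exponential term is 1 when r = 0
    theta_dl = tk * (1000.0 / p_hpa) ** (0.2854 * (1.0 - 0.28 * r))
    return theta_dl * math.exp((3376.0 / t_lcl - 2.54) * r * (1.0 + 0.81 * r))


def wbt(state: AirState) -> IndexValue:
    """Thermodynamic wet-bulb temperature (degC), Davies-Jones approach.

    The wet-bulb temperature of a parcel is the temperature at which a
    *saturated* parcel at the same pressure has the same equivalent
    potential temperature.  It is found by bracketed root-finding on
    Bolton's theta-e, converged to <= 0.01 degC.
    """
    e = vapour_pressure(state.t_c, state.rh_pct)
    target = _theta_e(state.t_c, e, state.p_kpa)

    def f(tw: float) -> float:
        return _theta_e(tw, saturation_vapour_pressure(tw), state.p_kpa) - target

    hi = min(state.t_c + 1e-6, 60.0)
    lo = -40.0
    try:
        if f(hi) < 0.0:
            # target theta-e above the saturated curve at t_c: saturated air,
            # wet bulb equals the dry bulb to solver precision.
            return IndexValue(state.t_c)
        tw = brentq(f, lo, hi, xtol=_WBT_TOL_C / 10.0, maxiter=100)
    except ValueError:
        return IndexValue.undefined("CONVERGENCE")
    return IndexValue(min(tw, state.t_c))


# ---------------------------------------------------------------------------
# NOAA heat index
# ---------------------------------------------------------------------------

def heat_index(state: AirState) -> IndexValue:
    """NOAA heat index (degC).

    Evaluated in degF per the NOAA specification: the simple Steadman
    average is computed first; when it reaches 80 degF the Rothfusz
    regression applies, with the published low-humidity and high-humidity
    adjustment terms.
    """
    t = state.t_c * 9.0 / 5.0 + 32.0
    rh = state.rh_pct
    simple = 0.5 * (t + 61.0 + (t - 68.0) * 1.2 + rh * 0.094)
    if simple < 80.0:
        hi_f = simple
    else:
        hi_f = (
            -42.379
            + 2.04901523 * t
            + 10.14333127 * rh
            - 0.22475541 * t * rh
            - 6.83783e-3 * t * t
            - 5.481717e-2 * rh * rh
            + 1.22874e-3 * t * t * rh
            + 8.5282e-4 * t * rh * rh
            - 1.99e-6 * t * t * rh * rh
        )
        if rh < 13.0 and 80.0 <= t <= 112.0:
            hi_f -= ((13.0 - rh) / 4.0) * math.sqrt((17.0 - abs(t - 95.0)) / 17.0)
        elif rh > 85.0 and 80.0 <= t <= 87.0:
            hi_f += ((rh - 85.0) / 10.0) * ((87.0 - t) / 5.0)
    return IndexValue((hi_f - 32.0) * 5.0 / 9.0)


# ---------------------------------------------------------------------------
# Humidex and apparent temperature
# ---------------------------------------------------------------------------

def humidex(state: AirState) -> IndexValue:
    """Humidex (degC): T + 0.5555 * (e_hPa - 10), e from the dewpoint."""
    if state.rh_pct <= 0.0:
        return IndexValue.undefined("RH_ZERO")
    # e = esat(dewpoint) exactly, since the dewpoint is the analytic
    # inverse of the same saturation curve
    e_hpa = 10.0 * vapour_pressure(state.t_c, state.rh_pct)
    return IndexValue(state.t_c + 0.5555 * (e_hpa - 10.0))


def apparent_temperature(state: AirState) -> IndexValue:
    """Steadman's shaded apparent temperature (degC), with wind.

    AT = T + 0.33 e - 0.70 v - 4.00, with e the vapour pressure in hPa and
    v the 10 m wind speed in m/s; no radiation term.
    """
    e_hpa = 10.0 * vapour_pressure(state.t_c, state.rh_pct)
    return IndexValue(state.t_c + 0.33 * e_hpa - 0.70 * state.wind_ms - 4.00)


# ---------------------------------------------------------------------------
# UTCI
# ---------------------------------------------------------------------------

def utci(state: AirState) -> IndexValue:
    """Universal thermal climate index (degC), polynomial approximation.

    Returns a flagged-undefined value outside the published validity box
    (air temperature in [-50, 50] degC, vapour pressure <= 5 kPa, wind in
    [0.5, 17] m/s, Tmrt - Ta in [-30, 70] K) rather than extrapolating.
    """
    ta = state.t_c
    va = state.wind_ms
    d_tmrt = state.tmrt - ta
    if ta > UTCI_T_LIMIT_C or ta < UTCI_T_LOWER_C:
        return IndexValue.undefined("T_LIMIT")
    try:
        e_kpa = vapour_pressure(ta, state.rh_pct)
    except Exception:
        # below the saturation-curve fit domain; no heat-stress relevance
        return IndexValue.undefined("T_LIMIT")
    if e_kpa > UTCI_VP_LIMIT_KPA:
        return IndexValue.undefined("VP_LIMIT")
    if not UTCI_WIND_RANGE_MS[0] <= va <= UTCI_WIND_RANGE_MS[1]:
        return IndexValue.undefined("WIND_LIMIT")
    if not UTCI_DTMRT_RANGE_K[0] <= d_tmrt <= UTCI_DTMRT_RANGE_K[1]:
        return IndexValue.undefined("TMRT_LIMIT")

    # Precompute powers once; the polynomial has 210 monomials of total
    # degree <= 6 in (Ta, va, D_Tmrt, Pa).
    tp = [1.0] * 7
    vp = [1.0] * 7
    dp = [1.0] * 7
    pp = [1.0] * 7
    for i in range(1, 7):
        tp[i] = tp[i - 1] * ta
        vp[i] = vp[i - 1] * va
        dp[i] = dp[i - 1] * d_tmrt
        pp[i] = pp[i - 1] * e_kpa
    offset = 0.0
    for (a, b, c, d), coef in zip(_UTCI_EXPONENTS, _UTCI_COEFFS):
        offset += coef * tp[a] * vp[b] * dp[c] * pp[d]
    return IndexValue(ta + offset)


# ---------------------------------------------------------------------------
# WBGT family and Ts
# ---------------------------------------------------------------------------

def wbgt_indoor(state: AirState) -> IndexValue:
    """WBGT without the radiation term (degC), Lemke & Kjellstrom.

    0.67 Tw + 0.33 Ta - 0.048 log10(v) (Ta - Tw): a wind-dependent convex
    blend of the psychrometric wet-bulb temperature and air temperature.
    """
    w = wbt(state)
    if not w.defined:
        return w
    k = 0.048 * math.log10(state.wind_ms)
    return IndexValue(
        0.67 * w.value + 0.33 * state.t_c - k * (state.t_c - w.value)
    )


def swbgt(state: AirState) -> IndexValue:
    """Simplified WBGT (degC): 0.567 T + 0.393 e_hPa + 3.94."""
    e_hpa = 10.0 * vapour_pressure(state.t_c, state.rh_pct)
    return IndexValue(0.567 * state.t_c + 0.393 * e_hpa + 3.94)


def ts_mora(state: AirState) -> IndexValue:
    """Mora-derived heat stress metric (degC): WBT + 4.5 (1 - h^2).

    h is the *fractional* relative humidity, so the offset spans 4.5 degC
    at bone-dry air down to 0 at saturation.
    """
    w = wbt(state)
    if not w.defined:
        return w
    f = state.rh_pct / 100.0
    return IndexValue(w.value + 4.5 * (1.0 - f * f))


# ---------------------------------------------------------------------------
# Registry
# ---------------------------------------------------------------------------

REGISTRY: dict[str, IndexEvaluator] = {
    "WBT": wbt,
    "HI": heat_index,
    "HUMIDEX": humidex,
    "AT": apparent_temperature,
    "UTCI": utci,
    "WBGT_INDOOR": wbgt_indoor,
    "SWBGT": swbgt,
    "TS_MORA": ts_mora,
}


def index_names() -> list[str]:
    """Stable identifiers of all registered indices."""
    return list(REGISTRY)


def get_index(name: str) -> IndexEvaluator:
    """Look up an index evaluator by its (case-insensitive) identifier."""
    key = name.strip().upper()
    try:
        return REGISTRY[key]
    except KeyError:
        raise KeyError(
            f"unknown index {name!r}; known: {', '.join(REGISTRY)}"
        ) from None
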