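"""Shared fixtures and independent oracles.

The oracles here are deliberately written from the defining equations,
not by calling the package's own code paths, so they stay independent of
what they check:

* ``balance_wbt`` solves the isobaric psychrometric balance
  cp (T - Tw) = Lv(Tw) (rs(Tw) - r) by plain bisection.
* ``stull_wbt`` is Stull's (2011) empirical psychrometric wet-bulb fit.
* ``kendall_tau_brute`` / ``spearman_via_ranks`` are O(n^2) concordance
  counting and rank-transform-then-Pearson.
* ``bolton_theta_e`` re-states the equivalent potential temperature used
  to build adiabatic-saturation paths.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

# Buck (1981) saturation curve, restated here so oracle inputs match the
# package's humidity convention without importing its internals.
def esat_kpa(t_c: float) -> float:
    return 0.61121 * math.exp(17.502 * t_c / (240.97 + t_c))


def balance_wbt(t_c: float, rh_pct: float, p_kpa: float = 101.325) -> float:
    """Isobaric psychrometric-balance wet bulb by bisection."""
    e = rh_pct / 100.0 * esat_kpa(t_c)
    r = 0.622 * e / (p_kpa - e)

    def f(tw: float) -> float:
        es = esat_kpa(tw)
        rs = 0.622 * es / (p_kpa - es)
        lv = 2.501e6 - 2340.0 * tw
        cp = 1005.0 + 1850.0 * r
        return cp * (t_c - tw) - lv * (rs - r)

    lo, hi = -40.0, t_c
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if f(mid) > 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def stull_wbt(t_c: float, rh_pct: float) -> float:
    """Stull's empirical wet-bulb fit (valid mid-range, ~+-0.3 degC)."""
    return (
        t_c * math.atan(0.151977 * math.sqrt(rh_pct + 8.313659))
        + math.atan(t_c + rh_pct)
        - math.atan(rh_pct - 1.676331)
        + 0.00391838 * rh_pct ** 1.5 * math.atan(0.023101 * rh_pct)
        - 4.686035
    )


def bolton_theta_e(t_c: float, e_kpa: float, p_kpa: float = 101.325) -> float:
    """Bolton (1980) equivalent potential temperature (K)."""
    tk = t_c + 273.15
    e_hpa, p_hpa = e_kpa * 10.0, p_kpa * 10.0
    r = 0.622 * e_hpa / (p_hpa - e_hpa)
    t_lcl = 2840.0 / (3.5 * math.log(tk) - math.log(e_hpa) - 4.805) + 55.0
    theta_dl = tk * (1000.0 / p_hpa) ** (0.2854 * (1.0 - 0.28 * r))
    return theta_dl * math.exp((3376.0 / t_lcl - 2.54) * r * (1.0 + 0.81 * r))


def kendall_tau_brute(x, y) -> float:
    """Tau-b by exhaustive O(n^2) pair counting with tie correction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    conc = disc = ties_x = ties_y = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx, dy = x[i] - x[j], y[i] - y[j]
            if dx == 0 and dy == 0:
                continue
            if dx == 0:
                ties_x += 1
            elif dy == 0:
                ties_y += 1
            elif dx * dy > 0:
                conc += 1
            else:
                disc += 1
    n0 = n * (n - 1) // 2
    denom = math.sqrt((n0 - _tie_term(x)) * (n0 - _tie_term(y)))
    return (conc - disc) / denom


def _tie_term(v: np.ndarray) -> float:
    _, counts = np.unique(v, return_counts=True)
    return float(sum(c * (c - 1) // 2 for c in counts))


def spearman_via_ranks(x, y) -> float:
    """Spearman's rho as Pearson correlation of average ranks."""
    from scipy.stats import rankdata

    rx, ry = rankdata(x), rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


@pytest.fixture(scope="session")
def test_lattice():
    """Coarse T x h lattice spanning the supported domain."""
    return (
        np.arange(-10.0, 55.1, 5.0),
        np.arange(1.0, 100.1, 9.0),
    )
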