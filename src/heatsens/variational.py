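"""Marginal temperature-equivalent sensitivity analysis.

Heat stress indices live on mutually incomparable scales, but the
*gradient of their isopleths* in temperature-humidity space does not:
the marginal temperature-equivalent change

    M = (dU/dT) / (dU/dh)        [% RH per degC]

is the change in relative humidity that moves an index U by the same
amount as a 1 degC change in temperature.  M can be compared freely
between indices at the same atmospheric state, and the difference in M
between two indices says which of them weights humidity more heavily.

This module computes the finite-difference partials, M, differences in M
between indices, M over temperature-humidity grids (with validity and
climate-envelope masking), traced isopleths, and per-regime summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import measure

from .indices import IndexEvaluator
from .psychro import AirState

__all__ = [
    "FDScheme",
    "FDResult",
    "MValue",
    "MField",
    "Isopleth",
    "MASK_VALID",
    "MASK_INDEX_UNDEFINED",
    "MASK_M_INFINITE",
    "MASK_OUTSIDE_ENVELOPE",
    "MASK_ENVELOPE_NO_DATA",
    "MASK_NAMES",
    "REGIMES",
    "partial_t",
    "partial_h",
    "marginal_m",
    "delta_m",
    "m_grid",
    "trace_isopleth",
    "evaluate_along",
    "regime_summary",
    "default_axes",
]

# Canonical regime points (degC, % RH) used in the per-regime summaries.
REGIMES: dict[str, tuple[float, float]] = {
    "low_temperature": (20.0, 50.0),
    "hot_humid": (35.0, 80.0),
    "hot_dry": (40.0, 20.0),
}

MASK_VALID = 0
MASK_INDEX_UNDEFINED = 1
MASK_M_INFINITE = 2
MASK_OUTSIDE_ENVELOPE = 3
MASK_ENVELOPE_NO_DATA = 4
MASK_NAMES = {
    MASK_VALID: "VALID",
    MASK_INDEX_UNDEFINED: "INDEX_UNDEFINED",
    MASK_M_INFINITE: "M_INFINITE",
    MASK_OUTSIDE_ENVELOPE: "OUTSIDE_ENVELOPE",
    MASK_ENVELOPE_NO_DATA: "ENVELOPE_NO_DATA",
}

#: Tolerance (index units) within which traced isopleth points must
#: re-evaluate to the requested level on the default grid.
ISOPLETH_TOL = 0.05


@dataclass(frozen=True)
class FDScheme:
    """Finite-difference scheme for the partials behind M.

    Steps default to 0.1 degC / 0.1 % RH: small enough for first-order
    accuracy on these smooth indices, two orders of magnitude above the
    0.01 degC wet-bulb solver tolerance so iteration noise does not
    corrupt the differences.  ``forward`` is the default mode; ``central``
    exists as a consistency oracle.
    """

    delta_t: float = 0.1
    delta_h: float = 0.1
    mode: str = "forward"

    def __post_init__(self) -> None:
        if not (0.0 < self.delta_t <= 1.0 and 0.0 < self.delta_h <= 1.0):
            raise ValueError("steps must lie in (0, 1]")
        if self.mode not in ("forward", "central"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass(frozen=True)
class FDResult:
    """A finite-difference partial, with defined/boundary bookkeeping."""

    value: float
    defined: bool = True
    reason: str | None = None
    boundary: bool = False  # true when a backward step replaced forward

    @staticmethod
    def undefined(reason: str) -> "FDResult":
        return FDResult(math.nan, defined=False, reason=reason)


@dataclass(frozen=True)
class MValue:
    """A marginal temperature-equivalent change (% RH per degC).

    An index that is locally humidity-flat has a genuinely infinite M;
    that is reported as ``infinite=True`` with ``value = inf`` rather
    than as an error so grids render instead of crashing.
    """

    value: float
    defined: bool = True
    infinite: bool = False
    reason: str | None = None

    @property
    def finite(self) -> bool:
        return self.defined and not self.infinite

    @staticmethod
    def undefined(reason: str) -> "MValue":
        return MValue(math.nan, defined=False, reason=reason)


def _eval(index: IndexEvaluator, state: AirState):
    return index(state)


def partial_t(index: IndexEvaluator, state: AirState, scheme: FDScheme = FDScheme()) -> FDResult:
    """Partial derivative of the index with respect to temperature.

    Forward mode: (U(T+dT, h) - U(T, h)) / dT.  Central mode uses the
    symmetric stencil.  Any undefined stencil point makes the result
    undefined, carrying the index's reason code.
    """
    dt = scheme.delta_t
    if scheme.mode == "central":
        lo, hi = _eval(index, state.shift(dt=-dt)), _eval(index, state.shift(dt=dt))
        if not (lo.defined and hi.defined):
            return FDResult.undefined((lo if not lo.defined else hi).reason or "UNDEFINED")
        return FDResult((hi.value - lo.value) / (2.0 * dt))
    u0, u1 = _eval(index, state), _eval(index, state.shift(dt=dt))
    if not (u0.defined and u1.defined):
        return FDResult.undefined((u0 if not u0.defined else u1).reason or "UNDEFINED")
    return FDResult((u1.value - u0.value) / dt)


def partial_h(index: IndexEvaluator, state: AirState, scheme: FDScheme = FDScheme()) -> FDResult:
    """Partial derivative of the index with respect to relative humidity.

    At the h = 100 % boundary a forward step would supersaturate, so a
    backward step is taken instead and flagged (``boundary=True``); the
    same applies to central mode at either edge of [0, 100].
    """
    dh = scheme.delta_h
    h = state.rh_pct
    if scheme.mode == "central" and h - dh >= 0.0 and h + dh <= 100.0:
        lo, hi = _eval(index, state.shift(dh=-dh)), _eval(index, state.shift(dh=dh))
        if not (lo.defined and hi.defined):
            return FDResult.undefined((lo if not lo.defined else hi).reason or "UNDEFINED")
        return FDResult((hi.value - lo.value) / (2.0 * dh))
    if h + dh <= 100.0:
        u0, u1 = _eval(index, state), _eval(index, state.shift(dh=dh))
        boundary = scheme.mode == "central"  # central fell back to one-sided
        if not (u0.defined and u1.defined):
            return FDResult.undefined((u0 if not u0.defined else u1).reason or "UNDEFINED")
        return FDResult((u1.value - u0.value) / dh, boundary=boundary)
    # backward step at the saturation boundary
    u0, u1 = _eval(index, state.shift(dh=-dh)), _eval(index, state)
    if not (u0.defined and u1.defined):
        return FDResult.undefined((u0 if not u0.defined else u1).reason or "UNDEFINED")
    return FDResult((u1.value - u0.value) / dh, boundary=True)


def marginal_m(index: IndexEvaluator, state: AirState, scheme: FDScheme = FDScheme()) -> MValue:
    """Marginal temperature-equivalent change M = (dU/dT)/(dU/dh).

    Units: % RH per degC.  A zero humidity partial (humidity-insensitive
    index) yields the infinite-M sentinel, flagged but not erroneous.
    """
    pt = partial_t(index, state, scheme)
    if not pt.defined:
        return MValue.undefined(pt.reason or "UNDEFINED")
    ph = partial_h(index, state, scheme)
    if not ph.defined:
        return MValue.undefined(ph.reason or "UNDEFINED")
    if ph.value == 0.0:
        return MValue(math.inf, infinite=True, reason="M_INFINITE")
    return MValue(pt.value / ph.value)


def delta_m(
    index_a: IndexEvaluator,
    index_b: IndexEvaluator,
    state: AirState,
    scheme: FDScheme = FDScheme(),
) -> MValue:
    """Difference in M between two indices, M_a - M_b, at one state.

    Antisymmetric under operand swap.  Undefined (with reason) if either
    M is undefined or infinite.
    """
    ma = marginal_m(index_a, state, scheme)
    mb = marginal_m(index_b, state, scheme)
    for m, tag in ((ma, "A"), (mb, "B")):
        if not m.defined:
            return MValue.undefined(f"{tag}:{m.reason}")
        if m.infinite:
            return MValue.undefined(f"{tag}:M_INFINITE")
    return MValue(ma.value - mb.value)


def default_axes() -> tuple[np.ndarray, np.ndarray]:
    """Default grid: T 0..50 degC step 0.5, h 1..100 % step 1."""
    return (
        np.arange(0.0, 50.0 + 1e-9, 0.5),
        np.arange(1.0, 100.0 + 1e-9, 1.0),
    )


@dataclass
class MField:
    """Grid of M values for one index over a T x h lattice.

    ``values[i, j]`` is M at ``(t_axis[i], h_axis[j])``; ``mask`` carries
    per-cell codes distinguishing an undefined index, an infinite M and
    conditions outside the climate envelope so each can be rendered
    (hatched) differently.
    """

    t_axis: np.ndarray
    h_axis: np.ndarray
    values: np.ndarray
    mask: np.ndarray
    index_name: str

    def __post_init__(self) -> None:
        if np.any(np.diff(self.t_axis) <= 0) or np.any(np.diff(self.h_axis) <= 0):
            raise ValueError("axes must be strictly increasing")

    def mask_counts(self) -> dict[str, int]:
        return {
            name: int(np.sum(self.mask == code)) for code, name in MASK_NAMES.items()
        }

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: t_c, rh_pct, index, m_pct_per_degc, mask_code."""
        tt, hh = np.meshgrid(self.t_axis, self.h_axis, indexing="ij")
        return pd.DataFrame(
            {
                "t_c": tt.ravel(),
                "rh_pct": hh.ravel(),
                "index": self.index_name,
                "m_pct_per_degc": self.values.ravel(),
                "mask_code": [MASK_NAMES[c] for c in self.mask.ravel()],
            }
        )


def m_grid(
    index: IndexEvaluator,
    t_axis: np.ndarray | None = None,
    h_axis: np.ndarray | None = None,
    scheme: FDScheme = FDScheme(),
    envelope=None,
    index_name: str = "",
    wind_ms: float = 0.5,
    p_kpa: float = 101.325,
) -> MField:
    """Compute M at every cell of a T x h lattice.

    Cells are masked (value NaN) where the index is undefined at the
    stencil, where M is infinite, or where the optional climate envelope
    excludes the condition; each case carries a distinct code.
    """
    if t_axis is None or h_axis is None:
        dt, dh = default_axes()
        t_axis = dt if t_axis is None else np.asarray(t_axis, dtype=float)
        h_axis = dh if h_axis is None else np.asarray(h_axis, dtype=float)
    t_axis = np.asarray(t_axis, dtype=float)
    h_axis = np.asarray(h_axis, dtype=float)
    if t_axis.size == 0 or h_axis.size == 0:
        raise ValueError("grid axes must be non-empty")

    values = np.full((t_axis.size, h_axis.size), np.nan)
    mask = np.zeros(values.shape, dtype=np.int8)
    for i, t in enumerate(t_axis):
        for j, h in enumerate(h_axis):
            state = AirState(float(t), float(h), wind_ms=wind_ms, p_kpa=p_kpa)
            if envelope is not None:
                status = envelope.classify(state)
                if status == "no_data":
                    mask[i, j] = MASK_ENVELOPE_NO_DATA
                    continue
                if status == "exceeds":
                    mask[i, j] = MASK_OUTSIDE_ENVELOPE
                    continue
            m = marginal_m(index, state, scheme)
            if not m.defined:
                mask[i, j] = MASK_INDEX_UNDEFINED
            elif m.infinite:
                mask[i, j] = MASK_M_INFINITE
            else:
                values[i, j] = m.value
    return MField(t_axis, h_axis, values, mask, index_name)


@dataclass
class Isopleth:
    """Ordered polyline(s) along which an index equals a fixed level.

    Each branch is an (n, 2) array of (t_c, rh_pct) points oriented so
    relative humidity is monotone from first to last point.  ``empty`` is
    true when the level was never bracketed on the grid.
    """

    index_name: str
    level: float
    branches: list[np.ndarray] = field(default_factory=list)

    @property
    def empty(self) -> bool:
        return not self.branches

    @property
    def points(self) -> np.ndarray:
        """All points of all branches, stacked in branch order."""
        if self.empty:
            return np.empty((0, 2))
        return np.vstack(self.branches)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for b, branch in enumerate(self.branches):
            for k, (t, h) in enumerate(branch):
                rows.append((self.index_name, self.level, b, k, t, h))
        return pd.DataFrame(
            rows,
            columns=["index", "level", "branch_id", "point_order", "t_c", "rh_pct"],
        )


def trace_isopleth(
    index: IndexEvaluator,
    level: float,
    t_axis: np.ndarray,
    h_axis: np.ndarray,
    wind_ms: float = 0.5,
    p_kpa: float = 101.325,
    index_name: str = "",
) -> Isopleth:
    """Trace the level set of an index by marching squares.

    The index is evaluated on the grid (undefined cells become NaN and
    are skipped by the contour finder), and contour points are linearly
    interpolated along cell edges, so every returned point re-evaluates
    to the level within interpolation tolerance.  Multiple disjoint
    branches are allowed; an unbracketed level gives an empty, flagged
    result.
    """
    t_axis = np.asarray(t_axis, dtype=float)
    h_axis = np.asarray(h_axis, dtype=float)
    grid = np.full((t_axis.size, h_axis.size), np.nan)
    for i, t in enumerate(t_axis):
        for j, h in enumerate(h_axis):
            v = index(AirState(float(t), float(h), wind_ms=wind_ms, p_kpa=p_kpa))
            if v.defined:
                grid[i, j] = v.value
    contours = measure.find_contours(grid, level)
    branches: list[np.ndarray] = []
    for c in contours:
        t_pts = np.interp(c[:, 0], np.arange(t_axis.size), t_axis)
        h_pts = np.interp(c[:, 1], np.arange(h_axis.size), h_axis)
        branch = np.column_stack([t_pts, h_pts])
        if branch.shape[0] < 2:
            continue
        if branch[-1, 1] < branch[0, 1]:
            branch = branch[::-1]
        branches.append(branch)
    return Isopleth(index_name=index_name, level=level, branches=branches)


def evaluate_along(
    isopleth: Isopleth,
    other_index: IndexEvaluator,
    wind_ms: float = 0.5,
    p_kpa: float = 101.325,
) -> pd.DataFrame:
    """Evaluate another index at each point of a traced isopleth.

    Returns a frame with columns t_c, rh_pct, value, defined; undefined
    points carry NaN and are excluded from any min/max summary.
    """
    rows = []
    for t, h in isopleth.points:
        v = other_index(AirState(float(t), float(h), wind_ms=wind_ms, p_kpa=p_kpa))
        rows.append((t, h, v.value if v.defined else np.nan, v.defined))
    return pd.DataFrame(rows, columns=["t_c", "rh_pct", "value", "defined"])


def regime_summary(
    indices: dict[str, IndexEvaluator],
    scheme: FDScheme = FDScheme(),
    wind_ms: float = 0.5,
    p_kpa: float = 101.325,
) -> pd.DataFrame:
    """M for every index at the three canonical regime points.

    Regimes: low-temperature (20 degC, 50 %), hot-humid (35 degC, 80 %),
    hot-dry (40 degC, 20 %).  Returns a long frame with columns index,
    regime, t_c, rh_pct, m_pct_per_degc, defined, infinite.
    """
    rows = []
    for name, evaluator in indices.items():
        for regime, (t, h) in REGIMES.items():
            state = AirState(t, h, wind_ms=wind_ms, p_kpa=p_kpa)
            m = marginal_m(evaluator, state, scheme)
            rows.append((name, regime, t, h, m.value, m.defined, m.infinite))
    return pd.DataFrame(
        rows,
        columns=[
            "index", "regime", "t_c", "rh_pct",
            "m_pct_per_degc", "defined", "infinite",
        ],
    )
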