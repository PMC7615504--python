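"""Present-climate envelope: per-humidity maximum co-occurring temperature.

Not every point of a temperature-humidity grid corresponds to conditions
that actually occur: very hot and very humid air at once is (so far)
rare.  A :class:`ClimateEnvelope` records, per relative-humidity bin, the
maximum dry-bulb temperature observed to co-occur with that humidity, so
grid computations can hatch never-observed conditions.

The envelope can be built from any (T, h) observation sequence (e.g. a
reanalysis scan), loaded from CSV, or generated synthetically.  The
synthetic stand-in caps conditions at a wet-bulb temperature of 31 degC
— about the highest value occurring in the present climate — plus a hard
dry-bulb cap, which reproduces the qualitative shape of a
reanalysis-derived envelope (hot-humid corner excluded, hot-dry corner
admitted) without any data download.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .indices import wbt
from .psychro import AirState

__all__ = [
    "ClimateEnvelope",
    "build_envelope",
    "synthetic_envelope",
    "load_envelope",
    "save_envelope",
]


@dataclass
class ClimateEnvelope:
    """Per-RH-bin maximum co-occurring temperature.

    Bins partition (0, 100] % into equal widths; ``t_max[i]`` is the
    maximum temperature for the bin with upper edge ``bin_upper[i]``.
    NaN marks a bin with no observations; such bins are conservatively
    treated as outside the climate (flagged distinctly from exceedance).
    """

    bin_upper: np.ndarray  # upper edges, last one = 100.0
    t_max: np.ndarray      # degC; NaN = no data
    provenance: str = ""

    def __post_init__(self) -> None:
        self.bin_upper = np.asarray(self.bin_upper, dtype=float)
        self.t_max = np.asarray(self.t_max, dtype=float)
        if self.bin_upper.size != self.t_max.size:
            raise ValueError("bin_upper and t_max must have equal length")
        widths = np.diff(np.concatenate([[0.0], self.bin_upper]))
        if not np.allclose(widths, widths[0]) or not math.isclose(
            self.bin_upper[-1], 100.0
        ):
            raise ValueError("bins must uniformly cover (0, 100]")

    @property
    def bin_width(self) -> float:
        return float(self.bin_upper[0])

    def _bin_index(self, rh_pct: float) -> int:
        if rh_pct <= 0.0:
            return 0
        return min(
            int(math.ceil(rh_pct / self.bin_width)) - 1, self.bin_upper.size - 1
        )

    def classify(self, state: AirState) -> str:
        """'inside', 'exceeds', or 'no_data' for the state's humidity bin."""
        tm = self.t_max[self._bin_index(state.rh_pct)]
        if math.isnan(tm):
            return "no_data"
        return "inside" if state.t_c <= tm else "exceeds"

    def contains(self, state: AirState) -> bool:
        """True iff the state's temperature is within its bin's maximum.

        The upper bound is closed (T equal to the bin maximum is inside);
        bins with no data are outside.
        """
        return self.classify(state) == "inside"


def build_envelope(
    observations, bin_width: float = 1.0, provenance: str = "observations"
) -> ClimateEnvelope:
    """Build an envelope as the per-bin maximum temperature.

    ``observations`` is a sequence of (T degC, h %) pairs; ``bin_width``
    must divide 100.  Bins that receive no observations are marked
    no-data.  The result is invariant to observation order.
    """
    obs = np.asarray(list(observations), dtype=float)
    if obs.size == 0:
        raise ValueError("observations must be non-empty")
    n_bins = 100.0 / bin_width
    if not math.isclose(n_bins, round(n_bins)):
        raise ValueError(f"bin_width={bin_width} does not divide 100")
    n_bins = int(round(n_bins))
    upper = bin_width * np.arange(1, n_bins + 1)
    t_max = np.full(n_bins, np.nan)
    for t, h in obs:
        if not 0.0 <= h <= 100.0:
            raise ValueError(f"observation humidity {h} outside [0, 100]")
        i = 0 if h <= 0.0 else min(int(math.ceil(h / bin_width)) - 1, n_bins - 1)
        if math.isnan(t_max[i]) or t > t_max[i]:
            t_max[i] = t
    return ClimateEnvelope(upper, t_max, provenance=provenance)


def synthetic_envelope(
    t_cap: float = 55.0, wbt_cap: float = 31.0, bin_width: float = 1.0
) -> ClimateEnvelope:
    """Synthetic stand-in for a reanalysis-derived climate envelope.

    Per bin (evaluated at its upper humidity edge), the maximum
    temperature is the lesser of a hard dry-bulb cap and the temperature
    at which the wet-bulb temperature reaches ``wbt_cap``, found by
    root-finding on the WBT evaluator.  Dry bins are rarely WBT-limited
    and stay at the dry-bulb cap.  The result is monotone non-increasing
    in humidity.
    """
    if t_cap <= 0.0 or wbt_cap <= 0.0:
        raise ValueError("caps must be positive")
    n_bins = 100.0 / bin_width
    if not math.isclose(n_bins, round(n_bins)):
        raise ValueError(f"bin_width={bin_width} does not divide 100")
    n_bins = int(round(n_bins))
    upper = bin_width * np.arange(1, n_bins + 1)
    t_max = np.empty(n_bins)

    def excess(t: float, h: float) -> float:
        return wbt(AirState(t, h)).value - wbt_cap

    for i, h in enumerate(upper):
        if excess(t_cap, float(h)) <= 0.0:
            t_max[i] = t_cap  # WBT never reaches the cap below t_cap
        else:
            t_max[i] = brentq(excess, wbt_cap, t_cap, args=(float(h),), xtol=1e-3)
    # WBT increases with humidity at fixed T, so the limiting temperature
    # must fall with humidity; enforce against solver round-off.
    t_max = np.minimum.accumulate(t_max)
    return ClimateEnvelope(
        upper, t_max, provenance=f"synthetic-v1(t_cap={t_cap},wbt_cap={wbt_cap})"
    )


def save_envelope(env: ClimateEnvelope, path) -> None:
    """Serialize to CSV with columns rh_bin_upper_pct, t_max_c.

    No-data bins are written as an empty field.
    """
    df = pd.DataFrame(
        {"rh_bin_upper_pct": env.bin_upper, "t_max_c": env.t_max}
    )
    df.to_csv(path, index=False)


def load_envelope(path) -> ClimateEnvelope:
    """Load an envelope CSV written by :func:`save_envelope`.

    Malformed rows raise a parse error naming the offending line; empty
    ``t_max_c`` fields are restored as no-data bins.
    """
    df = pd.read_csv(path)
    for col in ("rh_bin_upper_pct", "t_max_c"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    upper = np.empty(len(df))
    t_max = np.empty(len(df))
    for row_number, (_, row) in enumerate(df.iterrows(), start=2):
        try:
            upper[row_number - 2] = float(row["rh_bin_upper_pct"])
        except (TypeError, ValueError):
            raise ValueError(
                f"{path}: line {row_number}: bad rh_bin_upper_pct "
                f"{row['rh_bin_upper_pct']!r}"
            ) from None
        raw = row["t_max_c"]
        if pd.isna(raw):
            t_max[row_number - 2] = np.nan
        else:
            try:
                t_max[row_number - 2] = float(raw)
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path}: line {row_number}: bad t_max_c {raw!r}"
                ) from None
    import os

    return ClimateEnvelope(upper, t_max, provenance=os.path.basename(str(path)))
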