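"""Scenario audit: does the index choice reverse the conclusion?

Land-surface interventions (irrigation, urban greening, soil-moisture
changes) typically cool the air while moistening it.  Whether such a
coupled (dT < 0, dq > 0) perturbation *raises* or *lowers* heat stress
depends on the index: an index that weights humidity heavily (WBT) can
move opposite to one that weights temperature heavily (UTCI) under the
very same perturbations.

This module applies coupled temperature / specific-humidity perturbations
to baseline states, computes the change in every index, rank-correlates
each against the humidity change (Kendall's tau-b and Spearman's rho),
and flags when two indices disagree in sign — the conclusion-reversal
phenomenon.  A seeded synthetic generator emulates the structure of
soil-moisture modelling experiments: hot, dry heatwave baselines with
anti-correlated temperature/moisture perturbations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .indices import REGISTRY, IndexEvaluator
from .psychro import (
    AirState,
    SupersaturationError,
    rh_from_specific_humidity,
    specific_humidity,
    STANDARD_PRESSURE_KPA,
)

__all__ = [
    "ScenarioRecord",
    "AuditResult",
    "perturb",
    "index_changes",
    "rank_correlations",
    "audit",
    "synthesize_soil_moisture_scenarios",
    "records_to_frame",
    "records_from_frame",
]


@dataclass(frozen=True)
class ScenarioRecord:
    """One baseline condition plus its coupled perturbation.

    ``dq_kgkg`` is a specific-humidity perturbation (kg/kg); ``dt_c`` a
    temperature perturbation (degC).
    """

    t0_c: float
    h0_pct: float
    dt_c: float
    dq_kgkg: float


def perturb(
    record: ScenarioRecord, p_kpa: float = STANDARD_PRESSURE_KPA
) -> tuple[AirState, AirState]:
    """Realize the baseline and perturbed states of a record.

    The perturbed state has temperature t0 + dt and specific humidity
    q(t0, h0, p) + dq, converted back to relative humidity at the
    perturbed temperature.  Raises :class:`SupersaturationError` (or
    ``DomainError`` for negative humidity) when the perturbed state is
    unphysical; callers flag and exclude such records.
    """
    base = AirState(record.t0_c, record.h0_pct, p_kpa=p_kpa)
    q1 = specific_humidity(record.t0_c, record.h0_pct, p_kpa) + record.dq_kgkg
    t1 = record.t0_c + record.dt_c
    rh1 = rh_from_specific_humidity(q1, t1, p_kpa)
    return base, AirState(t1, rh1, p_kpa=p_kpa)


def index_changes(
    records: list[ScenarioRecord],
    indices: dict[str, IndexEvaluator] | None = None,
    p_kpa: float = STANDARD_PRESSURE_KPA,
) -> pd.DataFrame:
    """Per-record, per-index changes index(perturbed) - index(baseline).

    Returns one row per record with columns ``dq_kgkg``, ``flagged``
    (unphysical perturbed state) and ``d_<INDEX>`` per index; a change is
    NaN unless the index is defined at both endpoint states.
    """
    if not records:
        raise ValueError("records must be non-empty")
    indices = dict(REGISTRY) if indices is None else indices
    rows = []
    for rid, rec in enumerate(records):
        row: dict = {"record_id": rid, "dq_kgkg": rec.dq_kgkg, "flagged": False}
        try:
            base, pert = perturb(rec, p_kpa)
        except ValueError:  # supersaturation / negative humidity
            row["flagged"] = True
            for name in indices:
                row[f"d_{name}"] = np.nan
            rows.append(row)
            continue
        for name, evaluator in indices.items():
            v0, v1 = evaluator(base), evaluator(pert)
            row[f"d_{name}"] = (
                v1.value - v0.value if (v0.defined and v1.defined) else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("record_id")


def rank_correlations(x, y) -> tuple[float, float]:
    """Kendall's tau-b and Spearman's rho between two sequences.

    Tau-b (tie-corrected) is used because modelled changes often tie
    after rounding.  Requires at least 3 pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("sequences must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs for rank correlations")
    tau = stats.kendalltau(x, y, variant="b").statistic
    rho = stats.spearmanr(x, y).statistic
    return float(tau), float(rho)


@dataclass
class AuditResult:
    """Outcome of a scenario audit.

    ``changes``: the per-record change table from :func:`index_changes`.
    ``correlations``: per-index frame with kendall_tau, spearman_rho,
    n_used, n_flagged and the sign of tau.  ``reversal_flag`` is true
    when any two indices have opposite-signed tau — the same scenarios
    would support opposite conclusions depending on the index chosen.
    """

    changes: pd.DataFrame
    correlations: pd.DataFrame
    reversal_flag: bool

    def summary_dict(self) -> dict:
        return {
            "reversal_flag": bool(self.reversal_flag),
            "indices": {
                name: {
                    "kendall_tau": None
                    if pd.isna(row["kendall_tau"])
                    else float(row["kendall_tau"]),
                    "spearman_rho": None
                    if pd.isna(row["spearman_rho"])
                    else float(row["spearman_rho"]),
                    "n_used": int(row["n_used"]),
                    "n_flagged": int(row["n_flagged"]),
                }
                for name, row in self.correlations.iterrows()
            },
        }


def audit(
    records: list[ScenarioRecord],
    indices: dict[str, IndexEvaluator] | None = None,
    p_kpa: float = STANDARD_PRESSURE_KPA,
) -> AuditResult:
    """Rank-correlate each index's change against the humidity change.

    Records with unphysical perturbations, and records where an index is
    undefined at either endpoint, are excluded from that index's
    correlation and counted.  Correlations with fewer than 3 usable pairs
    are reported as NaN.
    """
    changes = index_changes(records, indices, p_kpa)
    names = [c[2:] for c in changes.columns if c.startswith("d_")]
    n = len(changes)
    rows = []
    taus = {}
    for name in names:
        valid = changes[f"d_{name}"].notna()
        used = changes[valid]
        if len(used) >= 3:
            tau, rho = rank_correlations(used["dq_kgkg"], used[f"d_{name}"])
        else:
            tau = rho = float("nan")
        taus[name] = tau
        rows.append(
            {
                "index": name,
                "kendall_tau": tau,
                "spearman_rho": rho,
                "tau_sign": 0 if (math.isnan(tau) or tau == 0) else int(math.copysign(1, tau)),
                "n_used": len(used),
                "n_flagged": n - len(used),
            }
        )
    corr = pd.DataFrame(rows).set_index("index")
    signs = {s for s in corr["tau_sign"] if s != 0}
    return AuditResult(changes, corr, reversal_flag=len(signs) > 1)


def synthesize_soil_moisture_scenarios(
    n: int,
    seed: int,
    coupling: float = -0.7,
    noise_sd_c: float = 0.2,
) -> list[ScenarioRecord]:
    """Generate scenarios with the structure of soil-moisture experiments.

    Baselines are heatwave-like: T uniform on [30, 42] degC, h uniform on
    [15, 60] %.  Moisture perturbations dq are uniform on [-2, +2] g/kg,
    and temperature responds with the opposite sign:
    dt = coupling * dq_gkg + noise (sd ``noise_sd_c`` degC), with
    ``coupling`` in degC per g/kg, negative — wetter soil cools.
    Fully reproducible from the seed.
    """
    if n < 10:
        raise ValueError("n must be at least 10")
    if not coupling < 0:
        raise ValueError("coupling must be negative (moistening cools)")
    rng = np.random.default_rng(seed)
    t0 = rng.uniform(30.0, 42.0, n)
    h0 = rng.uniform(15.0, 60.0, n)
    dq_gkg = rng.uniform(-2.0, 2.0, n)
    dt = coupling * dq_gkg + rng.normal(0.0, noise_sd_c, n)
    return [
        ScenarioRecord(float(t), float(h), float(d), float(q) / 1000.0)
        for t, h, d, q in zip(t0, h0, dt, dq_gkg)
    ]


def records_to_frame(records: list[ScenarioRecord]) -> pd.DataFrame:
    """Scenario CSV schema: t0_c, h0_pct, dt_c, dq_kgkg."""
    return pd.DataFrame(
        [(r.t0_c, r.h0_pct, r.dt_c, r.dq_kgkg) for r in records],
        columns=["t0_c", "h0_pct", "dt_c", "dq_kgkg"],
    )


def records_from_frame(df: pd.DataFrame) -> list[ScenarioRecord]:
    """Parse scenario records, naming the offending row on bad data."""
    for col in ("t0_c", "h0_pct", "dt_c", "dq_kgkg"):
        if col not in df.columns:
            raise ValueError(f"scenario table missing required column {col!r}")
    records = []
    for row_number, (_, row) in enumerate(df.iterrows(), start=2):
        try:
            records.append(
                ScenarioRecord(
                    float(row["t0_c"]),
                    float(row["h0_pct"]),
                    float(row["dt_c"]),
                    float(row["dq_kgkg"]),
                )
            )
        except (TypeError, ValueError):
            raise ValueError(f"scenario table: bad values at line {row_number}") from None
    return records
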