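"""Descriptive performance computations for the challenge trial.

Splits each 15-d period into the prechallenge ([-3, 0)), challenge
([0, 5)) and recovery ([5, 12)) intervals, pools treatment groups into
the period-specific analysis pools, and computes per-pool ADFI, ADG and
feed:gain together with percent-change summaries and metabolic-weight
scaling.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .cohort import METABOLIC_EXPONENT, PERIODS, StudyDataset

__all__ = [
    "INTERVALS",
    "assign_pools",
    "interval_performance",
    "percent_change",
    "metabolic_scale",
    "daily_average",
    "study_summary",
]

#: half-open day intervals within each period
INTERVALS = ((-3, 0), (0, 5), (5, 12))

_POOLS = {
    "P1": {"TTT": "T", "THT": "T", "TTH": "T", "HTT": "H", "HHH": "H"},
    "P2": {"TTT": "TT&HT", "TTH": "TT&HT", "HTT": "TT&HT", "THT": "TH", "HHH": "HH"},
    "P3": {"TTT": "TTT&HTT&THT", "HTT": "TTT&HTT&THT", "THT": "TTT&HTT&THT",
           "TTH": "TTH", "HHH": "HHH"},
}


def assign_pools(period: str) -> dict[str, str]:
    """Treatment-group -> analysis-pool mapping for one period.

    Unchallenged groups are pooled; groups with distinct challenge
    histories are kept separate (e.g. in P3 the first-challenge TTH and
    the thrice-challenged HHH each form their own pool).
    """
    if period not in _POOLS:
        raise ValueError(f"unknown period {period!r}; expected one of {PERIODS}")
    return dict(_POOLS[period])


def percent_change(pre_value: float, during_value: float, rounded: bool = False) -> float:
    """Percent decrease relative to the prechallenge value.

    Positive for decreases, i.e. 100*(pre - during)/pre.  With
    ``rounded`` the result is rounded to the nearest integer percent,
    halves away from zero (the convention used for reported summaries).
    """
    if not pre_value > 0:
        raise ValueError("prechallenge value must be > 0")
    pct = 100.0 * (pre_value - during_value) / pre_value
    if rounded:
        return float(math.floor(pct + 0.5) if pct >= 0 else math.ceil(pct - 0.5))
    return pct


def metabolic_scale(feed_g_d, bw_kg):
    """Scale feed intake to metabolic body size: g/d per kg^0.60."""
    bw = np.asarray(bw_kg, dtype=float)
    if np.any(bw <= 0):
        raise ValueError("body weight must be > 0")
    out = np.asarray(feed_g_d, dtype=float) / bw**METABOLIC_EXPONENT
    return float(out) if np.ndim(feed_g_d) == 0 and np.ndim(bw_kg) == 0 else out


def daily_average(
    records: pd.DataFrame, min_coverage: int = 1, time_column: str = "time"
) -> pd.DataFrame:
    """Collapse sub-daily sensor readings to daily means per animal.

    ``records`` needs columns ``animal_id``, ``time`` (datetime-like)
    and ``value``.  Days with fewer than ``min_coverage`` readings are
    kept but flagged ``low_coverage``.
    """
    f = records.copy()
    f[time_column] = pd.to_datetime(f[time_column])
    f["date"] = f[time_column].dt.normalize()
    out = (
        f.groupby(["animal_id", "date"], sort=True)["value"]
        .agg(value="mean", n_readings="count")
        .reset_index()
    )
    out["low_coverage"] = out["n_readings"] < min_coverage
    return out


def _bw_at(bw: pd.DataFrame, day: float):
    hit = bw.loc[np.isclose(bw["day"], day), "value"]
    return float(hit.iloc[0]) if len(hit) else None


def interval_performance(study: StudyDataset, period: str) -> pd.DataFrame:
    """Per-pool ADFI, ADG and F:G over the three intervals of one period.

    Feed is attributed to the day offered (half-open intervals on
    integer days); interval-boundary body weights come from the weigh
    days (-3, 0, 5) and the end-of-period weighing (day 12).  Animals
    with non-positive gain have their F:G flagged undefined and are
    excluded from the pool F:G mean.
    """
    pools = assign_pools(period)
    rec = study.records
    rec = rec[rec["period"] == period]
    rows = []
    for aid, sub in rec.groupby("animal_id"):
        group = sub["group"].iloc[0]
        pool = pools.get(group, group)  # unknown groups stand alone
        feed = sub[sub["variable"] == "ADFI_g_d"]
        bw = sub[sub["variable"] == "BW_kg"]
        for a, b in INTERVALS:
            fdays = feed[(feed["day"] >= a) & (feed["day"] < b)]
            adfi = float(fdays["value"].mean()) if len(fdays) else np.nan
            bw_a, bw_b = _bw_at(bw, a), _bw_at(bw, b)
            if bw_a is None or bw_b is None:
                rows.append((pool, aid, (a, b), adfi, np.nan, np.nan, True, True))
                continue
            gain_kg = bw_b - bw_a
            adg = 1000.0 * gain_kg / (b - a)
            total_feed_kg = float(fdays["value"].sum()) / 1000.0
            fg_undefined = gain_kg <= 0
            fg = np.nan if fg_undefined else total_feed_kg / gain_kg
            rows.append((pool, aid, (a, b), adfi, adg, fg, fg_undefined, False))
    per_animal = pd.DataFrame(
        rows,
        columns=["pool", "animal_id", "interval", "adfi_g_d", "adg_g_d",
                 "fg_kg_kg", "fg_undefined", "missing_bw"],
    )
    out = []
    for (pool, interval), sub in per_animal.groupby(["pool", "interval"], sort=False):
        out.append(
            {
                "period": period,
                "pool": pool,
                "interval_start": interval[0],
                "interval_end": interval[1],
                "n_animals": sub["animal_id"].nunique(),
                "adfi_g_d": sub["adfi_g_d"].mean(),
                "adg_g_d": sub["adg_g_d"].mean(),
                "fg_kg_kg": sub.loc[~sub["fg_undefined"], "fg_kg_kg"].mean(),
                "n_fg_undefined": int(sub["fg_undefined"].sum()),
                "flagged": bool(sub["missing_bw"].any()),
            }
        )
    summary = pd.DataFrame(out).sort_values(
        ["pool", "interval_start"], ignore_index=True
    )
    return summary


def study_summary(study: StudyDataset) -> pd.DataFrame:
    """Tidy performance table across all periods, pools and intervals."""
    return pd.concat(
        [interval_performance(study, p) for p in PERIODS], ignore_index=True
    )
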