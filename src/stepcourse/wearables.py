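"""Minute-level step streams -> daily summaries, cadence bouts, monthly exposures.

The processing chain mirrors standard wearable-device practice: a *valid day*
requires at least 10 clock hours containing nonzero step minutes and at least
100 total steps; cadence *bouts* are maximal runs of >=2 consecutive minutes at
or above a steps/minute threshold (60 = slow walking, 100 = moderate-to-vigorous);
months are consecutive 30-day blocks from each participant's monitoring start,
and a month is usable as a time-varying exposure only when it holds >=15 valid
days.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

MINUTES_PER_DAY = 1440
DAYS_PER_MONTH = 30

#: valid-day thresholds
MIN_WEAR_HOURS = 10
MIN_DAILY_STEPS = 100
#: months with fewer valid days than this are excluded from time-varying models
MIN_VALID_DAYS_PER_MONTH = 15
#: minimum monitoring span (months between first and last valid day) for inclusion
MIN_MONITORING_MONTHS = 6

CADENCE_SLOW = 60
CADENCE_MVPA = 100
MIN_BOUT_MINUTES = 2


@dataclass(frozen=True)
class Bout:
    """A maximal run of consecutive minutes at/above a cadence threshold."""

    start: int  # minute-of-day index, inclusive
    stop: int  # exclusive
    mean_cadence: float

    @property
    def n_minutes(self) -> int:
        return self.stop - self.start


def detect_bouts(minutes, cadence_threshold: float, min_len: int = MIN_BOUT_MINUTES) -> list[Bout]:
    """Find maximal runs of consecutive minutes with steps >= ``cadence_threshold``.

    Runs shorter than ``min_len`` minutes are discarded. Returned bouts are
    non-overlapping and ordered by start minute.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    if cadence_threshold <= 0:
        raise ValueError("cadence_threshold must be positive")
    x = np.asarray(minutes)
    if np.any(x < 0):
        raise ValueError("negative step counts")
    above = x >= cadence_threshold
    if not above.any():
        return []
    # run boundaries via sign changes of the indicator
    padded = np.concatenate(([False], above, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, stops = edges[::2], edges[1::2]
    out = []
    for s, e in zip(starts, stops):
        if e - s >= min_len:
            out.append(Bout(int(s), int(e), float(x[s:e].mean())))
    return out


def _bout_totals(minutes, threshold: float) -> tuple[int, int]:
    """(total bout minutes, total bout steps) at a cadence threshold."""
    bouts = detect_bouts(minutes, threshold)
    n_min = sum(b.n_minutes for b in bouts)
    n_steps = int(sum(b.mean_cadence * b.n_minutes for b in bouts))
    return n_min, n_steps


def wear_hours(minutes) -> int:
    """Count of distinct clock hours (00-23 buckets) containing >=1 nonzero minute.

    The input is a per-minute vector aligned to minute-of-day (length <= 1440).
    """
    x = np.asarray(minutes)
    n = len(x)
    if n > MINUTES_PER_DAY:
        raise ValueError("more than one day of minutes")
    hour = np.arange(n) // 60
    return int(len(np.unique(hour[x > 0])))


def summarize_day(minutes) -> dict:
    """Reduce one day's minute vector to total steps, wear time, bouts, validity.

    ``minutes`` is a length-<=1440 vector aligned to minute-of-day. A day is
    valid iff wear_hours >= 10 and total steps >= 100.
    """
    x = np.asarray(minutes)
    if np.any(x < 0):
        raise ValueError("negative step counts")
    wh = wear_hours(x)
    total = int(x.sum())
    bm60, bs60 = _bout_totals(x, CADENCE_SLOW)
    bm100, bs100 = _bout_totals(x, CADENCE_MVPA)
    return {
        "total_steps": total,
        "wear_hours": wh,
        "bout_min_60": bm60,
        "bout_steps_60": bs60,
        "bout_min_100": bm100,
        "bout_steps_100": bs100,
        "is_valid": bool(wh >= MIN_WEAR_HOURS and total >= MIN_DAILY_STEPS),
    }


def summarize_days(stream: pd.DataFrame, monitoring_start=None) -> pd.DataFrame:
    """Roll a long minute-level stream up to one row per participant-day.

    ``stream`` has columns participant_id, timestamp (datetime64), steps.
    ``monitoring_start`` maps participant -> first monitored timestamp; by
    default each participant's first observed day is day 0.
    """
    df = stream
    if df["steps"].lt(0).any():
        raise ValueError("negative step counts")
    ts = pd.to_datetime(df["timestamp"])
    date = ts.dt.normalize()
    if monitoring_start is None:
        start = date.groupby(df["participant_id"]).transform("min")
    else:
        start = df["participant_id"].map(monitoring_start).pipe(pd.to_datetime).dt.normalize()
    day = (date - start).dt.days
    minute_of_day = ts.dt.hour * 60 + ts.dt.minute
    work = pd.DataFrame(
        {
            "participant_id": df["participant_id"].to_numpy(),
            "day": day.to_numpy(),
            "minute": minute_of_day.to_numpy(),
            "steps": df["steps"].to_numpy(),
        }
    )
    rows = []
    for (pid, d), grp in work.groupby(["participant_id", "day"], sort=True):
        vec = np.zeros(MINUTES_PER_DAY, dtype=np.int64)
        np.add.at(vec, grp["minute"].to_numpy(), grp["steps"].to_numpy())
        row = summarize_day(vec)
        row["participant_id"] = pid
        row["day"] = int(d)
        rows.append(row)
    cols = [
        "participant_id",
        "day",
        "total_steps",
        "wear_hours",
        "bout_min_60",
        "bout_steps_60",
        "bout_min_100",
        "bout_steps_100",
        "is_valid",
    ]
    return pd.DataFrame(rows)[cols]


def monthly_exposures(daily: pd.DataFrame) -> pd.DataFrame:
    """Bin one participant's daily summaries into 30-day months.

    Returns one row per month index from 0 through the last observed month:
    mean_steps and mean_wear_hours over *valid* days only, n_valid_days,
    is_valid_month (>=15 valid days) and running_mean_steps, the valid-day
    weighted mean of all valid days through the end of that month.
    """
    if len(daily) == 0:
        raise ValueError("empty daily summary table")
    d = daily.copy()
    d["month"] = d["day"] // DAYS_PER_MONTH
    n_months = int(d["month"].max()) + 1
    idx = pd.RangeIndex(n_months, name="month")
    valid = d[d["is_valid"]]
    g = valid.groupby("month")
    out = pd.DataFrame(index=idx)
    out["mean_steps"] = g["total_steps"].mean().reindex(idx)
    out["n_valid_days"] = g.size().reindex(idx, fill_value=0).astype(int)
    out["mean_wear_hours"] = g["wear_hours"].mean().reindex(idx)
    out["is_valid_month"] = out["n_valid_days"] >= MIN_VALID_DAYS_PER_MONTH
    cum_steps = g["total_steps"].sum().reindex(idx, fill_value=0).cumsum()
    cum_days = out["n_valid_days"].cumsum()
    out["running_mean_steps"] = np.where(cum_days > 0, cum_steps / cum_days.replace(0, 1), np.nan)
    return out.reset_index()


def monthly_exposures_all(daily_all: pd.DataFrame) -> dict:
    """Vectorized ``monthly_exposures`` for a multi-participant daily table.

    Returns {participant_id: monthly frame}, identical to calling
    ``monthly_exposures`` per participant but in one pass.
    """
    if len(daily_all) == 0:
        raise ValueError("empty daily summary table")
    d = daily_all[["participant_id", "day", "total_steps", "wear_hours", "is_valid"]].copy()
    d["month"] = d["day"] // DAYS_PER_MONTH
    nmax = d.groupby("participant_id")["month"].max()
    pids = nmax.index.to_numpy()
    full = pd.DataFrame(
        {
            "participant_id": np.repeat(pids, nmax.to_numpy() + 1),
            "month": np.concatenate([np.arange(m + 1) for m in nmax.to_numpy()]),
        }
    )
    val = d[d["is_valid"]]
    g = (
        val.groupby(["participant_id", "month"])
        .agg(
            step_sum=("total_steps", "sum"),
            n_valid_days=("total_steps", "size"),
            wear_sum=("wear_hours", "sum"),
        )
        .reset_index()
    )
    full = full.merge(g, on=["participant_id", "month"], how="left")
    full[["step_sum", "n_valid_days", "wear_sum"]] = full[
        ["step_sum", "n_valid_days", "wear_sum"]
    ].fillna(0)
    full["n_valid_days"] = full["n_valid_days"].astype(int)
    n = full["n_valid_days"].to_numpy()
    full["mean_steps"] = np.where(n > 0, full["step_sum"] / np.maximum(n, 1), np.nan)
    full["mean_wear_hours"] = np.where(n > 0, full["wear_sum"] / np.maximum(n, 1), np.nan)
    full["is_valid_month"] = n >= MIN_VALID_DAYS_PER_MONTH
    gp = full.groupby("participant_id")
    csum = gp["step_sum"].cumsum()
    cn = gp["n_valid_days"].cumsum()
    full["running_mean_steps"] = np.where(cn > 0, csum / cn.replace(0, 1), np.nan)
    cols = [
        "month",
        "mean_steps",
        "n_valid_days",
        "mean_wear_hours",
        "is_valid_month",
        "running_mean_steps",
    ]
    return {p: grp[cols].reset_index(drop=True) for p, grp in full.groupby("participant_id")}


def window_average(daily: pd.DataFrame, start_month: float, end_month: float) -> float:
    """Mean daily steps over valid days with start_month <= day/30 < end_month.

    NaN when the window holds no valid days.
    """
    if end_month <= start_month:
        raise ValueError("inverted window")
    sel = daily[
        daily["is_valid"]
        & (daily["day"] >= start_month * DAYS_PER_MONTH)
        & (daily["day"] < end_month * DAYS_PER_MONTH)
    ]
    if len(sel) == 0:
        return float("nan")
    return float(sel["total_steps"].mean())


def intensity_summary(daily: pd.DataFrame) -> dict:
    """Pooled mean bout cadence over all valid days, at both thresholds.

    Cadence is time-weighted: total bout steps / total bout minutes across
    valid days (not the mean of per-bout means). NaN when no bout minutes.
    """
    valid = daily[daily["is_valid"]]
    if len(valid) == 0:
        raise ValueError("no valid days")
    out = {}
    for thr in (60, 100):
        m = valid[f"bout_min_{thr}"].sum()
        s = valid[f"bout_steps_{thr}"].sum()
        out[f"c{thr}"] = float(s / m) if m > 0 else float("nan")
    return out


def participant_spans(daily_all: pd.DataFrame) -> pd.DataFrame:
    """Per-participant monitoring span in months between first and last valid day."""
    valid = daily_all[daily_all["is_valid"]]
    g = valid.groupby("participant_id")["day"]
    span = (g.max() - g.min()) / DAYS_PER_MONTH
    return span.rename("span_months").reset_index()


def filter_participants(daily_all: pd.DataFrame, min_months: float = MIN_MONITORING_MONTHS):
    """Keep participants with >= ``min_months`` between first and last valid day.

    Returns (filtered daily table, flow counts dict) where the counts record
    how many participants and days each exclusion removed.
    """
    n0 = daily_all["participant_id"].nunique()
    days0 = len(daily_all)
    spans = participant_spans(daily_all)
    keep = set(spans.loc[spans["span_months"] >= min_months, "participant_id"])
    out = daily_all[daily_all["participant_id"].isin(keep)]
    flow = {
        "participants_in": n0,
        "participants_kept": len(keep),
        "participants_excluded_short_span": n0 - len(keep),
        "days_in": days0,
        "days_kept": len(out),
        "pct_days_invalid_low_steps": float(
            100.0 * (daily_all["total_steps"] < MIN_DAILY_STEPS).mean()
        ),
    }
    return out, flow


@dataclass
class VolumeIntensityResult:
    rho: float
    p: float
    n: int
    crosstab: pd.DataFrame | None = None


def correlate_volume_intensity(
    person_table: pd.DataFrame,
    steps_col: str = "mean_steps",
    cadence_col: str = "c60",
    event_col: str | None = None,
) -> VolumeIntensityResult:
    """Spearman correlation of person-level step volume vs bout cadence.

    Pairwise-complete observations; with an event column the quartile
    cross-tab of volume x cadence carries per-cell incident rates, otherwise
    cell counts.
    """
    d = person_table[[steps_col, cadence_col] + ([event_col] if event_col else [])].dropna(
        subset=[steps_col, cadence_col]
    )
    if len(d) < 3:
        raise ValueError("need at least 3 complete pairs")
    rho, p = stats.spearmanr(d[steps_col], d[cadence_col])
    sq = pd.qcut(d[steps_col], 4, labels=["Q1", "Q2", "Q3", "Q4"], duplicates="drop")
    cq = pd.qcut(d[cadence_col], 4, labels=["Q1", "Q2", "Q3", "Q4"], duplicates="drop")
    if event_col:
        tab = d.groupby([sq, cq], observed=False)[event_col].mean().unstack()
    else:
        tab = pd.crosstab(sq, cq)
    return VolumeIntensityResult(rho=float(rho), p=float(p), n=len(d), crosstab=tab)
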