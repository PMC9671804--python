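"""ICD events -> phecodes -> incident cohorts -> counting-process tables.

Implements the EHR side of the analysis: mapping billing codes to phecode
phenotypes, the 6-month washout rule (a new diagnosis coded in the first six
months of monitoring marks the condition as prevalent and excludes the person
for that outcome), censoring at the last medical encounter across the
measurement/lab/procedure/condition domains, and assembly of (start, stop]
counting-process rows carrying the time-varying monthly step exposure.

All times are months (30-day blocks) on each person's own monitoring clock;
dates are integer day offsets from monitoring start.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .wearables import DAYS_PER_MONTH

logger = logging.getLogger(__name__)

ENCOUNTER_DOMAINS = ("measurement", "lab", "procedure", "condition")


def map_events_to_phecodes(
    conditions: pd.DataFrame,
    phecode_map: pd.DataFrame,
    person_sex: pd.Series | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Join condition rows to the phecode map; keep the earliest date per pair.

    Returns the (person_id, phecode, first_date) table and a log dict with
    mapped/unmapped counts. Codes absent from the map are dropped and counted.
    Sex-specific phecodes (a ``restrict_sex`` map column) are honored when a
    person_id -> sex series is supplied, otherwise ignored with a warning.
    """
    bad_vocab = set(conditions["vocabulary"]) - {"ICD9CM", "ICD10CM"}
    if bad_vocab:
        raise ValueError(f"unknown vocabulary values: {sorted(bad_vocab)}")
    merged = conditions.merge(phecode_map, on=["code", "vocabulary"], how="left")
    unmapped = merged["phecode"].isna()
    n_unmapped = int(unmapped.sum())
    if n_unmapped:
        logger.info("dropped %d condition rows with codes absent from the map", n_unmapped)
    mapped = merged[~unmapped]
    if "restrict_sex" in mapped.columns and mapped["restrict_sex"].notna().any():
        if person_sex is None:
            logger.warning("map has sex-specific phecodes but no sex data; restriction ignored")
        else:
            sex = mapped["person_id"].map(person_sex)
            keep = mapped["restrict_sex"].isna() | (mapped["restrict_sex"] == sex)
            mapped = mapped[keep]
    first = (
        mapped.groupby(["person_id", "phecode"], as_index=False)["date"]
        .min()
        .rename(columns={"date": "first_date"})
    )
    log = {"n_rows": len(conditions), "n_mapped": len(mapped), "n_unmapped": n_unmapped}
    return first, log


def censoring_dates(encounters: pd.DataFrame) -> pd.Series:
    """Last medical encounter per person: max date over the four domains."""
    enc = encounters[encounters["domain"].isin(ENCOUNTER_DOMAINS)]
    if len(enc) < len(encounters):
        raise ValueError("encounter table contains unknown domains")
    return enc.groupby("person_id")["date"].max()


@dataclass(frozen=True)
class CohortConfig:
    """One outcome: a phecode (or combined set) plus washout length."""

    phecodes: tuple[str, ...]
    washout_months: float = 6.0
    name: str = ""

    def __post_init__(self):
        if self.washout_months <= 0:
            raise ValueError("washout must be positive")


def build_incident_cohort(
    phecode_events: pd.DataFrame,
    censor: pd.Series,
    config: CohortConfig,
    persons: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-person entry/exit/event for one outcome, with exclusion reasons.

    Persons whose first qualifying occurrence (earliest across the combined
    phecode set) predates monitoring or falls inside the washout are excluded
    as prevalent; persons whose censoring date is inside the washout carry no
    risk time. Survivors enter the risk set at washout end (late entry) and
    exit at the first post-washout occurrence (event) or at censoring.
    """
    persons = censor.index.to_numpy() if persons is None else np.asarray(persons)
    missing = set(persons) - set(censor.index)
    if missing:
        raise ValueError(f"persons without any encounter (no censoring date): {sorted(missing)[:5]}")
    ev = phecode_events[phecode_events["phecode"].isin(config.phecodes)]
    first_occ = ev.groupby("person_id")["first_date"].min() / DAYS_PER_MONTH
    w = config.washout_months
    rows, excl = [], []
    for p in persons:
        c_m = censor.loc[p] / DAYS_PER_MONTH
        t_occ = first_occ.get(p, np.nan)
        if np.isfinite(t_occ) and t_occ < 0:
            excl.append({"person_id": p, "reason": "prevalent_before_monitoring"})
            continue
        if np.isfinite(t_occ) and t_occ <= w:
            excl.append({"person_id": p, "reason": "prevalent_washout"})
            continue
        if c_m <= w and not np.isfinite(t_occ):
            excl.append({"person_id": p, "reason": "no_followup_after_washout"})
            continue
        event = int(np.isfinite(t_occ))
        exit_m = t_occ if event else c_m
        rows.append({"person_id": p, "entry": w, "exit": float(exit_m), "event": event})
    cohort = pd.DataFrame(rows, columns=["person_id", "entry", "exit", "event"])
    exclusions = pd.DataFrame(excl, columns=["person_id", "reason"])
    return cohort, exclusions


def build_counting_process(
    cohort: pd.DataFrame,
    monthly: dict | pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    exposure_mode: str = "running_mean",
) -> tuple[pd.DataFrame, dict]:
    """Expand an incident cohort into monthly (start, stop] risk intervals.

    ``monthly`` holds each person's monthly summary (as produced by
    ``wearables.monthly_exposures``), either a dict person -> frame or one
    frame with a participant_id column. The interval (m, m+1] carries the
    exposure computed from data through the end of month m-1 — the running
    mean of valid days (default) or month m-1's own mean — so no step data
    on or after an interval's month can influence its covariates. The
    interval is kept only when month m-1 met the >=15-valid-day rule; invalid
    months leave gaps in the risk set. The event interval is always retained
    (its lagged exposure is still computable) unless the person has no valid
    month at all.

    Returns the table and a log dict with dropped-month accounting.
    """
    if exposure_mode not in ("running_mean", "month"):
        raise ValueError("exposure_mode must be 'running_mean' or 'month'")
    if isinstance(monthly, pd.DataFrame):
        monthly = {p: g for p, g in monthly.groupby("participant_id")}
    rows = []
    n_dropped = 0
    n_total = 0
    n_zero_persons = 0
    for person in cohort.itertuples():
        p = person.person_id
        mo = monthly.get(p)
        if mo is None or not mo["is_valid_month"].any():
            n_zero_persons += 1
            continue
        nm = int(mo["month"].max()) + 1
        valid = np.zeros(nm, dtype=bool)
        run = np.full(nm, np.nan)
        permo = np.full(nm, np.nan)
        wear = np.full(nm, np.nan)
        mi = mo["month"].to_numpy()
        valid[mi] = mo["is_valid_month"].to_numpy()
        run[mi] = mo["running_mean_steps"].to_numpy()
        permo[mi] = mo["mean_steps"].to_numpy()
        wear[mi] = mo["mean_wear_hours"].to_numpy()
        # last valid month strictly before m, -1 if none
        last_valid = np.full(nm + 1, -1, dtype=int)
        for j in range(nm):
            last_valid[j + 1] = j if valid[j] else last_valid[j]
        last_m = int(np.ceil(person.exit)) - 1
        for m in range(int(person.entry), last_m + 1):
            stop = min(m + 1, person.exit)
            if stop <= m:
                continue
            n_total += 1
            is_event_row = bool(person.event and stop >= person.exit)
            prev_ok = bool(valid[m - 1]) if 0 <= m - 1 < nm else False
            if not prev_ok and not is_event_row:
                n_dropped += 1
                continue
            lv = last_valid[min(m, nm)]
            if lv < 0:
                n_dropped += 1
                continue
            s = run[lv] if exposure_mode == "running_mean" else permo[lv]
            rows.append(
                {
                    "person_id": p,
                    "start": float(m),
                    "stop": float(stop),
                    "event": int(is_event_row),
                    "steps": float(s),
                    "wear_hours_tv": float(wear[lv]),
                }
            )
    table = pd.DataFrame(
        rows, columns=["person_id", "start", "stop", "event", "steps", "wear_hours_tv"]
    )
    if covariates is not None:
        table = table.merge(covariates, on="person_id", how="left")
    log = {
        "n_intervals": n_total,
        "n_dropped_invalid_month": n_dropped,
        "pct_months_excluded": 100.0 * n_dropped / n_total if n_total else float("nan"),
        "n_persons_no_valid_months": n_zero_persons,
    }
    return table, log


def cooccurrence_table(cohorts: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Counts of persons with events in each pair of outcomes.

    A plain tabular stand-in for a multimorbidity UpSet display: the diagonal
    holds per-outcome event counts, off-diagonals pairwise co-occurrence.
    """
    names = list(cohorts)
    event_sets = {
        n: set(c.loc[c["event"] == 1, "person_id"]) for n, c in cohorts.items()
    }
    out = pd.DataFrame(0, index=names, columns=names, dtype=int)
    for a in names:
        for b in names:
            out.loc[a, b] = len(event_sets[a] & event_sets[b])
    return out


@dataclass
class DescriptiveComparison:
    table: pd.DataFrame = field(default_factory=pd.DataFrame)


def describe_cohort(
    covariates: pd.DataFrame,
    included_mask: np.ndarray,
    continuous: tuple[str, ...] = ("age", "bmi", "sbp"),
    categorical: tuple[str, ...] = ("sex", "race", "education", "smoking", "alcohol", "cad", "cancer"),
) -> pd.DataFrame:
    """Baseline-characteristics table with included-vs-excluded comparisons.

    Continuous variables: median (IQR), Mann-Whitney U p-value. Categorical:
    count (percent of group), chi-square p-value. Percentages use the full
    group size as denominator (missing counted in the base), matching common
    cohort-table practice.
    """
    from scipy import stats

    inc = covariates[included_mask]
    exc = covariates[~included_mask]
    rows = []
    for c in continuous:
        a, b = inc[c].dropna(), exc[c].dropna()
        p = np.nan
        if len(a) and len(b):
            p = stats.mannwhitneyu(a, b).pvalue
        rows.append(
            {
                "variable": c,
                "category": "",
                "included": f"{a.median():.2f} ({a.quantile(.25):.2f}-{a.quantile(.75):.2f})"
                if len(a)
                else "",
                "excluded": f"{b.median():.2f} ({b.quantile(.25):.2f}-{b.quantile(.75):.2f})"
                if len(b)
                else "",
                "p": p,
            }
        )
    for c in categorical:
        tab = pd.crosstab(covariates[c], included_mask)
        p = np.nan
        if tab.shape == (tab.shape[0], 2) and tab.shape[0] > 1 and len(exc):
            p = stats.chi2_contingency(tab)[1]
        for cat in tab.index:
            n_i = int(tab.loc[cat, True]) if True in tab.columns else 0
            n_e = int(tab.loc[cat, False]) if False in tab.columns else 0
            rows.append(
                {
                    "variable": c,
                    "category": str(cat),
                    "included": f"{n_i} ({100 * n_i / max(len(inc), 1):.1f})",
                    "excluded": f"{n_e} ({100 * n_e / max(len(exc), 1):.1f})" if len(exc) else "",
                    "p": p,
                }
            )
    return pd.DataFrame(rows)
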