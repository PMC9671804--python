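"""Synthetic wearable + EHR cohorts with known step-count/hazard relationships.

Generates, from a single seed: participant covariates with MCAR missingness,
minute- and day-level step streams with cadence-bout structure, OMOP-style
condition and encounter tables, and the ground truth needed to verify that
the downstream pipeline recovers what was injected.

Three hazard shapes are supported for each outcome:

* ``null`` — events independent of steps (falsification / calibration);
* ``loglinear`` — log hazard linear in the running-average daily steps,
  parameterized by the hazard ratio per 1,000 steps;
* ``plateau`` — log hazard linear below a knot (default 9,000 steps/day) and
  flat above it, the shape seen for incident diabetes/hypertension.

The hazard is piecewise-constant per 30-day month and is driven by the same
time-varying covariate the analysis model uses: the valid-day running mean of
daily steps through the *previous* month. Event times are drawn by exact
inverse-transform sampling on the cumulative hazard.

Scale notes: the person-level daily-step distribution is log-normal with
median ~7,700 steps/day and IQR ~5,900-9,800 (between-person log-SD 0.38);
non-wear arrives in multi-day episodes via a two-state Markov chain so that a
realistic share of months fail the >=15-valid-day rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .wearables import DAYS_PER_MONTH, MINUTES_PER_DAY

ANCHOR = pd.Timestamp("2020-01-01")
WASHOUT_MONTHS = 6


@dataclass(frozen=True)
class HazardSpec:
    """Shape of the true exposure-log-hazard relationship for one outcome."""

    kind: str = "loglinear"  # null | loglinear | plateau
    hr_per_1000: float = 0.80  # loglinear slope as HR per 1,000 steps
    knot: float = 9000.0  # plateau inflection, steps/day
    baseline_monthly: float = 0.005  # hazard/month at the reference exposure

    def __post_init__(self):
        if self.kind not in ("null", "loglinear", "plateau"):
            raise ValueError(f"unknown hazard kind {self.kind!r}")
        if self.hr_per_1000 > 1.0 and self.kind != "null":
            raise ValueError("protective scenarios require hr_per_1000 <= 1")
        if self.baseline_monthly < 0:
            raise ValueError("baseline hazard must be >= 0")

    @property
    def beta_per_step(self) -> float:
        return np.log(self.hr_per_1000) / 1000.0

    def log_multiplier(self, s, reference: float = 7700.0):
        """True log hazard multiplier at running-mean exposure s (steps/day)."""
        s = np.asarray(s, dtype=float)
        if self.kind == "null":
            out = np.zeros_like(s)
        elif self.kind == "loglinear":
            out = self.beta_per_step * (s - reference)
        else:  # plateau: linear below knot, flat above
            out = self.beta_per_step * (np.minimum(s, self.knot) - self.knot)
        if not np.all(np.isfinite(out)):
            raise ValueError("hazard spec produced non-finite rates")
        return out


@dataclass(frozen=True)
class BoutMix:
    """Within-day cadence mixture: share of daily steps and typical cadence."""

    frac_slow: float = 0.40  # steps taken in >=60 spm bouts (below 100)
    frac_fast: float = 0.15  # steps taken in >=100 spm bouts
    cadence_slow: float = 85.0
    cadence_fast: float = 112.0


@dataclass(frozen=True)
class SimConfig:
    n_participants: int = 500
    monitoring_years: float = 3.0
    seed: int = 0
    step_level_median: float = 7700.0  # person-level median daily steps
    step_level_sigma: float = 0.38  # between-person SD of log daily steps
    day_sigma: float = 0.32  # within-person day-to-day log-SD
    wear_hours_mean: float = 14.0
    wear_hours_sd: float = 2.5
    frac_nonwear_days: float = 0.18
    nonwear_episode_days: float = 10.0  # mean length of a non-wear episode
    followup_min_frac: float = 0.65  # per-person monitoring length, uniform frac
    hazard_spec: HazardSpec = field(default_factory=HazardSpec)
    covariate_missingness: float = 0.10
    frac_prevalent: float = 0.05  # injected pre-washout diagnoses
    bout_mix: BoutMix = field(default_factory=BoutMix)
    date_shift: bool = False  # uniform 1-365 day shift of all of a person's dates

    def __post_init__(self):
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if not 0.0 <= self.covariate_missingness <= 1.0:
            raise ValueError("covariate_missingness must be in [0, 1]")
        if not 0.0 <= self.frac_nonwear_days <= 1.0:
            raise ValueError("frac_nonwear_days must be in [0, 1]")

    @property
    def n_days(self) -> int:
        return int(round(self.monitoring_years * 365))


#: covariate columns eligible for MCAR missingness (age kept complete so the
#: imputation model always has a fully observed predictor)
MISSABLE_COVARIATES = ["sex", "race", "ethnicity", "education", "smoking", "alcohol", "bmi", "sbp"]


def gen_cohort(config: SimConfig, rng: np.random.Generator | None = None):
    """Participant covariate table plus the per-person ground-truth state.

    Covariate marginals echo a predominantly female, white, college-educated
    activity-tracker cohort. Missingness is injected completely at random.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = config.n_participants
    cov = pd.DataFrame(
        {
            "person_id": np.arange(n),
            "age": np.clip(rng.normal(55, 15, n), 18, 90).round(1),
            "sex": rng.choice(["female", "male"], n, p=[0.73, 0.27]),
            "race": rng.choice(["white", "black", "other"], n, p=[0.839, 0.056, 0.105]),
            "ethnicity": rng.choice(["not_hispanic", "hispanic"], n, p=[0.93, 0.07]),
            "education": rng.choice(
                ["college", "some_college", "no_college"], n, p=[0.714, 0.223, 0.063]
            ),
            "smoking": rng.binomial(1, 0.32, n),
            "alcohol": rng.binomial(1, 0.968, n),
            "bmi": np.exp(rng.normal(np.log(28.1), 0.20, n)).round(1),
            "sbp": rng.normal(122, 14, n).round(0),
            "cad": rng.binomial(1, 0.028, n),
            "cancer": rng.binomial(1, 0.237, n),
        }
    )
    # person-level activity state
    log_mu = rng.normal(np.log(config.step_level_median), config.step_level_sigma, n)
    # bout cadence correlates positively with volume (rho ~0.5-0.9 in cohorts)
    cadence_shift = 12.0 * (log_mu - np.log(config.step_level_median)) + rng.normal(0, 3.0, n)
    monitor_days = (
        config.n_days * rng.uniform(config.followup_min_frac, 1.0, n)
    ).astype(int)
    date_offset = rng.integers(1, 366, n) if config.date_shift else np.zeros(n, dtype=int)
    truth = {
        "log_mu": log_mu,
        "cadence_shift": cadence_shift,
        "monitor_days": monitor_days,
        "date_offset": date_offset,
        "person_mean_steps": np.exp(log_mu + config.day_sigma**2 / 2),
    }
    if config.covariate_missingness > 0:
        mask = rng.random((n, len(MISSABLE_COVARIATES))) < config.covariate_missingness
        for j, c in enumerate(MISSABLE_COVARIATES):
            cov.loc[mask[:, j], c] = np.nan
    return cov, truth


def _nonwear_markov(rng, n_persons, n_days, frac, mean_episode):
    """Two-state Markov chain giving clumped non-wear days (persons x days)."""
    if frac >= 1.0:
        return np.ones((n_persons, n_days), dtype=bool)
    if frac <= 0.0:
        return np.zeros((n_persons, n_days), dtype=bool)
    p_exit = 1.0 / mean_episode
    p_enter = min(frac * p_exit / (1.0 - frac), 1.0)
    state = rng.random(n_persons) < frac
    out = np.empty((n_persons, n_days), dtype=bool)
    for d in range(n_days):
        out[:, d] = state
        u = rng.random(n_persons)
        state = np.where(state, u >= p_exit, u < p_enter)
    return out


def gen_daily_data(config: SimConfig, truth: dict, rng: np.random.Generator) -> pd.DataFrame:
    """Day-level step summaries for the whole cohort, vectorized.

    Emits the same schema the wearable-processing chain produces from minute
    streams (total steps, wear hours, bout minutes/steps at 60 and 100 spm,
    validity), so downstream stages are agnostic about which path made it.
    """
    n, nd = config.n_participants, config.n_days
    nonwear = _nonwear_markov(rng, n, nd, config.frac_nonwear_days, config.nonwear_episode_days)
    log_mu = truth["log_mu"][:, None]
    steps = np.exp(rng.normal(log_mu, config.day_sigma, (n, nd))).round().astype(np.int64)
    wear_h = np.clip(
        rng.normal(config.wear_hours_mean, config.wear_hours_sd, (n, nd)).round(), 4, 24
    ).astype(np.int64)
    steps[nonwear] = 0
    wear_h[nonwear] = 0

    mix = config.bout_mix
    slow_f = np.clip(rng.normal(mix.frac_slow, 0.08, (n, nd)), 0.05, 0.8)
    fast_f = np.clip(rng.normal(mix.frac_fast, 0.06, (n, nd)), 0.0, 0.5)
    cad_slow = np.clip(
        rng.normal(mix.cadence_slow + truth["cadence_shift"][:, None], 4.0, (n, nd)), 62, 99
    )
    cad_fast = np.clip(
        rng.normal(mix.cadence_fast + truth["cadence_shift"][:, None], 4.0, (n, nd)), 101, 140
    )
    slow_steps = (slow_f * steps).astype(np.int64)
    fast_steps = (fast_f * steps).astype(np.int64)
    slow_min = np.ceil(slow_steps / cad_slow).astype(np.int64)
    fast_min = np.ceil(fast_steps / cad_fast).astype(np.int64)

    pid = np.repeat(np.arange(n), nd)
    day = np.tile(np.arange(nd), n)
    df = pd.DataFrame(
        {
            "participant_id": pid,
            "day": day,
            "total_steps": steps.ravel(),
            "wear_hours": wear_h.ravel(),
            "bout_min_60": (slow_min + fast_min).ravel(),
            "bout_steps_60": (slow_steps + fast_steps).ravel(),
            "bout_min_100": fast_min.ravel(),
            "bout_steps_100": fast_steps.ravel(),
        }
    )
    df["is_valid"] = (df["wear_hours"] >= 10) & (df["total_steps"] >= 100)
    # truncate to each person's monitoring length
    df = df[df["day"] < truth["monitor_days"][df["participant_id"]]].reset_index(drop=True)
    return df


def gen_minute_stream(
    config: SimConfig,
    daily: pd.DataFrame,
    participant_id: int,
    rng: np.random.Generator,
    days: range | None = None,
) -> pd.DataFrame:
    """Minute-level stream for one participant, consistent with ``daily``.

    Every day emits a full 1,440-minute grid; the day's total steps equal the
    daily table exactly (multinomial allocation over an intensity profile that
    concentrates steps into cadence bouts within the wear-hour block).
    """
    d = daily[daily["participant_id"] == participant_id]
    if days is not None:
        d = d[d["day"].isin(list(days))]
    mix = config.bout_mix
    frames = []
    for row in d.itertuples():
        vec = np.zeros(MINUTES_PER_DAY, dtype=np.int64)
        total = int(row.total_steps)
        if total > 0:
            wh = max(int(row.wear_hours), 1)
            start_h = int(np.clip(rng.normal(8, 1.5), 0, 24 - wh))
            lo, hi = start_h * 60, (start_h + wh) * 60
            weights = np.zeros(MINUTES_PER_DAY)
            weights[lo:hi] = 6.0  # incidental movement
            # place cadence bouts inside the wear block
            for n_min, cad in ((int(row.bout_min_60 - row.bout_min_100), mix.cadence_slow),
                               (int(row.bout_min_100), mix.cadence_fast)):
                placed = 0
                while placed < n_min:
                    run = min(int(rng.geometric(1 / 6.0)) + 1, n_min - placed)
                    pos = int(rng.integers(lo, max(hi - run, lo + 1)))
                    weights[pos : pos + run] = cad
                    placed += run
            vec = rng.multinomial(total, weights / weights.sum())
        ts = ANCHOR + pd.to_timedelta(int(row.day), unit="D") + pd.to_timedelta(
            np.arange(MINUTES_PER_DAY), unit="min"
        )
        frames.append(
            pd.DataFrame({"participant_id": participant_id, "timestamp": ts, "steps": vec})
        )
    if not frames:
        return pd.DataFrame(columns=["participant_id", "timestamp", "steps"])
    return pd.concat(frames, ignore_index=True)


def true_monthly_exposure(daily: pd.DataFrame, n_months: int) -> np.ndarray:
    """Per-person lagged running-mean exposure matrix (persons x months).

    Column m is the valid-day running mean of daily steps through the end of
    month m-1 — the covariate that drives the hazard on the interval
    (m, m+1]. Months before any valid day carry the first available value.
    """
    d = daily[daily["is_valid"]].copy()
    d["month"] = d["day"] // DAYS_PER_MONTH
    pids = np.sort(daily["participant_id"].unique())
    idx = pd.Series(np.arange(len(pids)), index=pids)
    sums = np.zeros((len(pids), n_months))
    cnts = np.zeros((len(pids), n_months))
    g = d.groupby(["participant_id", "month"])["total_steps"].agg(["sum", "size"]).reset_index()
    g = g[g["month"] < n_months]
    r = idx.loc[g["participant_id"]].to_numpy()
    c = g["month"].to_numpy(dtype=int)
    sums[r, c] = g["sum"].to_numpy()
    cnts[r, c] = g["size"].to_numpy()
    csum = np.cumsum(sums, axis=1)
    ccnt = np.cumsum(cnts, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        run = np.where(ccnt > 0, csum / np.maximum(ccnt, 1), np.nan)
    # exposure for month m is the running mean through month m-1
    lagged = np.empty_like(run)
    lagged[:, 1:] = run[:, :-1]
    lagged[:, 0] = np.nan
    # leading months (no valid history yet) borrow the first available value
    first = np.full(len(pids), np.nan)
    any_valid = ccnt[:, -1] > 0
    first_col = np.argmax(ccnt > 0, axis=1)
    first[any_valid] = run[any_valid, first_col[any_valid]]
    fallback = np.nanmean(run) if np.isfinite(run).any() else 0.0
    first = np.where(np.isfinite(first), first, fallback)
    for j in range(n_months):
        nanmask = ~np.isfinite(lagged[:, j])
        lagged[nanmask, j] = first[nanmask]
    return lagged


def sample_event_times(
    exposure: np.ndarray,
    spec: HazardSpec,
    rng: np.random.Generator,
    reference: float = 7700.0,
) -> np.ndarray:
    """Inverse-transform event times (months) from piecewise-constant hazards.

    ``exposure[i, m]`` drives the hazard of person i on (m, m+1]. Returns inf
    where no event occurs within the covered months.
    """
    lam = spec.baseline_monthly * np.exp(spec.log_multiplier(exposure, reference))
    lam = np.where(np.isfinite(lam), lam, 0.0)
    cumhaz = np.cumsum(lam, axis=1)
    e = rng.exponential(1.0, size=lam.shape[0])
    n, M = lam.shape
    times = np.full(n, np.inf)
    hit = cumhaz >= e[:, None]
    has = hit.any(axis=1)
    m_idx = np.argmax(hit, axis=1)
    prev = np.where(m_idx > 0, cumhaz[np.arange(n), m_idx - 1], 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = (e - prev) / lam[np.arange(n), m_idx]
    times[has] = m_idx[has] + np.clip(frac[has], 0.0, 1.0)
    return times


# --------------------------------------------------------------------------
# ICD -> phecode fixture map and EHR event tables

_MAP_ROWS = [
    # phecode, label, ICD9CM, ICD10CM codes
    ("250.2", "type 2 diabetes", ["250.00"], ["E11.9", "E11.65"]),
    ("250.24", "type 2 diabetes w/ neurological manifestation", ["250.60"], ["E11.40"]),
    ("401.1", "essential hypertension", ["401.9"], ["I10"]),
    ("278.1", "obesity", ["278.00"], ["E66.9"]),
    ("530.11", "GERD", ["530.81"], ["K21.9"]),
    ("296.22", "major depressive disorder", ["296.20"], ["F32.9"]),
    ("327.3", "sleep apnea", ["780.57"], ["G47.30"]),
    ("327.32", "obstructive sleep apnea", ["327.23"], ["G47.33"]),
    ("351", "carpal tunnel syndrome", ["354.0"], ["G56.00"]),
    ("702.1", "actinic keratosis", ["702.0"], ["L57.0"]),
    ("495", "asthma", ["493.90"], ["J45.909"]),
    ("038", "septicemia", ["038.9"], ["A41.9"]),
    ("574.1", "cholelithiasis", ["574.20"], ["K80.20"]),
    ("535", "gastritis", ["535.50"], ["K29.70"]),
]

#: phecode pairs analyzed as a single combined condition downstream
COMBINED_PHECODES = {
    "diabetes": ("250.2", "250.24"),
    "sleep_apnea": ("327.3", "327.32"),
}


def gen_phecode_map_fixture() -> pd.DataFrame:
    """Small many-to-one ICD -> phecode map covering every emitted ICD code."""
    rows = []
    for phe, label, icd9, icd10 in _MAP_ROWS:
        for c in icd9:
            rows.append({"code": c, "vocabulary": "ICD9CM", "phecode": phe, "phecode_string": label})
        for c in icd10:
            rows.append({"code": c, "vocabulary": "ICD10CM", "phecode": phe, "phecode_string": label})
    return pd.DataFrame(rows)


def _icd_for_phecode(map_df: pd.DataFrame, phecode: str, rng) -> tuple[str, str]:
    rows = map_df[map_df["phecode"] == phecode]
    r = rows.iloc[int(rng.integers(len(rows)))]
    return r["code"], r["vocabulary"]


def gen_outcome_events(
    config: SimConfig,
    truth: dict,
    exposure: np.ndarray,
    phecode: str,
    spec: HazardSpec,
    rng: np.random.Generator,
    map_df: pd.DataFrame | None = None,
    inject_prevalent: bool = True,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Condition rows for one outcome, plus the true event times (months).

    Events are drawn from the piecewise-constant hazard, kept only when they
    fall inside the person's monitoring window, and emitted as ICD9/ICD10
    rows drawn from the fixture map. A small fraction of persons additionally
    receive a pre-washout (prevalent) diagnosis to exercise exclusions.
    """
    map_df = gen_phecode_map_fixture() if map_df is None else map_df
    times = sample_event_times(exposure, spec, rng, reference=config.step_level_median)
    monitor_months = truth["monitor_days"] / DAYS_PER_MONTH
    rows = []
    for i in np.flatnonzero(np.isfinite(times)):
        t = times[i]
        if t > monitor_months[i]:
            continue
        code, vocab = _icd_for_phecode(map_df, phecode, rng)
        rows.append(
            {
                "person_id": i,
                "date": int(round(t * DAYS_PER_MONTH)),
                "code": code,
                "vocabulary": vocab,
            }
        )
    if inject_prevalent and config.frac_prevalent > 0:
        prev = rng.random(config.n_participants) < config.frac_prevalent
        for i in np.flatnonzero(prev):
            code, vocab = _icd_for_phecode(map_df, phecode, rng)
            day = int(rng.integers(-180, WASHOUT_MONTHS * DAYS_PER_MONTH))
            rows.append({"person_id": i, "date": day, "code": code, "vocabulary": vocab})
    cols = ["person_id", "date", "code", "vocabulary"]
    cond = pd.DataFrame(rows, columns=cols).sort_values(["person_id", "date"]).reset_index(drop=True)
    return cond, times


def gen_encounters(config: SimConfig, truth: dict, rng: np.random.Generator) -> pd.DataFrame:
    """Encounter dates across the four censoring domains.

    Every person gets a terminal measurement at the end of their monitoring
    window plus Poisson-many earlier visits, so the censoring date equals the
    monitoring end.
    """
    n = config.n_participants
    ends = truth["monitor_days"].astype(int)
    k = rng.poisson(8, n) + 1
    pid = np.repeat(np.arange(n), k)
    days = np.floor(rng.random(k.sum()) * np.maximum(ends[pid], 1)).astype(int)
    domains = rng.choice(["measurement", "lab", "procedure", "condition"], k.sum())
    visits = pd.DataFrame({"person_id": pid, "date": days, "domain": domains})
    terminal = pd.DataFrame(
        {"person_id": np.arange(n), "date": ends, "domain": "measurement"}
    )
    return pd.concat([visits, terminal], ignore_index=True)


def apply_date_shift(tables: dict[str, pd.DataFrame], truth: dict) -> dict[str, pd.DataFrame]:
    """Shift each person's dates by their uniform 1-365 day offset.

    A privacy-preserving transform; every downstream quantity is computed on
    the person's own monitoring clock, so estimates must be unchanged.
    """
    out = {}
    for name, df in tables.items():
        df = df.copy()
        key = "person_id" if "person_id" in df else "participant_id"
        datecol = "date" if "date" in df else "day"
        df[datecol] = df[datecol] + truth["date_offset"][df[key].to_numpy()]
        out[name] = df
    return out


def true_hr_75_25(config: SimConfig, truth: dict, spec: HazardSpec) -> float:
    """Ground-truth HR comparing 75th vs 25th percentile of person mean steps."""
    q25, q75 = np.percentile(truth["person_mean_steps"], [25, 75])
    lm = spec.log_multiplier(np.array([q75, q25]), config.step_level_median)
    return float(np.exp(lm[0] - lm[1]))


def simulate(config: SimConfig) -> dict:
    """One-call simulation: all tables plus ground truth, from one seed."""
    rng = np.random.default_rng(config.seed)
    cohort, truth = gen_cohort(config, rng)
    daily = gen_daily_data(config, truth, rng)
    n_months = int(np.ceil(config.n_days / DAYS_PER_MONTH))
    exposure = true_monthly_exposure(daily, n_months)
    truth["exposure"] = exposure
    map_df = gen_phecode_map_fixture()
    encounters = gen_encounters(config, truth, rng)
    return {
        "config": config,
        "cohort": cohort,
        "truth": truth,
        "daily": daily,
        "map": map_df,
        "encounters": encounters,
        "rng": rng,
    }
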