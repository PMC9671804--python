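"""End-to-end orchestration: simulate/ingest -> process -> screen -> model -> report.

A single ``run_full_analysis`` drives the whole chain on a simulated cohort:
wearable processing and cohort flow, descriptive comparisons, the phenome-wide
logistic screen, per-outcome incident cohorts and counting-process tables,
multiply-imputed time-varying Cox models with spline knot selection by AIC,
75th-vs-25th percentile hazard-ratio contrasts pooled by Rubin's rules,
cumulative incidence at 3/5/7 years, proportional-hazards checks, step
trajectories by case status, falsification outcomes and volume-intensity
descriptives. ``write_report`` serializes the bundle as CSV tables plus a
JSON summary with stable filenames.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import impute, phenotypes, phewas, survmod, synthdata, wearables
from .synthdata import HazardSpec, SimConfig

logger = logging.getLogger(__name__)

TRAJECTORY_WINDOWS = ((0, 3), (3, 6), (6, 12), (12, 24))


@dataclass(frozen=True)
class OutcomeSpec:
    name: str
    phecodes: tuple[str, ...]
    hazard: HazardSpec = field(default_factory=HazardSpec)


def default_outcomes() -> list[OutcomeSpec]:
    return [
        OutcomeSpec("diabetes", synthdata.COMBINED_PHECODES["diabetes"],
                    HazardSpec(kind="plateau", hr_per_1000=0.70, knot=9000.0,
                               baseline_monthly=0.003)),
        OutcomeSpec("obesity", ("278.1",),
                    HazardSpec(kind="loglinear", hr_per_1000=0.80, baseline_monthly=0.004)),
        OutcomeSpec("sleep_apnea", synthdata.COMBINED_PHECODES["sleep_apnea"],
                    HazardSpec(kind="loglinear", hr_per_1000=0.82, baseline_monthly=0.004)),
    ]


def default_falsification() -> list[OutcomeSpec]:
    return [
        OutcomeSpec("carpal_tunnel", ("351",), HazardSpec(kind="null", baseline_monthly=0.002)),
        OutcomeSpec("actinic_keratosis", ("702.1",), HazardSpec(kind="null", baseline_monthly=0.0025)),
    ]


def default_background() -> list[OutcomeSpec]:
    # step-independent phecodes that pad the phenome-wide screen
    return [
        OutcomeSpec("asthma", ("495",), HazardSpec(kind="null", baseline_monthly=0.002)),
        OutcomeSpec("cholelithiasis", ("574.1",), HazardSpec(kind="null", baseline_monthly=0.0015)),
        OutcomeSpec("gastritis", ("535",), HazardSpec(kind="null", baseline_monthly=0.002)),
        OutcomeSpec("septicemia", ("038",), HazardSpec(kind="null", baseline_monthly=0.001)),
    ]


@dataclass(frozen=True)
class RunConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    outcomes: tuple[OutcomeSpec, ...] = tuple(default_outcomes())
    falsification: tuple[OutcomeSpec, ...] = tuple(default_falsification())
    background: tuple[OutcomeSpec, ...] = tuple(default_background())
    models: tuple[str, ...] = ("model1", "model2")
    knot_choices: tuple[int, ...] = (3, 4, 5)
    exposure_mode: str = "running_mean"
    m_imputations: int = 5
    washout_months: float = 6.0
    seed: int | None = None  # overrides sim.seed when set

    def __post_init__(self):
        known = set(self.outcomes) | set(self.falsification) | set(self.background)
        map_phecodes = set(synthdata.gen_phecode_map_fixture()["phecode"])
        declared = {p for o in known for p in o.phecodes}
        missing = declared - map_phecodes
        if missing:
            raise ValueError(f"declared phecodes absent from the map: {sorted(missing)}")


def config_from_yaml(path) -> RunConfig:
    """Build a RunConfig from a YAML file mirroring the dataclass layout."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    sim_raw = raw.pop("sim", {})
    hz = sim_raw.pop("hazard_spec", None)
    if hz:
        sim_raw["hazard_spec"] = HazardSpec(**hz)
    sim = SimConfig(**sim_raw)

    def _outs(key, default):
        if key not in raw:
            return tuple(default)
        specs = []
        for o in raw.pop(key):
            hzo = HazardSpec(**o["hazard"]) if "hazard" in o else HazardSpec()
            specs.append(OutcomeSpec(o["name"], tuple(o["phecodes"]), hzo))
        return tuple(specs)

    outcomes = _outs("outcomes", default_outcomes())
    falsification = _outs("falsification", default_falsification())
    background = _outs("background", default_background())
    for key in ("models", "knot_choices"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return RunConfig(
        sim=sim, outcomes=outcomes, falsification=falsification, background=background, **raw
    )


def encode_covariates(cov: pd.DataFrame) -> pd.DataFrame:
    """Dummy-code a (complete) covariate table for the Cox design."""
    return pd.DataFrame(
        {
            "person_id": cov["person_id"],
            "age": cov["age"].astype(float),
            "sex_male": (cov["sex"] == "male").astype(float),
            "race_black": (cov["race"] == "black").astype(float),
            "race_other": (cov["race"] == "other").astype(float),
            "sbp": cov["sbp"].astype(float),
            "cad": cov["cad"].astype(float),
            "cancer": cov["cancer"].astype(float),
            "smoking": cov["smoking"].astype(float),
            "education_some_college": (cov["education"] == "some_college").astype(float),
            "education_no_college": (cov["education"] == "no_college").astype(float),
            "alcohol": cov["alcohol"].astype(float),
            "bmi": cov["bmi"].astype(float),
        }
    )


def reference_profile(encoded: pd.DataFrame) -> dict:
    """Median continuous values, modal categories — the incidence-curve profile."""
    prof = {}
    for c in encoded.columns:
        if c == "person_id":
            continue
        vals = encoded[c]
        prof[c] = float(vals.median()) if vals.nunique() > 2 else float(round(vals.mean()))
    return prof


def _monthly_by_person(daily: pd.DataFrame) -> dict:
    return wearables.monthly_exposures_all(daily)


def analyze_outcome(
    name: str,
    phecodes: tuple[str, ...],
    phecode_events: pd.DataFrame,
    censor: pd.Series,
    monthly: dict,
    imputed_encoded: list[pd.DataFrame],
    person_steps: pd.Series,
    daily: pd.DataFrame,
    config: RunConfig,
) -> dict:
    """All survival analyses for one outcome; returns a result dict."""
    cc = phenotypes.CohortConfig(tuple(phecodes), config.washout_months, name)
    cohort, exclusions = phenotypes.build_incident_cohort(phecode_events, censor, cc)
    out = {
        "name": name,
        "cohort": cohort,
        "exclusions": exclusions,
        "n": len(cohort),
        "n_events": int(cohort["event"].sum()),
    }
    if cohort["event"].sum() < 10:
        out["skipped"] = "fewer than 10 events"
        return out
    base_cov = imputed_encoded[0]
    table0, cplog = phenotypes.build_counting_process(
        cohort, monthly, base_cov, config.exposure_mode
    )
    out["cp_log"] = cplog

    # knot selection by AIC on the first completed dataset, adjusted model 1
    cohort_steps = person_steps.reindex(cohort["person_id"]).dropna()
    fits_by_k = {}
    for k in config.knot_choices:
        try:
            spec_k = survmod.SplineSpec(survmod.rcs_knots(table0["steps"], k))
        except ValueError:
            continue
        t_k = _with_exposure(table0, spec_k)
        fits_by_k[k] = (
            spec_k,
            survmod.fit_cox_tv(t_k, spec_k.columns + survmod.MODEL_SUITE["model1"]),
        )
    if not fits_by_k:  # exposure too degenerate for any spline: fall back to linear
        spec_lin = survmod.SplineSpec(name="steps")
        t_lin = _with_exposure(table0, spec_lin)
        fits_by_k = {0: (spec_lin, survmod.fit_cox_tv(
            t_lin, spec_lin.columns + survmod.MODEL_SUITE["model1"]))}
    chosen_k = survmod.select_by_aic([f for _, f in fits_by_k.values()])
    k_star = next(k for k, (_, f) in fits_by_k.items() if f is chosen_k)
    spec = fits_by_k[k_star][0]
    out["aic_by_k"] = {k: f.aic for k, (_, f) in fits_by_k.items()}
    out["k_chosen"] = k_star

    # chunk tests on the chosen model (overall association and nonlinearity)
    out["chunk_association"] = survmod.wald_chunk_test(chosen_k, spec.columns)
    if spec.nonlinear_columns:
        out["chunk_nonlinearity"] = survmod.wald_chunk_test(chosen_k, spec.nonlinear_columns)

    # model suite across imputations, pooled 75-vs-25 contrasts
    model_rows = []
    keep_fit = {}
    for model in config.models:
        covs = survmod.MODEL_SUITE[model]
        logs, ses = [], []
        for enc in imputed_encoded:
            tab, _ = phenotypes.build_counting_process(cohort, monthly, enc, config.exposure_mode)
            tab = _with_exposure(tab, spec)
            fit = survmod.fit_cox_tv(tab, spec.columns + covs)
            con = survmod.hr_contrast(fit, spec, cohort_steps)
            logs.append(con.log_hr)
            ses.append(con.se**2)
            keep_fit[model] = (fit, tab)
        if len(logs) >= 2:
            pooled = impute.rubin_pool(logs, ses)
            hr, lo, hi, pv = np.exp(pooled.qbar), np.exp(pooled.ci_low), np.exp(pooled.ci_high), pooled.p
        else:
            hr, lo, hi, pv = con.hr, con.ci_low, con.ci_high, con.p
        model_rows.append(
            {
                "outcome": name,
                "model": model,
                "n": out["n"],
                "n_events": out["n_events"],
                "s25": con.s25,
                "s75": con.s75,
                "hr_75_25": float(hr),
                "ci_low": float(lo),
                "ci_high": float(hi),
                "p": float(pv),
            }
        )
    out["contrast_table"] = pd.DataFrame(model_rows)

    # curves/incidence from the widest adjusted model available
    curve_model = "model2" if "model2" in keep_fit else config.models[-1]
    fit_c, tab_c = keep_fit[curve_model]
    ref = float(cohort_steps.median())
    grid = np.linspace(cohort_steps.quantile(0.05), cohort_steps.quantile(0.95), 25)
    out["hr_curve"] = survmod.hr_curve(
        fit_c, spec, grid, ref, observed_range=(table0["steps"].min(), table0["steps"].max())
    )
    prof = reference_profile(imputed_encoded[0])
    inc_rows = []
    for s in (4000, 6000, 8000, 10000):
        ic = survmod.cumulative_incidence(fit_c, spec, s, prof, years=(3, 5, 7))
        for y, f, lo, hi in zip(ic.years, ic.incidence, ic.lo, ic.hi):
            inc_rows.append(
                {"outcome": name, "steps": s, "year": y, "incidence": f, "lo": lo, "hi": hi}
            )
    out["incidence"] = pd.DataFrame(inc_rows)
    out["ph_test"] = survmod.ph_diagnostics(keep_fit[config.models[0]][0])

    # step trajectories before/without diagnosis
    traj = []
    for w0, w1 in TRAJECTORY_WINDOWS:
        for ev in (0, 1):
            ids = cohort.loc[cohort["event"] == ev, "person_id"]
            vals = [
                wearables.window_average(g, w0, w1)
                for _, g in daily[daily["participant_id"].isin(ids)].groupby("participant_id")
            ]
            vals = [v for v in vals if np.isfinite(v)]
            traj.append(
                {
                    "outcome": name,
                    "window": f"{w0}-{w1}mo",
                    "event": ev,
                    "mean_steps": float(np.mean(vals)) if vals else np.nan,
                    "n": len(vals),
                }
            )
    out["trajectories"] = pd.DataFrame(traj)
    return out


def _with_exposure(table: pd.DataFrame, spec: survmod.SplineSpec) -> pd.DataFrame:
    """Replace the raw steps column with the exposure design columns."""
    t = table.copy()
    des = spec.design(t["steps"].to_numpy())
    for c in des.columns:
        t[c] = des[c].to_numpy()
    return t


def run_full_analysis(config: RunConfig) -> dict:
    """Simulate a cohort and run every analysis stage; returns the bundle."""
    if config.seed is not None:
        config = replace(config, sim=replace(config.sim, seed=config.seed))
    sim = synthdata.simulate(config.sim)
    truth, daily, map_df = sim["truth"], sim["daily"], sim["map"]
    rng = sim["rng"]

    # outcome events for every declared spec
    conditions = []
    truth_times = {}
    for spec in list(config.outcomes) + list(config.falsification) + list(config.background):
        for phe in spec.phecodes[:1]:  # the combined partner gets a share below
            cond, times = synthdata.gen_outcome_events(
                config.sim, truth, truth["exposure"], phe, spec.hazard, rng, map_df
            )
            conditions.append(cond)
            truth_times[spec.name] = times
        # route ~20% of combined-outcome events through the partner phecode
        if len(spec.phecodes) > 1:
            c0 = conditions[-1]
            flip = rng.random(len(c0)) < 0.2
            for i in np.flatnonzero(flip):
                code, vocab = synthdata._icd_for_phecode(map_df, spec.phecodes[1], rng)
                c0.loc[c0.index[i], ["code", "vocabulary"]] = [code, vocab]
    conditions = pd.concat(conditions, ignore_index=True)

    phecode_events, map_log = phenotypes.map_events_to_phecodes(conditions, map_df)
    censor = phenotypes.censoring_dates(sim["encounters"])

    daily_f, flow = wearables.filter_participants(daily)
    included = np.sort(daily_f["participant_id"].unique())
    censor = censor[censor.index.isin(included)]
    monthly = _monthly_by_person(daily_f)
    valid_daily = daily_f[daily_f["is_valid"]]
    person_steps = valid_daily.groupby("participant_id")["total_steps"].mean()

    cov = sim["cohort"]
    included_mask = cov["person_id"].isin(included).to_numpy()
    descriptives = phenotypes.describe_cohort(cov, included_mask)

    screen = phewas.run_phewas(
        person_steps, cov, phecode_events, phewas.PheWASConfig(config.washout_months)
    )

    # multiple imputation of covariates for included persons, then encoding
    cov_inc = cov[included_mask].reset_index(drop=True)
    imputed = impute.pmm_impute(cov_inc, m=config.m_imputations, seed=config.sim.seed + 1)
    baseline = {}
    for w0, w1, col in ((0, 3, "baseline_steps_3mo"), (0, 6, "baseline_steps_6mo")):
        baseline[col] = {
            p: wearables.window_average(g, w0, w1) for p, g in daily_f.groupby("participant_id")
        }
    imputed_encoded = []
    for imp in imputed:
        enc = encode_covariates(imp)
        for col, mapping in baseline.items():
            enc[col] = enc["person_id"].map(mapping)
            enc[col] = enc[col].fillna(enc[col].median())
        imputed_encoded.append(enc)

    results = {}
    for spec in config.outcomes:
        results[spec.name] = analyze_outcome(
            spec.name, spec.phecodes, phecode_events, censor, monthly,
            imputed_encoded, person_steps, daily_f, config,
        )
    falsif_rows = []
    for spec in config.falsification:
        r = analyze_outcome(
            spec.name, spec.phecodes, phecode_events, censor, monthly,
            imputed_encoded[:1], person_steps, daily_f,
            replace(config, models=("model1",), m_imputations=1),
        )
        falsif_rows.append(
            {
                "outcome": spec.name,
                "n": r["n"],
                "n_events": r["n_events"],
                "chunk_p": r["chunk_association"].p if "chunk_association" in r else np.nan,
            }
        )

    # intensity descriptives
    intensity = (
        daily_f.groupby("participant_id")
        .apply(lambda g: pd.Series(wearables.intensity_summary(g)), include_groups=False)
        .reset_index()
    )
    itab = intensity.merge(
        person_steps.rename("mean_steps"), left_on="participant_id", right_index=True
    )
    ev_ids = set()
    if config.outcomes:
        first = config.outcomes[0].name
        ev_ids = set(results[first]["cohort"].query("event == 1")["person_id"])
    itab["event"] = itab["participant_id"].isin(ev_ids).astype(int)
    vi = wearables.correlate_volume_intensity(itab, "mean_steps", "c60", "event")

    cohorts = {n: r["cohort"] for n, r in results.items() if "cohort" in r}
    bundle = {
        "config": config,
        "flow": flow,
        "map_log": map_log,
        "descriptives": descriptives,
        "phewas": screen,
        "outcomes": results,
        "falsification": pd.DataFrame(falsif_rows),
        "volume_intensity": {"rho": vi.rho, "p": vi.p, "crosstab": vi.crosstab},
        "cooccurrence": phenotypes.cooccurrence_table(cohorts),
        "truth_hr_75_25": {
            s.name: synthdata.true_hr_75_25(config.sim, truth, s.hazard) for s in config.outcomes
        },
    }
    return bundle


def intensity_adjusted_analysis(
    table: pd.DataFrame,
    person_cadence: pd.Series,
    k_steps: int = 3,
    k_cadence: int = 3,
) -> dict:
    """Fit step volume and bout cadence as two splines in one Cox model.

    ``person_cadence`` maps person_id -> mean bout cadence over valid days.
    Returns both chunk tests (does volume survive adjustment for intensity,
    and vice versa) plus the fit.
    """
    t = table.copy()
    t["cadence"] = t["person_id"].map(person_cadence)
    t = t[t["cadence"].notna()]
    s_spec = survmod.SplineSpec(survmod.rcs_knots(t["steps"], k_steps), name="steps")
    c_spec = survmod.SplineSpec(survmod.rcs_knots(t["cadence"], k_cadence), name="cadence")
    for spec, src in ((s_spec, "steps"), (c_spec, "cadence")):
        des = spec.design(t[src].to_numpy())
        for c in spec.columns:
            t[c] = des[c].to_numpy()
    fit = survmod.fit_cox_tv(t, s_spec.columns + c_spec.columns)
    return {
        "fit": fit,
        "chunk_steps": survmod.wald_chunk_test(fit, s_spec.columns),
        "chunk_cadence": survmod.wald_chunk_test(fit, c_spec.columns),
        "steps_spec": s_spec,
        "cadence_spec": c_spec,
    }


def bmi_interaction_analysis(table: pd.DataFrame, bmi: pd.Series) -> dict:
    """Linear steps, baseline BMI and their product in one Cox model.

    Returns the fit and the Wald test of the interaction term; the hazard
    ratio per 1,000 steps then varies linearly with BMI.
    """
    t = table.copy()
    t["bmi"] = t["person_id"].map(bmi)
    t = t[t["bmi"].notna()]
    t["steps_k"] = t["steps"] / 1000.0
    t["bmi_x_steps"] = t["bmi"] * t["steps_k"]
    fit = survmod.fit_cox_tv(t, ["steps_k", "bmi", "bmi_x_steps"])

    def hr_per_1000_at(bmi_value: float) -> float:
        return float(np.exp(fit.params["steps_k"] + fit.params["bmi_x_steps"] * bmi_value))

    return {
        "fit": fit,
        "interaction_test": survmod.wald_chunk_test(fit, ["bmi_x_steps"]),
        "hr_per_1000_at": hr_per_1000_at,
    }


# --------------------------------------------------------------------------
# reporting


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    return obj


def write_report(bundle: dict, out_dir) -> list[str]:
    """CSV tables + JSON summary with stable filenames; returns paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    def _csv(df: pd.DataFrame, name: str):
        p = out / name
        df.to_csv(p, index=False)
        written.append(str(p))

    _csv(bundle["descriptives"], "table1_descriptives.csv")
    _csv(bundle["phewas"], "phewas.csv")
    _csv(bundle["falsification"], "falsification.csv")
    _csv(bundle["cooccurrence"].reset_index(names="outcome"), "cooccurrence.csv")
    contrast_tables, incidence, trajectories, ph_tests = [], [], [], []
    summary = {
        "flow": bundle["flow"],
        "map_log": bundle["map_log"],
        "volume_intensity": {
            "rho": bundle["volume_intensity"]["rho"],
            "p": bundle["volume_intensity"]["p"],
        },
        "truth_hr_75_25": bundle["truth_hr_75_25"],
        "outcomes": {},
    }
    for name, r in bundle["outcomes"].items():
        osum = {"n": r["n"], "n_events": r["n_events"]}
        if "skipped" in r:
            osum["skipped"] = r["skipped"]
        else:
            contrast_tables.append(r["contrast_table"])
            incidence.append(r["incidence"])
            trajectories.append(r["trajectories"])
            pht = r["ph_test"].copy()
            pht.insert(0, "outcome", name)
            ph_tests.append(pht)
            _csv(r["hr_curve"], f"hr_curve_{name}.csv")
            osum.update(
                k_chosen=r["k_chosen"],
                aic_by_k=r["aic_by_k"],
                chunk_association=dataclasses.asdict(r["chunk_association"]),
                pct_months_excluded=r["cp_log"]["pct_months_excluded"],
            )
            if "chunk_nonlinearity" in r:
                osum["chunk_nonlinearity"] = dataclasses.asdict(r["chunk_nonlinearity"])
        summary["outcomes"][name] = osum
    if contrast_tables:
        _csv(pd.concat(contrast_tables, ignore_index=True), "table2_contrasts.csv")
        _csv(pd.concat(incidence, ignore_index=True), "cumulative_incidence.csv")
        _csv(pd.concat(trajectories, ignore_index=True), "trajectories.csv")
        _csv(pd.concat(ph_tests, ignore_index=True), "ph_tests.csv")
    (out / "summary.json").write_text(json.dumps(_jsonable(summary), indent=2))
    written.append(str(out / "summary.json"))
    return written
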