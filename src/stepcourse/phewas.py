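"""Phenome-wide logistic screen of average daily steps against every phecode.

For each phecode: cases are persons whose first occurrence falls after the
washout, persons with pre-monitoring or washout occurrences are excluded,
and everyone else is a control. A logistic model adjusted for age, sex and
race estimates the odds ratio per 1,000-step increase in the overall mean
daily step count, with Bonferroni control over the number of phecodes fitted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .wearables import DAYS_PER_MONTH

#: fewer cases than this flags the fit as unstable (kept, not dropped)
MIN_EVENTS_LOGISTIC = 20


def bonferroni_threshold(m: int) -> float:
    """Familywise 0.05 split evenly over m tests."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return 0.05 / m


@dataclass
class PheWASConfig:
    washout_months: float = 6.0
    min_events: int = MIN_EVENTS_LOGISTIC
    alpha: float = 0.05


def _design(covariates: pd.DataFrame) -> pd.DataFrame:
    """Complete-case age/sex/race design with treatment-coded categories."""
    d = covariates[["person_id", "age", "sex", "race"]].dropna()
    X = pd.DataFrame(
        {
            "person_id": d["person_id"],
            "age": d["age"].astype(float),
            "sex_male": (d["sex"] == "male").astype(float),
            "race_black": (d["race"] == "black").astype(float),
            "race_other": (d["race"] == "other").astype(float),
        }
    )
    return X


def run_phewas(
    person_steps: pd.Series,
    covariates: pd.DataFrame,
    phecode_events: pd.DataFrame,
    config: PheWASConfig | None = None,
) -> pd.DataFrame:
    """Screen every phecode in the event table against mean daily steps.

    ``person_steps`` maps person_id -> mean steps/day over the whole
    monitoring period. Returns one row per phecode with case counts, the
    per-step coefficient, OR per 1,000 steps with Wald CI, p-value, stability
    flag and Bonferroni pass flag (threshold over the phecodes actually
    fitted). Sorted by p.
    """
    cfg = config or PheWASConfig()
    X0 = _design(covariates)
    X0 = X0[X0["person_id"].isin(person_steps.index)]
    steps_k = person_steps / 1000.0  # fit on the per-1,000 scale
    rows = []
    for phe, grp in phecode_events.groupby("phecode"):
        occ = grp.set_index("person_id")["first_date"] / DAYS_PER_MONTH
        occ = occ[occ.index.isin(X0["person_id"])]
        excluded = set(occ.index[occ <= cfg.washout_months])
        cases = set(occ.index[occ > cfg.washout_months])
        d = X0[~X0["person_id"].isin(excluded)].copy()
        d["y"] = d["person_id"].isin(cases).astype(float)
        d["steps_k"] = d["person_id"].map(steps_k)
        d = d.dropna(subset=["steps_k"])
        n_cases, n_total = int(d["y"].sum()), len(d)
        row = {
            "phecode": phe,
            "n_cases": n_cases,
            "n_total": n_total,
            "beta": np.nan,
            "or_1000": np.nan,
            "ci_low": np.nan,
            "ci_high": np.nan,
            "p": np.nan,
            "unstable": n_cases < cfg.min_events,
            "separation": False,
        }
        if n_cases > 0 and n_cases < n_total:
            exog = sm.add_constant(d[["steps_k", "age", "sex_male", "race_black", "race_other"]])
            try:
                with np.errstate(all="ignore"):
                    fit = sm.GLM(d["y"], exog, family=sm.families.Binomial()).fit(maxiter=100)
                b = fit.params["steps_k"]
                se = fit.bse["steps_k"]
                if not np.isfinite(se) or se > 50:
                    row["separation"] = True
                else:
                    row.update(
                        beta=b / 1000.0,
                        or_1000=float(np.exp(b)),
                        ci_low=float(np.exp(b - 1.96 * se)),
                        ci_high=float(np.exp(b + 1.96 * se)),
                        p=float(fit.pvalues["steps_k"]),
                    )
            except Exception:
                row["separation"] = True
        rows.append(row)
    out = pd.DataFrame(rows)
    m_fitted = int(out["p"].notna().sum())
    thr = bonferroni_threshold(m_fitted) if m_fitted else np.nan
    out["m_tests"] = m_fitted
    out["bonferroni_alpha"] = thr
    out["passes_bonferroni"] = out["p"] < thr
    return out.sort_values("p", na_position="last").reset_index(drop=True)
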