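"""Multiple imputation by predictive mean matching, and Rubin pooling.

PMM keeps imputed values in-domain by construction: each missing cell is
filled with an *observed* value copied from one of the k donors whose
linear-model predictions lie nearest the missing cell's prediction.
Categorical columns are handled through integer score coding of the same
mechanism, so imputed categories are always levels that occur in the data.
With several incomplete columns the sweeps are chained (column-by-column,
repeated); with a single incomplete column one pass suffices.

Estimates fitted on each completed dataset are combined with Rubin's rules:
total variance T = W + (1 + 1/m) B with Barnard-Rubin degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_M = 5
DEFAULT_K_DONORS = 5
CHAINED_SWEEPS = 5


def _code_frame(df: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Numeric copy of the frame; categoricals become integer level codes."""
    coded = pd.DataFrame(index=df.index)
    decoders = {}
    for c in df.columns:
        col = df[c]
        if pd.api.types.is_numeric_dtype(col):
            coded[c] = col.astype(float)
        else:
            levels = pd.Index(sorted(col.dropna().unique()))
            coded[c] = col.map({v: i for i, v in enumerate(levels)}).astype(float)
            decoders[c] = levels
    return coded, decoders


def _pmm_column(coded: pd.DataFrame, target: str, miss: np.ndarray, k: int, rng) -> np.ndarray:
    """One PMM draw for the missing cells of one column (coded values)."""
    obs = ~miss
    predictors = [c for c in coded.columns if c != target]
    X = np.column_stack([np.ones(len(coded))] + [coded[c].to_numpy() for c in predictors])
    y = coded[target].to_numpy()
    beta, *_ = np.linalg.lstsq(X[obs], y[obs], rcond=None)
    yhat = X @ beta
    yhat_obs = yhat[obs]
    y_obs = y[obs]
    out = y.copy()
    kk = min(k, len(y_obs))
    for i in np.flatnonzero(miss):
        dist = np.abs(yhat_obs - yhat[i])
        donors = np.argpartition(dist, kk - 1)[:kk]
        out[i] = y_obs[donors[int(rng.integers(kk))]]
    return out


def pmm_impute(
    table: pd.DataFrame,
    m: int = DEFAULT_M,
    k_donors: int = DEFAULT_K_DONORS,
    seed: int = 0,
    exclude: tuple[str, ...] = ("person_id",),
) -> list[pd.DataFrame]:
    """m completed copies of ``table`` via predictive mean matching.

    Columns listed in ``exclude`` pass through untouched. Raises if a column
    is entirely missing. Non-missing cells are identical across the m copies.
    """
    work_cols = [c for c in table.columns if c not in exclude]
    sub = table[work_cols]
    fully_missing = [c for c in work_cols if sub[c].isna().all()]
    if fully_missing:
        raise ValueError(f"column(s) entirely missing: {fully_missing}")
    miss_cols = [c for c in work_cols if sub[c].isna().any()]
    if not miss_cols:
        return [table.copy() for _ in range(m)]
    coded0, decoders = _code_frame(sub)
    masks = {c: sub[c].isna().to_numpy() for c in miss_cols}
    sweeps = 1 if len(miss_cols) == 1 else CHAINED_SWEEPS
    rng_master = np.random.default_rng(seed)
    out = []
    for _ in range(m):
        rng = np.random.default_rng(rng_master.integers(2**31))
        coded = coded0.copy()
        # initialize missing cells at column medians so chained sweeps can start
        for c in miss_cols:
            coded.loc[masks[c], c] = coded[c].median()
        for _sweep in range(sweeps):
            for c in miss_cols:
                coded[c] = _pmm_column(coded, c, masks[c], k_donors, rng)
        done = table.copy()
        for c in miss_cols:
            if c in decoders:
                done[c] = decoders[c].to_numpy()[coded[c].to_numpy().astype(int)]
            else:
                filled = table[c].copy().astype(float)
                filled[masks[c]] = coded.loc[masks[c], c]
                done[c] = filled
        out.append(done)
    return out


@dataclass
class PooledEstimate:
    """Rubin's-rules combination of m estimates of one scalar."""

    qbar: float  # pooled point estimate
    wbar: float  # mean within-imputation variance
    b: float  # between-imputation variance
    t: float  # total variance
    df: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    m: int


def rubin_pool(estimates, variances, nu_com: float = np.inf, alpha: float = 0.05) -> PooledEstimate:
    """Pool point estimates and their squared SEs across imputations."""
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    if q.shape != u.shape:
        raise ValueError("estimates and variances differ in length")
    m = len(q)
    if m < 2:
        raise ValueError("need m >= 2 imputations to pool")
    qbar = q.mean()
    wbar = u.mean()
    b = q.var(ddof=1)
    t = wbar + (1 + 1 / m) * b
    if b > 0:
        lam = (1 + 1 / m) * b / t
        nu_old = (m - 1) / lam**2
        if np.isfinite(nu_com):
            nu_obs = (nu_com + 1) / (nu_com + 3) * nu_com * (1 - lam)
            df = 1.0 / (1.0 / nu_old + 1.0 / nu_obs)
        else:
            df = nu_old
    else:
        df = np.inf
    se = float(np.sqrt(t))
    crit = stats.t.ppf(1 - alpha / 2, df) if np.isfinite(df) else stats.norm.ppf(1 - alpha / 2)
    if se > 0:
        pval = (
            2 * stats.t.sf(abs(qbar) / se, df)
            if np.isfinite(df)
            else 2 * stats.norm.sf(abs(qbar) / se)
        )
    else:
        pval = 1.0 if qbar == 0 else 0.0
    return PooledEstimate(
        qbar=float(qbar),
        wbar=float(wbar),
        b=float(b),
        t=float(t),
        df=float(df),
        se=se,
        ci_low=float(qbar - crit * se),
        ci_high=float(qbar + crit * se),
        p=float(pval),
        m=m,
    )
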