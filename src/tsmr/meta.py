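"""Inverse-variance meta-analysis of log-scale MR estimates across cohorts.

Fixed-effect pooling weights each study by 1/se²; the random-effects model
adds the DerSimonian–Laird moment estimate of between-study variance τ².
Inputs arrive either as (beta, se) pairs or as odds ratios with 95% CIs,
from which the log-scale se is recovered as (ln hi − ln lo)/3.92.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

Z975 = 1.96


@dataclass
class MetaResult:
    model: str
    pooled_beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    pooled_or: float
    or_ci_low: float
    or_ci_high: float
    tau2: float
    q_between: float
    i2: float
    n_studies: int


def se_from_or_ci(ci_low: float, ci_high: float) -> float:
    """Log-scale standard error implied by a printed 95% CI on the OR."""
    return (math.log(ci_high) - math.log(ci_low)) / (2 * Z975)


def meta_analyze(estimates, model: str = "random") -> MetaResult:
    """Pool (beta, se) pairs with fixed or DerSimonian–Laird random effects."""
    if model not in ("fixed", "random"):
        raise ValueError("model must be 'fixed' or 'random'")
    arr = np.asarray(estimates, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("estimates must be a sequence of (beta, se) pairs")
    beta, se = arr[:, 0], arr[:, 1]
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    n = len(beta)
    import warnings as _warnings
    if n < 2:
        _warnings.warn("single estimate: pooling is a passthrough", stacklevel=2)

    w_fixed = 1.0 / se ** 2
    mu_fixed = float(np.sum(w_fixed * beta) / np.sum(w_fixed))
    q = float(np.sum(w_fixed * (beta - mu_fixed) ** 2))
    df = max(n - 1, 1)
    i2 = max(0.0, 100.0 * (q - df) / q) if q > 0 else 0.0

    tau2 = 0.0
    if model == "random" and n > 1:
        c = np.sum(w_fixed) - np.sum(w_fixed ** 2) / np.sum(w_fixed)
        tau2 = max(0.0, (q - (n - 1)) / c) if c > 0 else 0.0
    w = 1.0 / (se ** 2 + tau2)
    mu = float(np.sum(w * beta) / np.sum(w))
    mu_se = float(1.0 / math.sqrt(np.sum(w)))
    pval = float(2.0 * stats.norm.sf(abs(mu) / mu_se))
    lo, hi = mu - Z975 * mu_se, mu + Z975 * mu_se
    return MetaResult(
        model=model, pooled_beta=mu, se=mu_se, ci_low=lo, ci_high=hi, pval=pval,
        pooled_or=math.exp(mu), or_ci_low=math.exp(lo), or_ci_high=math.exp(hi),
        tau2=tau2, q_between=q, i2=i2, n_studies=n,
    )


def meta_from_table(df: pd.DataFrame, model: str = "random") -> MetaResult:
    """Pool a study table with (study, beta, se) or (study, or, ci_low, ci_high)."""
    if {"beta", "se"} <= set(df.columns):
        pairs = df[["beta", "se"]].to_numpy(float)
    elif {"or", "ci_low", "ci_high"} <= set(df.columns):
        pairs = np.column_stack([
            np.log(df["or"].to_numpy(float)),
            [(math.log(h) - math.log(l)) / (2 * Z975)
             for l, h in zip(df["ci_low"], df["ci_high"])],
        ])
    else:
        raise ValueError("table needs (beta, se) or (or, ci_low, ci_high) columns")
    return meta_analyze(pairs, model=model)


def forest_data(df: pd.DataFrame, result: MetaResult) -> pd.DataFrame:
    """Forest-plot data table: per-study rows plus the pooled summary row."""
    if {"beta", "se"} <= set(df.columns):
        beta = df["beta"].to_numpy(float)
        se = df["se"].to_numpy(float)
    else:
        beta = np.log(df["or"].to_numpy(float))
        se = np.array([se_from_or_ci(l, h) for l, h in zip(df["ci_low"], df["ci_high"])])
    rows = pd.DataFrame({
        "study": df.get("study", pd.RangeIndex(len(df)).astype(str)),
        "or": np.exp(beta),
        "or_ci_low": np.exp(beta - Z975 * se),
        "or_ci_high": np.exp(beta + Z975 * se),
        "weight_pct": 100.0 * (1.0 / (se ** 2 + result.tau2))
        / np.sum(1.0 / (se ** 2 + result.tau2)),
    })
    pooled = pd.DataFrame({
        "study": [f"pooled ({result.model})"],
        "or": [result.pooled_or],
        "or_ci_low": [result.or_ci_low],
        "or_ci_high": [result.or_ci_high],
        "weight_pct": [100.0],
    })
    return pd.concat([rows, pooled], ignore_index=True)
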