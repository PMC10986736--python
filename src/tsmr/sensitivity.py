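"""Heterogeneity, pleiotropy, outlier, influence and power diagnostics.

Cochran's Q measures dispersion of the per-SNP Wald ratios around the IVW
estimate; MR-PRESSO tests the same dispersion against a parametric
simulation null and localizes it to individual outlier instruments;
leave-one-out re-estimation quantifies single-SNP influence; the power
calculation follows the non-centrality approximation used by the mRnd
calculator for binary outcomes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import MREstimate, ivw_estimate, wald_ratio
from .io import HarmonizedSet


@dataclass
class HeterogeneityResult:
    q: float
    df: int
    pval: float


@dataclass
class PressoResult:
    rss_obs: float
    global_p: float
    outlier_ids: list[str]
    outlier_p: pd.Series
    corrected_estimate: MREstimate | None
    distortion_p: float | None = None


@dataclass
class PowerResult:
    ncp: float
    power: float
    inputs: dict = field(default_factory=dict)


def cochran_q(h: HarmonizedSet, beta_ivw: float | None = None) -> HeterogeneityResult:
    """Cochran's Q over per-SNP Wald ratios with first-order IVW weights.

    Q = Σ w_j (ratio_j − β_IVW)² with w_j = β_xj²/se_yj²; under
    homogeneity Q ~ χ²(k−1).
    """
    df = h.df
    k = len(df)
    if k < 2:
        raise ValueError("Cochran's Q needs >= 2 instruments")
    bx = df["beta_x"].to_numpy(float)
    by = df["beta_y"].to_numpy(float)
    sy = df["se_y"].to_numpy(float)
    if beta_ivw is None:
        beta_ivw = ivw_estimate(h).beta
    ratios = by / bx
    w = (bx / sy) ** 2
    q = float(np.sum(w * (ratios - beta_ivw) ** 2))
    pval = float(stats.chi2.sf(q, df=k - 1))
    return HeterogeneityResult(q=q, df=k - 1, pval=pval)


def _loo_slopes(bx, by, w):
    """Leave-one-out zero-intercept WLS slopes in O(k) via sum updates."""
    sxx = np.sum(w * bx * bx)
    sxy = np.sum(w * bx * by)
    return (sxy - w * bx * by) / (sxx - w * bx * bx)


def mr_presso(
    h: HarmonizedSet,
    n_sim: int = 5000,
    seed: int = 42,
    outlier_alpha: float = 0.05,
) -> PressoResult:
    """MR-PRESSO global heterogeneity and per-SNP outlier test.

    The observed residual sum of squares uses leave-one-out predictions
    (SNP j's residual is taken against the slope fitted without it, so an
    outlier cannot mask itself).  The null distribution is built by
    redrawing every effect from its sampling distribution around the
    leave-one-out fit, ``n_sim`` times.  Per-SNP empirical p-values are
    Bonferroni-compared against ``outlier_alpha``; the corrected estimate
    is IVW on the non-flagged instruments.
    """
    df = h.df
    k = len(df)
    if k < 4:
        raise ValueError("MR-PRESSO needs >= 4 instruments")
    if n_sim < 1000:
        raise ValueError("n_sim must be >= 1000")
    bx = df["beta_x"].to_numpy(float)
    sx = df["se_x"].to_numpy(float)
    by = df["beta_y"].to_numpy(float)
    sy = df["se_y"].to_numpy(float)
    w = 1.0 / sy ** 2

    slopes_loo = _loo_slopes(bx, by, w)
    obs_res2 = w * (by - slopes_loo * bx) ** 2
    rss_obs = float(np.sum(obs_res2))

    rng = np.random.default_rng(seed)
    # parametric null: expected outcome effect is the LOO prediction
    bx_sim = rng.normal(bx, sx, size=(n_sim, k))
    by_sim = rng.normal(slopes_loo * bx, sy, size=(n_sim, k))
    w_row = w[None, :]
    sxx = np.sum(w_row * bx_sim ** 2, axis=1, keepdims=True)
    sxy = np.sum(w_row * bx_sim * by_sim, axis=1, keepdims=True)
    slopes_sim = (sxy - w_row * bx_sim * by_sim) / (sxx - w_row * bx_sim ** 2)
    res2_sim = w_row * (by_sim - slopes_sim * bx_sim) ** 2
    rss_sim = res2_sim.sum(axis=1)

    global_p = float((1 + np.sum(rss_sim >= rss_obs)) / (1 + n_sim))
    p_snp = (1 + np.sum(res2_sim >= obs_res2[None, :], axis=0)) / (1 + n_sim)
    outlier_mask = p_snp * k < outlier_alpha
    outlier_ids = list(df.loc[outlier_mask, "variant_id"])

    corrected = None
    keep = ~outlier_mask
    if keep.sum() >= 2:
        sub = HarmonizedSet(df=df[keep].reset_index(drop=True), audit=h.audit,
                            n_x=h.n_x, n_y=h.n_y)
        corrected = ivw_estimate(sub)
    distortion_p = None
    if outlier_mask.any() and corrected is not None:
        full = ivw_estimate(h)
        z = (full.beta - corrected.beta) / math.sqrt(full.se ** 2 + corrected.se ** 2)
        distortion_p = float(2.0 * stats.norm.sf(abs(z)))
    return PressoResult(
        rss_obs=rss_obs,
        global_p=global_p,
        outlier_ids=outlier_ids,
        outlier_p=pd.Series(p_snp, index=df["variant_id"].to_numpy()),
        corrected_estimate=corrected,
        distortion_p=distortion_p,
    )


def leave_one_out(h: HarmonizedSet) -> pd.DataFrame:
    """IVW re-estimates dropping one instrument at a time.

    Returns a table with the full-set row (``excluded = "none"``) followed
    by one row per excluded SNP, plus the per-SNP Wald ratio columns used
    for forest and funnel displays.
    """
    df = h.df
    k = len(df)
    if k < 3:
        raise ValueError("leave-one-out needs >= 3 instruments")
    full = ivw_estimate(h)
    rows = [{"excluded": "none", "beta": full.beta, "se": full.se, "pval": full.pval,
             "n_snp": k}]
    for j in range(k):
        sub = HarmonizedSet(df=df.drop(df.index[j]).reset_index(drop=True),
                            audit=h.audit, n_x=h.n_x, n_y=h.n_y)
        est = ivw_estimate(sub)
        rows.append({"excluded": df.iloc[j]["variant_id"], "beta": est.beta,
                     "se": est.se, "pval": est.pval, "n_snp": k - 1})
    return pd.DataFrame(rows)


def single_snp_table(h: HarmonizedSet) -> pd.DataFrame:
    """Per-SNP Wald ratios with precision — forest/funnel plot data."""
    rows = []
    for rec in h.df.itertuples(index=False):
        est = wald_ratio(rec.beta_x, rec.se_x, rec.beta_y, rec.se_y)
        rows.append({"variant_id": rec.variant_id, "beta": est.beta, "se": est.se,
                     "precision": 1.0 / est.se})
    return pd.DataFrame(rows)


def power_binary(n_total: float, case_fraction: float, r2_sum: float,
                 or_: float, alpha: float = 0.05) -> PowerResult:
    """Two-sided MR power for a binary outcome (mRnd-style approximation).

    Non-centrality NCP = N·R²·cf·(1−cf)·(ln OR)², with R² the summed
    variance explained by the instruments in the exposure; power is the
    probability a |Z| test at level α rejects when Z ~ N(√NCP, 1).
    """
    if not (0 <= r2_sum < 1):
        raise ValueError("r2_sum must lie in [0, 1)")
    if or_ <= 0:
        raise ValueError("odds ratio must be positive")
    if not (0 < case_fraction < 1):
        raise ValueError("case_fraction must lie in (0, 1)")
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    ncp = n_total * r2_sum * case_fraction * (1 - case_fraction) * math.log(or_) ** 2
    z = stats.norm.isf(alpha / 2.0)
    mu = math.sqrt(ncp)
    power = float(stats.norm.sf(z - mu) + stats.norm.cdf(-z - mu))
    return PowerResult(
        ncp=ncp,
        power=power,
        inputs={"n": n_total, "case_fraction": case_fraction, "r2_sum": r2_sum,
                "or": or_, "alpha": alpha},
    )
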