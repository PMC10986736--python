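"""Univariable MR estimators: Wald ratio, IVW, MR-Egger, weighted median.

All estimators consume a :class:`~tsmr.io.HarmonizedSet` whose exposure and
outcome effects refer to the same allele.  Effects are reported on the
outcome's scale per SD of exposure (log-odds for binary outcomes), with the
odds-ratio transform ``OR = exp(β)`` and normal-approximation 95% CIs.

The IVW estimator is the multiplicative random-effects form: the slope of
the zero-intercept weighted regression of β_y on β_x with weights 1/se_y²,
its standard error inflated by max(1, √(Q/(k−1))) when Cochran's Q exceeds
its expectation.  MR-Egger frees the intercept — a nonzero intercept is
evidence of directional horizontal pleiotropy.  The weighted median is
consistent when instruments carrying at least half the weight are valid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import HarmonizedSet

Z975 = 1.96  # conventional reporting quantile for 95% CIs


class InsufficientInstrumentsError(ValueError):
    pass


@dataclass
class MREstimate:
    """One method's causal estimate with CI, p, and odds-ratio transform."""

    method: str
    beta: float
    se: float
    n_snp: int
    pval: float = field(default=np.nan)
    ci_low: float = field(init=False)
    ci_high: float = field(init=False)
    or_: float = field(init=False)
    or_ci: tuple[float, float] = field(init=False)
    fdr: float | None = None
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_p: float | None = None

    def __post_init__(self) -> None:
        if np.isnan(self.pval):
            self.pval = 2.0 * stats.norm.sf(abs(self.beta) / self.se) if self.se > 0 else np.nan
        self.ci_low = self.beta - Z975 * self.se
        self.ci_high = self.beta + Z975 * self.se
        self.or_ = math.exp(self.beta)
        self.or_ci = (math.exp(self.ci_low), math.exp(self.ci_high))

    def as_row(self) -> dict:
        nan = float("nan")
        return {
            "method": self.method,
            "n_snp": self.n_snp,
            "beta": self.beta,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "pval": self.pval,
            "fdr": nan if self.fdr is None else self.fdr,
            "or": self.or_,
            "or_ci_low": self.or_ci[0],
            "or_ci_high": self.or_ci[1],
            "egger_intercept": nan if self.egger_intercept is None else self.egger_intercept,
            "egger_intercept_p": nan if self.egger_intercept_p is None else self.egger_intercept_p,
        }


def _arrays(h: HarmonizedSet):
    df = h.df
    return (
        df["beta_x"].to_numpy(float),
        df["se_x"].to_numpy(float),
        df["beta_y"].to_numpy(float),
        df["se_y"].to_numpy(float),
    )


def wald_ratio(beta_x, se_x, beta_y, se_y, second_order: bool = False) -> MREstimate:
    """Single-instrument causal estimate β_y/β_x.

    The default first-order delta-method se is se_y/|β_x|; the
    second-order form adds the exposure's sampling variance,
    √(se_y²/β_x² + β_y²·se_x²/β_x⁴).
    """
    if beta_x == 0:
        raise ZeroDivisionError("undefined Wald ratio: beta_x = 0")
    beta = beta_y / beta_x
    if second_order:
        se = math.sqrt(se_y ** 2 / beta_x ** 2 + beta_y ** 2 * se_x ** 2 / beta_x ** 4)
    else:
        se = se_y / abs(beta_x)
    return MREstimate(method="wald", beta=beta, se=se, n_snp=1)


def ivw_estimate(h: HarmonizedSet) -> MREstimate:
    """Multiplicative random-effects inverse-variance-weighted estimate."""
    bx, _, by, sy = _arrays(h)
    k = len(bx)
    if k < 1:
        raise InsufficientInstrumentsError("IVW needs at least one instrument")
    w = 1.0 / sy ** 2
    if not np.all(np.isfinite(w)) or np.any(w <= 0):
        raise ValueError("nonpositive or infinite weights")
    sxx = float(np.sum(w * bx * bx))
    beta = float(np.sum(w * bx * by)) / sxx
    q = float(np.sum(w * (by - beta * bx) ** 2))
    # degenerate single-instrument case collapses to the Wald ratio
    scale = max(1.0, math.sqrt(q / (k - 1))) if k > 1 else 1.0
    se = scale / math.sqrt(sxx)
    return MREstimate(method="ivw", beta=beta, se=se, n_snp=k)


def egger_estimate(h: HarmonizedSet) -> MREstimate:
    """MR-Egger regression: free-intercept WLS of β_y on β_x.

    Exposure effects are coerced positive first (flipping both betas),
    the conventional orientation for interpreting the intercept.  Slope
    and intercept standard errors carry the same multiplicative
    heterogeneity inflation as IVW, floored at 1.
    """
    bx, _, by, sy = _arrays(h)
    k = len(bx)
    if k < 3:
        raise InsufficientInstrumentsError("MR-Egger needs >= 3 instruments")
    sign = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * sign, by * sign
    w = 1.0 / sy ** 2
    X = np.column_stack([np.ones(k), bx])
    XtW = X.T * w
    xtwx = XtW @ X
    coef = np.linalg.solve(xtwx, XtW @ by)
    resid = by - X @ coef
    sigma2 = float(np.sum(w * resid ** 2)) / (k - 2)
    scale2 = max(1.0, sigma2)
    cov = np.linalg.inv(xtwx) * scale2
    inter, beta = float(coef[0]), float(coef[1])
    se_inter, se_beta = math.sqrt(cov[0, 0]), math.sqrt(cov[1, 1])
    est = MREstimate(method="egger", beta=beta, se=se_beta, n_snp=k)
    est.egger_intercept = inter
    est.egger_intercept_se = se_inter
    est.egger_intercept_p = 2.0 * stats.norm.sf(abs(inter) / se_inter)
    return est


def weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Weighted median with linear interpolation at cumulative weight 0.5."""
    order = np.argsort(values)
    v = np.asarray(values, float)[order]
    w = np.asarray(weights, float)[order]
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    cum = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    if 0.5 <= cum[0]:
        return float(v[0])
    if cum[-1] <= 0.5:
        return float(v[-1])
    return float(np.interp(0.5, cum, v))


def weighted_median_estimate(h: HarmonizedSet, n_boot: int = 1000, seed: int = 42) -> MREstimate:
    """Weighted median of per-SNP Wald ratios, inverse-variance weighted.

    The standard error comes from a parametric bootstrap: exposure and
    outcome effects are redrawn from their sampling distributions and the
    weighted median recomputed ``n_boot`` times.
    """
    bx, sx, by, sy = _arrays(h)
    k = len(bx)
    if k < 3:
        raise InsufficientInstrumentsError("weighted median needs >= 3 instruments")
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    ratios = by / bx
    w = (bx / sy) ** 2  # inverse first-order ratio variance
    beta = weighted_median(ratios, w)

    rng = np.random.default_rng(seed)
    bx_b = rng.normal(bx, sx, size=(n_boot, k))
    by_b = rng.normal(by, sy, size=(n_boot, k))
    ratios_b = by_b / bx_b
    w_b = (bx_b / sy) ** 2
    order = np.argsort(ratios_b, axis=1)
    v_sorted = np.take_along_axis(ratios_b, order, axis=1)
    w_sorted = np.take_along_axis(w_b, order, axis=1)
    cum = (np.cumsum(w_sorted, axis=1) - 0.5 * w_sorted) / np.sum(w_sorted, axis=1, keepdims=True)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        boots[i] = np.interp(0.5, cum[i], v_sorted[i])
    se = float(np.std(boots, ddof=1))
    return MREstimate(method="weighted_median", beta=beta, se=se, n_snp=k)


def beta_to_or(beta: float, se: float = 0.0):
    """Exponentiate a log-odds effect: OR and its 95% CI."""
    return math.exp(beta), (math.exp(beta - Z975 * se), math.exp(beta + Z975 * se))


def risk_reduction_percent(or_: float) -> float:
    """Percent risk reduction implied by an odds ratio: 100·(1 − OR)."""
    if or_ <= 0:
        raise ValueError("odds ratio must be positive")
    return 100.0 * (1.0 - or_)


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def estimate_all(h: HarmonizedSet, n_boot: int = 1000, seed: int = 42) -> list[MREstimate]:
    """Run the estimator battery appropriate to the instrument count."""
    k = len(h)
    if k == 0:
        raise InsufficientInstrumentsError("no instruments")
    if k == 1:
        row = h.df.iloc[0]
        return [wald_ratio(row["beta_x"], row["se_x"], row["beta_y"], row["se_y"])]
    out = [ivw_estimate(h)]
    if k >= 3:
        out.append(egger_estimate(h))
        out.append(weighted_median_estimate(h, n_boot=n_boot, seed=seed))
    return out


def estimates_table(estimates: list[MREstimate], fdr_family: bool = False) -> pd.DataFrame:
    """Collect estimates into the canonical results table.

    With ``fdr_family=True`` the listed estimates form one multiple-testing
    family and BH-adjusted p-values are filled in.
    """
    rows = [e.as_row() for e in estimates]
    df = pd.DataFrame(rows)
    if fdr_family and len(df):
        df["fdr"] = bh_fdr(df["pval"].to_numpy())
    return df
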