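"""Lightweight LD-score regression: SNP heritability and genetic correlation.

The univariate model regresses per-SNP association χ² (= z²) on LD scores:
E[χ²_j] = 1 + N·h²·l_j/M, so the slope on (N/M)·l_j estimates h² and the
intercept — 1 in the absence of confounding — absorbs cryptic relatedness
and population stratification.  The bivariate model regresses z₁ⱼ·z₂ⱼ on
(√(N₁N₂)/M)·l_j; its slope is the genetic covariance and
r_g = gencov/√(h²₁·h²₂).  Standard errors come from a delete-a-block
jackknife over contiguous SNP blocks.

This is a simplified estimator: a single heteroskedasticity-weighting pass
(weights from an initial unweighted fit) instead of the reference
implementation's iterated weights, and no reference-panel LD — LD scores
are supplied by the caller.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats


class UnidentifiableError(ValueError):
    pass


@dataclass
class H2Result:
    h2: float
    intercept: float
    se_h2: float
    n_blocks: int
    weight_h2: float = 0.0  # pre-fit h2 used to build the regression weights


@dataclass
class LdscResult:
    h2_1: float
    h2_2: float
    intercept_1: float
    intercept_2: float
    gencov: float
    gencov_intercept: float
    rg: float
    se_rg: float
    pval_rg: float
    n_blocks: int
    rg_out_of_bounds: bool = False


def _wls(x, y, w, fit_intercept=True):
    if fit_intercept:
        X = np.column_stack([np.ones_like(x), x])
    else:
        X = x[:, None]
    XtW = X.T * w
    coef = np.linalg.solve(XtW @ X, XtW @ y)
    if fit_intercept:
        return float(coef[1]), float(coef[0])
    return float(coef[0]), 0.0


def _block_bounds(m: int, n_blocks: int):
    n_blocks = max(2, min(n_blocks, m))
    edges = np.linspace(0, m, n_blocks + 1).astype(int)
    return [(edges[i], edges[i + 1]) for i in range(n_blocks)]


def _jackknife(values: np.ndarray):
    b = len(values)
    mean = values.mean()
    var = (b - 1) / b * np.sum((values - mean) ** 2)
    return math.sqrt(var)


def ldsc_h2(z, ld_scores, n, m=None, n_blocks: int = 200,
            fit_intercept: bool = True) -> H2Result:
    """Estimate SNP heritability from z-scores and LD scores."""
    z = np.asarray(z, float)
    l = np.asarray(ld_scores, float)
    if n <= 0:
        raise ValueError("n must be positive")
    m = int(m) if m is not None else len(z)
    if m <= 0:
        raise ValueError("m must be positive")
    if np.allclose(l, l[0]):
        raise UnidentifiableError("all LD scores equal: slope is unidentifiable")
    x = (n / m) * l
    y = z ** 2
    slope0, _ = _wls(x, y, np.ones_like(x), fit_intercept)
    h2_0 = min(max(slope0, 0.0), 0.99)
    w = 1.0 / (2.0 * (1.0 + n * h2_0 * l / m) ** 2)
    slope, inter = _wls(x, y, w, fit_intercept)
    if not fit_intercept:
        inter = 1.0
    bounds = _block_bounds(len(z), n_blocks)
    jk = np.empty(len(bounds))
    for i, (a, b) in enumerate(bounds):
        keep = np.ones(len(z), bool)
        keep[a:b] = False
        jk[i], _ = _wls(x[keep], y[keep], w[keep], fit_intercept)
    return H2Result(h2=slope, intercept=inter, se_h2=_jackknife(jk),
                    n_blocks=len(bounds), weight_h2=h2_0)


def ldsc_rg(z1, z2, ld_scores, n1, n2, m=None, n_blocks: int = 200,
            overlap_intercept: bool = False) -> LdscResult:
    """Cross-trait genetic correlation by LD-score regression.

    ``overlap_intercept=False`` (the default) estimates the cross-trait
    intercept freely; setting it constrains the intercept to 0, the value
    implied by non-overlapping samples.
    """
    z1 = np.asarray(z1, float)
    z2 = np.asarray(z2, float)
    l = np.asarray(ld_scores, float)
    m = int(m) if m is not None else len(z1)
    if len(z1) != len(z2) or len(z1) != len(l):
        raise ValueError("z1, z2 and ld_scores must be aligned")

    h1 = ldsc_h2(z1, l, n1, m, n_blocks)
    h2 = ldsc_h2(z2, l, n2, m, n_blocks)
    if h1.h2 <= 0 or h2.h2 <= 0:
        raise UnidentifiableError("rg undefined: non-positive heritability estimate")

    x = (math.sqrt(n1 * n2) / m) * l
    y = z1 * z2
    # symmetric heteroskedasticity weights built from the same pre-fit h2
    # values the univariate regressions used: for a trait against itself the
    # cross weights are then exactly proportional to the univariate weights,
    # so the cross slope reduces to the h2 slope and rg to 1
    h1c = h1.weight_h2
    h2c = h2.weight_h2
    w = 1.0 / ((1.0 + n1 * h1c * l / m) * (1.0 + n2 * h2c * l / m))
    fit_int = not overlap_intercept
    gencov, ginter = _wls(x, y, w, fit_int)
    rg = gencov / math.sqrt(h1.h2 * h2.h2)

    x1, x2 = (n1 / m) * l, (n2 / m) * l
    y1, y2 = z1 ** 2, z2 ** 2
    w1 = 1.0 / (2.0 * (1.0 + n1 * h1c * l / m) ** 2)
    w2 = 1.0 / (2.0 * (1.0 + n2 * h2c * l / m) ** 2)
    bounds = _block_bounds(len(z1), n_blocks)
    jk = np.empty(len(bounds))
    for i, (a, b) in enumerate(bounds):
        keep = np.ones(len(z1), bool)
        keep[a:b] = False
        g_b, _ = _wls(x[keep], y[keep], w[keep], fit_int)
        h1_b, _ = _wls(x1[keep], y1[keep], w1[keep], True)
        h2_b, _ = _wls(x2[keep], y2[keep], w2[keep], True)
        denom = math.sqrt(max(h1_b * h2_b, 1e-12))
        jk[i] = g_b / denom
    se_rg = _jackknife(jk)
    pval = float(2.0 * stats.norm.sf(abs(rg) / se_rg)) if se_rg > 0 else float("nan")
    return LdscResult(
        h2_1=h1.h2, h2_2=h2.h2,
        intercept_1=h1.intercept, intercept_2=h2.intercept,
        gencov=gencov, gencov_intercept=ginter,
        rg=rg, se_rg=se_rg, pval_rg=pval,
        n_blocks=len(bounds),
        rg_out_of_bounds=abs(rg) > 1.25,
    )
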