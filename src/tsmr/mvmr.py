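"""Multivariable MR direct effects and two-step mediation decomposition.

Multivariable MR regresses SNP-outcome effects jointly on several
SNP-exposure effect vectors (no intercept, weights 1/se_y²); the primary
exposure's coefficient is its direct effect conditional on the other
exposures.  The mediation decomposition multiplies the exposure→mediator
estimate by the mediator→outcome effect conditional on the exposure to get
the indirect effect, defines direct = total − indirect, and reports the
proportion mediated 100·indirect/total with a Sobel-type delta-method
standard error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import MREstimate, Z975
from .io import HarmonizedSet


class CollinearityError(np.linalg.LinAlgError):
    pass


@dataclass
class MVMRResult:
    """Per-exposure direct effects from one joint weighted regression."""

    exposures: list[str]
    beta: dict[str, float]
    se: dict[str, float]
    pval: dict[str, float]
    n_snp: int

    def or_ci(self, name: str) -> tuple[float, float, float]:
        b, s = self.beta[name], self.se[name]
        return math.exp(b), math.exp(b - Z975 * s), math.exp(b + Z975 * s)

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for name in self.exposures:
            or_, lo, hi = self.or_ci(name)
            rows.append({"exposure": name, "n_snp": self.n_snp,
                         "direct_beta": self.beta[name], "se": self.se[name],
                         "pval": self.pval[name], "or": or_,
                         "or_ci_low": lo, "or_ci_high": hi})
        return pd.DataFrame(rows)


@dataclass
class MediationResult:
    mediator: str
    total: float
    total_se: float
    direct: float
    direct_se: float
    indirect: float
    indirect_se: float
    proportion: float | None
    pval: float
    inconsistent: bool = False
    warnings: list[str] = field(default_factory=list)

    def ci(self, which: str) -> tuple[float, float]:
        b = getattr(self, which)
        s = getattr(self, f"{which}_se")
        return b - Z975 * s, b + Z975 * s

    def as_row(self) -> dict:
        return {
            "mediator": self.mediator,
            "total": self.total, "total_ci_low": self.ci("total")[0],
            "total_ci_high": self.ci("total")[1],
            "direct": self.direct, "direct_ci_low": self.ci("direct")[0],
            "direct_ci_high": self.ci("direct")[1],
            "indirect": self.indirect, "indirect_ci_low": self.ci("indirect")[0],
            "indirect_ci_high": self.ci("indirect")[1],
            "proportion_pct": self.proportion,
            "pval": self.pval,
            "inconsistent": self.inconsistent,
        }


def mvmr_ivw(exposure_betas: pd.DataFrame, beta_y, se_y,
             exposure_names: list[str] | None = None) -> MVMRResult:
    """Weighted multivariable regression of outcome effects on exposures.

    ``exposure_betas`` is a (k instruments × p exposures) table; the
    regression has no intercept and weights 1/se_y², with the same
    multiplicative heterogeneity inflation (floored at 1) as univariable
    IVW.  Exposure columns that are identically zero contribute nothing
    and get coefficient 0; genuinely collinear nonzero columns raise
    :class:`CollinearityError` naming the offending exposures.
    """
    X = np.asarray(exposure_betas, dtype=float)
    names = exposure_names or list(getattr(exposure_betas, "columns",
                                           [f"x{i}" for i in range(X.shape[1])]))
    y = np.asarray(beta_y, dtype=float)
    sy = np.asarray(se_y, dtype=float)
    k, p = X.shape
    if k < p + 1:
        raise ValueError("need more instruments than exposures")
    nonzero = [j for j in range(p) if np.any(X[:, j] != 0)]
    Xn = X[:, nonzero]
    if Xn.shape[1] and np.linalg.matrix_rank(Xn) < Xn.shape[1]:
        raise CollinearityError(
            "collinear exposure effect vectors among: "
            + ", ".join(names[j] for j in nonzero)
        )
    w = 1.0 / sy ** 2
    beta = np.zeros(p)
    se = np.full(p, np.nan)
    if Xn.shape[1]:
        XtW = Xn.T * w
        xtwx = XtW @ Xn
        coef = np.linalg.solve(xtwx, XtW @ y)
        resid = y - Xn @ coef
        dof = max(k - Xn.shape[1], 1)
        sigma2 = float(np.sum(w * resid ** 2)) / dof
        cov = np.linalg.inv(xtwx) * max(1.0, sigma2)
        for i, j in enumerate(nonzero):
            beta[j] = coef[i]
            se[j] = math.sqrt(cov[i, i])
    pvals = {n: float(2.0 * stats.norm.sf(abs(beta[j]) / se[j])) if np.isfinite(se[j]) else 1.0
             for j, n in enumerate(names)}
    return MVMRResult(
        exposures=names,
        beta={n: float(beta[j]) for j, n in enumerate(names)},
        se={n: float(se[j]) for j, n in enumerate(names)},
        pval=pvals,
        n_snp=k,
    )


def mvmr_from_harmonized(h: HarmonizedSet, extra_names: list[str],
                         primary: str = "exposure") -> MVMRResult:
    """Run MVMR on a jointly harmonized set (see ``harmonize_multi``)."""
    cols = {primary: h.df["beta_x"]}
    for n in extra_names:
        cols[n] = h.df[f"beta_{n}"]
    X = pd.DataFrame(cols)
    return mvmr_ivw(X, h.df["beta_y"], h.df["se_y"])


def mediation_effects(total: MREstimate, exp_to_med: MREstimate,
                      med_to_out_beta: float, med_to_out_se: float,
                      mediator: str = "mediator") -> MediationResult:
    """Two-step mediation decomposition on the log-odds scale.

    indirect = β(exposure→mediator) · β(mediator→outcome | exposure),
    direct = total − indirect (so the identity total = direct + indirect
    holds by construction), proportion mediated = 100·indirect/total.
    The indirect-effect standard error uses the product delta method
    √(β₁²σ₂² + β₂²σ₁²) and the p-value the corresponding z-test.
    """
    b1, s1 = exp_to_med.beta, exp_to_med.se
    b2, s2 = med_to_out_beta, med_to_out_se
    indirect = b1 * b2
    ind_se = math.sqrt(b1 ** 2 * s2 ** 2 + b2 ** 2 * s1 ** 2)
    direct = total.beta - indirect
    direct_se = math.sqrt(total.se ** 2 + ind_se ** 2)
    warnings: list[str] = []
    inconsistent = False
    if total.beta == 0:
        proportion = None
        warnings.append("total effect is zero; proportion mediated undefined")
    else:
        proportion = 100.0 * indirect / total.beta
        if proportion < 0 or proportion > 100:
            inconsistent = True
            warnings.append("inconsistent mediation: proportion outside [0, 100]%")
    pval = float(2.0 * stats.norm.sf(abs(indirect) / ind_se)) if ind_se > 0 else 1.0
    return MediationResult(
        mediator=mediator,
        total=total.beta, total_se=total.se,
        direct=direct, direct_se=direct_se,
        indirect=indirect, indirect_se=ind_se,
        proportion=proportion, pval=pval,
        inconsistent=inconsistent, warnings=warnings,
    )


def mediation_table(results: list[MediationResult]) -> pd.DataFrame:
    return pd.DataFrame([r.as_row() for r in results])
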