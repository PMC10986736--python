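"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator emulates the data layout of a two-sample Mendelian
randomization study: an exposure GWAS in one cohort, an outcome GWAS in a
second non-overlapping cohort, optional mediator GWAS, block LD structure,
and z-score pairs following the LD-score regression model.  Everything is
simulated directly on the summary-statistic scale (no individual-level
genotypes): per-SNP causal effects are drawn spike-and-slab, convolved with
block LD to give marginal effects, and observed with sampling noise whose
variance follows the standard 1 / (2·MAF·(1−MAF)·N) approximation.

Defaults mirror the discovery design of a UK-Biobank-scale dietary exposure
(N ≈ 460k, SD units, h² a few percent) against a large case-control
outcome GWAS (N ≈ 934k, log-odds scale) with a protective causal effect
θ = ln 0.614 ≈ −0.488 per SD.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .io import SummaryStatSet

#: discovery-scale defaults: exposure cohort, outcome cases/controls
DEFAULT_N_EXPOSURE = 460_443
DEFAULT_N_OUTCOME = 80_154 + 853_816
DEFAULT_CASE_FRACTION = 80_154 / DEFAULT_N_OUTCOME
DEFAULT_THETA = math.log(0.614)

_NON_PALINDROMIC_PAIRS = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: genomic spacing between adjacent simulated variants (bp); with the
#: conventional 10,000 kb clump window this puts ±100 neighbours in range
POS_SPACING = 100_000


class InvalidParameterError(ValueError):
    """Raised for generator parameters outside their documented domain."""


@dataclass
class SyntheticConfig:
    """Generative parameters for a two-sample summary-statistics system.

    ``theta`` is the causal effect of one SD of exposure on the outcome
    (log-odds for a binary outcome).  ``mediator_spec`` lists
    ``(beta_exposure_to_mediator, beta_mediator_to_outcome)`` pairs; when it
    is set, ``theta`` plays the role of the direct (unmediated) effect.
    """

    n_snps: int = 5000
    n_exposure: int = DEFAULT_N_EXPOSURE
    n_outcome: int = DEFAULT_N_OUTCOME
    maf_range: tuple[float, float] = (0.05, 0.5)
    prop_causal: float = 0.03
    exposure_h2: float = 0.04
    theta: float = DEFAULT_THETA
    pleiotropy_mode: str = "none"  # none | balanced | directional
    pleiotropy_sd: float = 0.0
    mediator_spec: list[tuple[float, float]] | None = None
    ld_block_size: int = 10
    ld_rho: float = 0.0
    seed: int = 42
    # secondary knobs
    outcome_case_fraction: float | None = DEFAULT_CASE_FRACTION
    n_mediator: int | None = None
    mediator_h2: float = 0.10
    palindromic_rate: float = 0.01
    strand_flip_rate: float = 0.01
    allele_swap_rate: float = 0.05

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise InvalidParameterError("maf_range must lie inside (0, 0.5]")
        if not (0 < self.prop_causal <= 1):
            raise InvalidParameterError("prop_causal must be in (0, 1]")
        if not (0 <= self.exposure_h2 < 1):
            raise InvalidParameterError("exposure_h2 must be in [0, 1)")
        if self.exposure_h2 > 0 and round(self.prop_causal * self.n_snps) < 1:
            raise InvalidParameterError(
                "exposure_h2 > 0 requires at least one causal SNP (prop_causal too small)"
            )
        if self.pleiotropy_mode not in ("none", "balanced", "directional"):
            raise InvalidParameterError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")
        if not (0 <= self.ld_rho < 1):
            raise InvalidParameterError("ld_rho must be in [0, 1)")
        if self.ld_block_size < 1:
            raise InvalidParameterError("ld_block_size must be >= 1")


@dataclass
class TruthManifest:
    """Ground truth behind one simulated system, for parameter recovery."""

    theta: float
    per_snp_beta_x: np.ndarray
    per_snp_alpha: np.ndarray
    true_indirect: list[float] = field(default_factory=list)
    true_total: float | None = None
    true_h2: dict = field(default_factory=dict)
    true_rg: float | None = None

    def __post_init__(self) -> None:
        if self.true_rg is not None and abs(self.true_rg) > 1:
            raise InvalidParameterError("true_rg must lie in [-1, 1]")

    def to_json(self, path) -> None:
        d = asdict(self)
        d["per_snp_beta_x"] = np.asarray(self.per_snp_beta_x).tolist()
        d["per_snp_alpha"] = np.asarray(self.per_snp_alpha).tolist()
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "TruthManifest":
        with open(path) as fh:
            d = json.load(fh)
        d["per_snp_beta_x"] = np.asarray(d["per_snp_beta_x"])
        d["per_snp_alpha"] = np.asarray(d["per_snp_alpha"])
        return cls(**d)


# ---------------------------------------------------------------------------
# LD structure
# ---------------------------------------------------------------------------

def make_ld_blocks(n_snps: int, block_size: int, rho: float):
    """Block-diagonal AR(1)-style LD: r = rho^|i−j| within a block, 0 across.

    Returns the dense correlation matrix (O(n²) memory — intended for
    instrument-scale problems) and the per-SNP LD scores
    l_j = Σ_k r²_jk, which include the self term (so l_j = 1 at rho = 0).
    """
    if not (0 <= rho < 1):
        raise InvalidParameterError("rho must be in [0, 1)")
    if block_size < 1 or n_snps < 1:
        raise InvalidParameterError("n_snps and block_size must be >= 1")
    R = np.zeros((n_snps, n_snps))
    scores = np.empty(n_snps)
    for start in range(0, n_snps, block_size):
        stop = min(start + block_size, n_snps)
        idx = np.arange(stop - start)
        block = rho ** np.abs(idx[:, None] - idx[None, :])
        R[start:stop, start:stop] = block
        scores[start:stop] = (block ** 2).sum(axis=1)
    return R, scores


def ld_scores_for(n_snps: int, block_size: int, rho: float) -> np.ndarray:
    """Per-SNP LD scores of the block model without materializing the matrix."""
    if not (0 <= rho < 1):
        raise InvalidParameterError("rho must be in [0, 1)")
    scores = np.empty(n_snps)
    for start in range(0, n_snps, block_size):
        stop = min(start + block_size, n_snps)
        idx = np.arange(stop - start)
        block2 = rho ** (2 * np.abs(idx[:, None] - idx[None, :]))
        scores[start:stop] = block2.sum(axis=1)
    return scores


def _blockwise(n_snps: int, block_size: int, rho: float):
    """Yield (start, stop, R_block, chol_block) over the block-diagonal LD."""
    for start in range(0, n_snps, block_size):
        stop = min(start + block_size, n_snps)
        idx = np.arange(stop - start)
        block = rho ** np.abs(idx[:, None] - idx[None, :])
        yield start, stop, block, np.linalg.cholesky(block)


def _ld_convolve(vec: np.ndarray, cfg: SyntheticConfig) -> np.ndarray:
    if cfg.ld_rho == 0:
        return vec
    out = np.empty_like(vec)
    for start, stop, block, _ in _blockwise(len(vec), cfg.ld_block_size, cfg.ld_rho):
        out[start:stop] = block @ vec[start:stop]
    return out


def _ld_noise(rng: np.random.Generator, se: np.ndarray, cfg: SyntheticConfig) -> np.ndarray:
    """Sampling noise, correlated within LD blocks (exact when se is constant
    within a block, first-order otherwise)."""
    eps = rng.standard_normal(len(se))
    if cfg.ld_rho == 0:
        return se * eps
    out = np.empty_like(eps)
    for start, stop, _, L in _blockwise(len(se), cfg.ld_block_size, cfg.ld_rho):
        out[start:stop] = L @ eps[start:stop]
    return se * out


# ---------------------------------------------------------------------------
# Core two-sample generator
# ---------------------------------------------------------------------------

def _spike_slab_effects(rng, n_snps, prop_causal, h2, het) -> np.ndarray:
    """Per-SNP causal effects: a random causal subset with normal effects,
    rescaled so Σ 2p(1−p)β² equals h2 exactly."""
    m = int(round(prop_causal * n_snps))
    beta = np.zeros(n_snps)
    if m == 0 or h2 == 0:
        return beta
    causal = rng.choice(n_snps, size=m, replace=False)
    raw = rng.standard_normal(m)
    scale2 = (het[causal] * raw ** 2).sum()
    beta[causal] = raw * math.sqrt(h2 / scale2)
    return beta


def _draw_alphas(rng, beta_x, mode, sd) -> np.ndarray:
    """Direct SNP→outcome (pleiotropic) effects on the exposure's causal set."""
    alpha = np.zeros_like(beta_x)
    if mode == "none" or sd == 0:
        return alpha
    causal = np.flatnonzero(beta_x)
    draws = rng.normal(0.0, sd, size=len(causal))
    if mode == "balanced":
        draws = draws - draws.mean()  # zero mean by construction
    else:  # directional
        draws = draws - draws.mean() + sd
    alpha[causal] = draws
    return alpha


def _sumstats_frame(cfg, vids, chrom, pos, ea, oa, eaf, beta_hat, se, n,
                    n_case=np.nan, n_control=np.nan, trait="") -> SummaryStatSet:
    with np.errstate(divide="ignore"):
        pval = stats.chi2.sf((beta_hat / se) ** 2, df=1)
    pval = np.clip(pval, np.nextafter(0, 1), 1.0)
    df = pd.DataFrame(
        {
            "variant_id": vids,
            "chrom": chrom,
            "pos": pos,
            "effect_allele": ea,
            "other_allele": oa,
            "eaf": eaf,
            "beta": beta_hat,
            "se": se,
            "pval": pval,
            "n": n,
            "n_case": n_case,
            "n_control": n_control,
        }
    )
    return SummaryStatSet(df=df, trait=trait)


def _base_layout(cfg: SyntheticConfig, rng):
    """Variant ids, positions, alleles and frequencies shared by all traits."""
    n = cfg.n_snps
    vids = np.array([f"rs{i:07d}" for i in range(1, n + 1)])
    chrom = np.full(n, "1", dtype=object)
    pos = (np.arange(n) + 1) * POS_SPACING
    maf = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=n)
    eaf = np.where(rng.random(n) < 0.5, maf, 1.0 - maf)
    pal = rng.random(n) < cfg.palindromic_rate
    pair_idx = rng.integers(0, len(_NON_PALINDROMIC_PAIRS), size=n)
    pal_idx = rng.integers(0, len(_PALINDROMIC_PAIRS), size=n)
    ea = np.empty(n, dtype=object)
    oa = np.empty(n, dtype=object)
    for i in range(n):
        a, b = (_PALINDROMIC_PAIRS[pal_idx[i]] if pal[i]
                else _NON_PALINDROMIC_PAIRS[pair_idx[i]])
        ea[i], oa[i] = a, b
    return vids, chrom, pos, ea, oa, eaf, maf


def _recode_alleles(cfg, rng, ea, oa, eaf, beta):
    """Re-express a table's alleles as a second consortium might: a fraction
    swapped (effect/other exchanged, beta negated, eaf complemented) and a
    fraction reported on the opposite strand (complement alleles)."""
    ea, oa = ea.copy(), oa.copy()
    eaf, beta = eaf.copy(), beta.copy()
    n = len(ea)
    swap = rng.random(n) < cfg.allele_swap_rate
    for i in np.flatnonzero(swap):
        ea[i], oa[i] = oa[i], ea[i]
    eaf[swap] = 1.0 - eaf[swap]
    beta[swap] = -beta[swap]
    flip = rng.random(n) < cfg.strand_flip_rate
    for i in np.flatnonzero(flip):
        ea[i], oa[i] = _COMPLEMENT[ea[i]], _COMPLEMENT[oa[i]]
    return ea, oa, eaf, beta


def simulate_two_sample_gwas(cfg: SyntheticConfig):
    """Simulate exposure and outcome summary statistics plus their truth.

    Returns ``(exposure, outcome, manifest)``.  Estimation noise is
    independent between the two samples (non-overlapping cohorts); the
    outcome's standard errors use the case/control effective sample size
    when ``outcome_case_fraction`` is set.
    """
    ss = np.random.SeedSequence(cfg.seed)
    r_layout, r_fx, r_nx, r_ny, r_code = [np.random.default_rng(s) for s in ss.spawn(5)]

    vids, chrom, pos, ea, oa, eaf, maf = _base_layout(cfg, r_layout)
    het = 2.0 * eaf * (1.0 - eaf)

    beta_x = _spike_slab_effects(r_fx, cfg.n_snps, cfg.prop_causal, cfg.exposure_h2, het)
    alpha = _draw_alphas(r_fx, beta_x, cfg.pleiotropy_mode, cfg.pleiotropy_sd)

    se_x = 1.0 / np.sqrt(het * cfg.n_exposure)
    beta_hat_x = _ld_convolve(beta_x, cfg) + _ld_noise(r_nx, se_x, cfg)

    v = 1.0
    n_case = n_control = np.nan
    if cfg.outcome_case_fraction is not None:
        cf = cfg.outcome_case_fraction
        v = cf * (1.0 - cf)
        n_case = round(cf * cfg.n_outcome)
        n_control = cfg.n_outcome - n_case
    se_y = 1.0 / np.sqrt(het * cfg.n_outcome * v)
    beta_y_true = cfg.theta * beta_x + alpha
    beta_hat_y = _ld_convolve(beta_y_true, cfg) + _ld_noise(r_ny, se_y, cfg)

    exposure = _sumstats_frame(cfg, vids, chrom, pos, ea, oa, eaf,
                               beta_hat_x, se_x, cfg.n_exposure, trait="exposure")
    ea_y, oa_y, eaf_y, bhat_y = _recode_alleles(cfg, r_code, ea, oa, eaf, beta_hat_y)
    outcome = _sumstats_frame(cfg, vids, chrom, pos, ea_y, oa_y, eaf_y,
                              bhat_y, se_y, cfg.n_outcome,
                              n_case=n_case, n_control=n_control, trait="outcome")
    manifest = TruthManifest(
        theta=cfg.theta,
        per_snp_beta_x=beta_x,
        per_snp_alpha=alpha,
        true_total=cfg.theta,
        true_h2={"exposure": cfg.exposure_h2},
    )
    return exposure, outcome, manifest


def simulate_mediation_system(cfg: SyntheticConfig):
    """Exposure → mediator(s) → outcome chain with known decomposition.

    ``cfg.theta`` is the direct effect; each ``(b_xm, b_my)`` in
    ``cfg.mediator_spec`` contributes an indirect effect b_xm·b_my, so the
    true total is θ_direct + Σ b_xm·b_my.  Each mediator also carries its
    own polygenic background (heritability ``cfg.mediator_h2``) giving it
    instruments of its own for multivariable MR.

    Returns ``(exposure, mediators, outcome, manifest)`` with ``mediators``
    a name → SummaryStatSet dict (``m1``, ``m2``, ...).
    """
    if not cfg.mediator_spec:
        raise InvalidParameterError("mediator_spec must be non-empty")
    ss = np.random.SeedSequence(cfg.seed)
    streams = ss.spawn(5 + 2 * len(cfg.mediator_spec))
    r_layout, r_fx, r_nx, r_ny, r_code = [np.random.default_rng(s) for s in streams[:5]]

    vids, chrom, pos, ea, oa, eaf, maf = _base_layout(cfg, r_layout)
    het = 2.0 * eaf * (1.0 - eaf)
    beta_x = _spike_slab_effects(r_fx, cfg.n_snps, cfg.prop_causal, cfg.exposure_h2, het)
    alpha = _draw_alphas(r_fx, beta_x, cfg.pleiotropy_mode, cfg.pleiotropy_sd)

    se_x = 1.0 / np.sqrt(het * cfg.n_exposure)
    beta_hat_x = _ld_convolve(beta_x, cfg) + _ld_noise(r_nx, se_x, cfg)
    exposure = _sumstats_frame(cfg, vids, chrom, pos, ea, oa, eaf,
                               beta_hat_x, se_x, cfg.n_exposure, trait="exposure")

    n_med = cfg.n_mediator or cfg.n_exposure
    se_m = 1.0 / np.sqrt(het * n_med)
    mediators: dict[str, SummaryStatSet] = {}
    beta_m_true_all = []
    for i, (b_xm, b_my) in enumerate(cfg.mediator_spec, start=1):
        r_fm = np.random.default_rng(streams[3 + 2 * i])
        r_nm = np.random.default_rng(streams[4 + 2 * i])
        gamma = _spike_slab_effects(r_fm, cfg.n_snps, cfg.prop_causal, cfg.mediator_h2, het)
        beta_m_true = b_xm * beta_x + gamma
        beta_m_true_all.append((b_my, beta_m_true))
        beta_hat_m = _ld_convolve(beta_m_true, cfg) + _ld_noise(r_nm, se_m, cfg)
        ea_m, oa_m, eaf_m, bh_m = _recode_alleles(cfg, r_code, ea, oa, eaf, beta_hat_m)
        mediators[f"m{i}"] = _sumstats_frame(
            cfg, vids, chrom, pos, ea_m, oa_m, eaf_m, bh_m, se_m, n_med, trait=f"m{i}"
        )

    v = 1.0
    n_case = n_control = np.nan
    if cfg.outcome_case_fraction is not None:
        cf = cfg.outcome_case_fraction
        v = cf * (1.0 - cf)
        n_case = round(cf * cfg.n_outcome)
        n_control = cfg.n_outcome - n_case
    se_y = 1.0 / np.sqrt(het * cfg.n_outcome * v)
    beta_y_true = cfg.theta * beta_x + alpha
    for b_my, beta_m_true in beta_m_true_all:
        beta_y_true = beta_y_true + b_my * beta_m_true
    beta_hat_y = _ld_convolve(beta_y_true, cfg) + _ld_noise(r_ny, se_y, cfg)
    ea_y, oa_y, eaf_y, bh_y = _recode_alleles(cfg, r_code, ea, oa, eaf, beta_hat_y)
    outcome = _sumstats_frame(cfg, vids, chrom, pos, ea_y, oa_y, eaf_y,
                              bh_y, se_y, cfg.n_outcome,
                              n_case=n_case, n_control=n_control, trait="outcome")

    indirect = [b_xm * b_my for b_xm, b_my in cfg.mediator_spec]
    manifest = TruthManifest(
        theta=cfg.theta,
        per_snp_beta_x=beta_x,
        per_snp_alpha=alpha,
        true_indirect=indirect,
        true_total=cfg.theta + sum(indirect),
        true_h2={"exposure": cfg.exposure_h2},
    )
    return exposure, mediators, outcome, manifest


def simulate_harmonized_panel(
    k: int,
    theta: float,
    seed: int,
    n_exposure: int = DEFAULT_N_EXPOSURE,
    n_outcome: int = DEFAULT_N_OUTCOME,
    instrument_h2: float = 0.04,
    pleiotropy_mode: str = "none",
    pleiotropy_sd: float = 0.0,
    outcome_case_fraction: float | None = DEFAULT_CASE_FRACTION,
):
    """A ready-harmonized panel of ``k`` independent instruments.

    Shortcut for estimator-calibration studies: every SNP is causal for the
    exposure (no selection step, hence no winner's-curse attenuation), LD-free,
    and already aligned to a common effect allele.  Returns
    ``(HarmonizedSet, TruthManifest)``.
    """
    from .io import HarmonizedSet  # local import keeps module load order simple

    cfg = SyntheticConfig(
        n_snps=k, n_exposure=n_exposure, n_outcome=n_outcome,
        prop_causal=1.0, exposure_h2=instrument_h2, theta=theta,
        pleiotropy_mode=pleiotropy_mode, pleiotropy_sd=pleiotropy_sd,
        ld_rho=0.0, seed=seed, outcome_case_fraction=outcome_case_fraction,
        palindromic_rate=0.0, strand_flip_rate=0.0, allele_swap_rate=0.0,
    )
    exposure, outcome, manifest = simulate_two_sample_gwas(cfg)
    e, o = exposure.df, outcome.df
    df = pd.DataFrame(
        {
            "variant_id": e["variant_id"],
            "chrom": e["chrom"],
            "pos": e["pos"],
            "eaf": e["eaf"],
            "beta_x": e["beta"],
            "se_x": e["se"],
            "pval_x": e["pval"],
            "beta_y": o["beta"],
            "se_y": o["se"],
            "pval_y": o["pval"],
        }
    )
    audit = pd.DataFrame({"variant_id": e["variant_id"],
                          "alignment_action": "kept"})
    h = HarmonizedSet(df=df, audit=audit, n_x=n_exposure, n_y=n_outcome)
    return h, manifest


# ---------------------------------------------------------------------------
# LDSC-style z-scores
# ---------------------------------------------------------------------------

def simulate_ldsc_traits(n_snps, n1, n2, h2_1, h2_2, rg, ld_scores, seed,
                         shared_noise: bool = False):
    """Two traits' z-scores following the LD-score regression model.

    Per-SNP genetic components are bivariate normal with correlation ``rg``
    and trait variances h2_i/M, scaled by the SNP's LD score so that
    E[χ²_ij] = 1 + n_i·h2_i·l_j/M and
    E[z_1j·z_2j] = rg·√(h2_1·h2_2·n_1·n_2)·l_j/M — the two regression
    relations the estimator fits.  ``shared_noise=True`` reuses one
    environmental noise stream for both traits (full sample overlap).
    """
    if abs(rg) > 1:
        raise InvalidParameterError("|rg| must be <= 1")
    for h2 in (h2_1, h2_2):
        if not (0 <= h2 < 1):
            raise InvalidParameterError("h2 values must be in [0, 1)")
    ld_scores = np.asarray(ld_scores, dtype=float)
    if len(ld_scores) != n_snps:
        raise InvalidParameterError("ld_scores length must equal n_snps")
    rng = np.random.default_rng(seed)
    m = n_snps
    g1 = rng.standard_normal(m)
    g_perp = rng.standard_normal(m)
    g2 = rg * g1 + math.sqrt(max(0.0, 1.0 - rg ** 2)) * g_perp
    e1 = rng.standard_normal(m)
    e2 = e1 if shared_noise else rng.standard_normal(m)
    z1 = np.sqrt(n1 * h2_1 * ld_scores / m) * g1 + e1
    z2 = np.sqrt(n2 * h2_2 * ld_scores / m) * g2 + e2
    return z1, z2


# ---------------------------------------------------------------------------
# Text writers for the generator's side tables
# ---------------------------------------------------------------------------

def write_ld_scores(vids, ld_scores, path) -> None:
    pd.DataFrame({"variant_id": vids, "ldscore": ld_scores}).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_ld_scores(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_ld_matrix(vids, R, path, r2: bool = True) -> None:
    """Square delimited LD table (r² by default) indexed by variant id."""
    M = R ** 2 if r2 else R
    pd.DataFrame(M, index=vids, columns=vids).to_csv(path, sep="\t", float_format="%.17g")


def write_ld_triplets(vids, cfg: SyntheticConfig, path, r2_floor: float = 1e-8) -> None:
    """Sparse within-block r² pairs (id_i, id_j, r2), diagonal included.

    The block-diagonal LD of ``cfg`` never links SNPs across blocks, so the
    triplet list is O(n_snps · block_size) instead of O(n_snps²).
    """
    vids = np.asarray(vids)
    rows_i, rows_j, vals = [], [], []
    for start in range(0, len(vids), cfg.ld_block_size):
        stop = min(start + cfg.ld_block_size, len(vids))
        idx = np.arange(start, stop)
        for a in range(len(idx)):
            for b in range(a, len(idx)):
                r2 = cfg.ld_rho ** (2 * (b - a))
                if r2 >= r2_floor or a == b:
                    rows_i.append(vids[idx[a]])
                    rows_j.append(vids[idx[b]])
                    vals.append(r2)
    pd.DataFrame({"id_i": rows_i, "id_j": rows_j, "r2": vals}).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )
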