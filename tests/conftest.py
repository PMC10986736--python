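import numpy as np
import pandas as pd
import pytest

from tsmr.io import HarmonizedSet, SummaryStatSet


def make_hset(beta_x, se_x, beta_y, se_y, n_x=100_000, n_y=200_000,
              eaf=None) -> HarmonizedSet:
    """Assemble a HarmonizedSet directly from effect arrays."""
    k = len(beta_x)
    eaf = np.full(k, 0.3) if eaf is None else np.asarray(eaf, float)
    vids = [f"rs{i + 1}" for i in range(k)]
    df = pd.DataFrame({
        "variant_id": vids,
        "chrom": "1",
        "pos": (np.arange(k) + 1) * 100_000,
        "eaf": eaf,
        "beta_x": np.asarray(beta_x, float),
        "se_x": np.asarray(se_x, float),
        "pval_x": 1e-10,
        "beta_y": np.asarray(beta_y, float),
        "se_y": np.asarray(se_y, float),
        "pval_y": 0.5,
    })
    audit = pd.DataFrame({"variant_id": vids, "alignment_action": "kept"})
    return HarmonizedSet(df=df, audit=audit, n_x=n_x, n_y=n_y)


def make_sumstats(variant_id, effect_allele, other_allele, eaf, beta, se,
                  pval=None, n=100_000, chrom="1", pos=None) -> SummaryStatSet:
    k = len(variant_id)
    df = pd.DataFrame({
        "variant_id": variant_id,
        "chrom": chrom,
        "pos": pos if pos is not None else (np.arange(k) + 1) * 100_000,
        "effect_allele": effect_allele,
        "other_allele": other_allele,
        "eaf": eaf,
        "beta": beta,
        "se": se,
        "pval": pval if pval is not None else np.full(k, 1e-10),
        "n": n,
    })
    return SummaryStatSet(df=df)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def synthetic_pair():
    """One discovery-scale simulated exposure/outcome pair (shared, read-only)."""
    from tsmr.synthetic import SyntheticConfig, simulate_two_sample_gwas

    cfg = SyntheticConfig(seed=7)
    exposure, outcome, manifest = simulate_two_sample_gwas(cfg)
    return cfg, exposure, outcome, manifest
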