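"""Instrument selection: significance, clumping, strength, directionality."""

import itertools

import numpy as np
import pandas as pd
import pytest

from tsmr.instruments import (f_statistic, filter_by_f, ld_clump, load_ld,
                              select_significant, steiger_filter,
                              variance_explained)
from tsmr.io import harmonize_pair
from tsmr.synthetic import (SyntheticConfig, make_ld_blocks,
                            simulate_harmonized_panel, simulate_two_sample_gwas)

from conftest import make_sumstats


class TestSignificance:
    def test_threshold_keeps_only_stronger_pvalues(self):
        sset = make_sumstats(["rs1", "rs2"], ["A", "A"], ["G", "G"],
                             [0.3, 0.3], [0.1, 0.1], [0.01, 0.01],
                             pval=[1e-9, 1e-7])
        assert list(select_significant(sset, 5e-8).df["variant_id"]) == ["rs1"]

    def test_nothing_significant_gives_empty_set(self):
        sset = make_sumstats(["rs1"], ["A"], ["G"], [0.3], [0.1], [0.01],
                             pval=[0.5])
        assert len(select_significant(sset, 5e-8)) == 0

    def test_threshold_one_is_identity(self):
        sset = make_sumstats(["rs1", "rs2"], ["A", "A"], ["G", "G"],
                             [0.3, 0.3], [0.1, 0.1], [0.01, 0.01],
                             pval=[0.2, 0.9])
        assert len(select_significant(sset, 1.0)) == 2


def _clump_oracle(df, r2mat, r2_max, window_bp):
    """Exhaustive greedy reference: repeatedly take the best remaining p."""
    remaining = list(df.sort_values(["pval", "variant_id"])["variant_id"])
    meta = df.set_index("variant_id")
    kept = []
    while remaining:
        best = remaining.pop(0)
        kept.append(best)
        survivors = []
        for v in remaining:
            linked = (
                r2mat.loc[best, v] >= r2_max
                and meta.loc[v, "chrom"] == meta.loc[best, "chrom"]
                and abs(meta.loc[v, "pos"] - meta.loc[best, "pos"]) <= window_bp
            )
            if not linked:
                survivors.append(v)
        remaining = survivors
    return sorted(kept)


class TestClumping:
    def test_unlinked_snps_all_kept(self):
        sset = make_sumstats(["rs1", "rs2", "rs3"], ["A"] * 3, ["G"] * 3,
                             [0.3] * 3, [0.1] * 3, [0.01] * 3,
                             pval=[1e-9, 1e-10, 1e-11])
        ld = pd.DataFrame(np.eye(3), index=sset.df["variant_id"],
                          columns=sset.df["variant_id"])
        assert len(ld_clump(sset, ld)) == 3

    def test_stronger_pvalue_dominates_linked_pair(self):
        sset = make_sumstats(["rs1", "rs2"], ["A"] * 2, ["G"] * 2,
                             [0.3] * 2, [0.1] * 2, [0.01] * 2,
                             pval=[1e-20, 1e-10])
        ld = pd.DataFrame([[1.0, 0.5], [0.5, 1.0]],
                          index=["rs1", "rs2"], columns=["rs1", "rs2"])
        kept = ld_clump(sset, ld, r2_max=0.001)
        assert list(kept.df["variant_id"]) == ["rs1"]

    def test_matches_exhaustive_greedy_oracle_on_ld_block(self, rng):
        R, _ = make_ld_blocks(50, 50, 0.9)
        vids = [f"rs{i:03d}" for i in range(50)]
        pvals = 10.0 ** rng.uniform(-30, -8, size=50)
        sset = make_sumstats(vids, ["A"] * 50, ["G"] * 50, [0.3] * 50,
                             [0.1] * 50, [0.01] * 50, pval=pvals)
        r2 = pd.DataFrame(R ** 2, index=vids, columns=vids)
        kept = sorted(ld_clump(sset, r2, r2_max=0.01, window_kb=10_000).df["variant_id"])
        oracle = _clump_oracle(sset.df, r2, 0.01, 10_000 * 1000)
        assert kept == oracle

    def test_result_independent_of_row_order(self, rng):
        R, _ = make_ld_blocks(30, 10, 0.8)
        vids = [f"rs{i:03d}" for i in range(30)]
        pvals = 10.0 ** rng.uniform(-30, -8, size=30)
        sset = make_sumstats(vids, ["A"] * 30, ["G"] * 30, [0.3] * 30,
                             [0.1] * 30, [0.01] * 30, pval=pvals)
        r2 = pd.DataFrame(R ** 2, index=vids, columns=vids)
        base = sorted(ld_clump(sset, r2, r2_max=0.05).df["variant_id"])
        perm = sset.df.sample(frac=1, random_state=1).reset_index(drop=True)
        shuffled = make_sumstats(perm["variant_id"], perm["effect_allele"],
                                 perm["other_allele"], perm["eaf"], perm["beta"],
                                 perm["se"], pval=perm["pval"], pos=perm["pos"])
        assert sorted(ld_clump(shuffled, r2, r2_max=0.05).df["variant_id"]) == base

    def test_missing_variant_raises_by_default(self):
        sset = make_sumstats(["rs1", "rs2"], ["A"] * 2, ["G"] * 2,
                             [0.3] * 2, [0.1] * 2, [0.01] * 2)
        ld = pd.DataFrame([[1.0]], index=["rs1"], columns=["rs1"])
        with pytest.raises(KeyError):
            ld_clump(sset, ld)
        assert len(ld_clump(sset, ld, missing="independent")) == 2

    def test_triplet_and_square_ld_loaders_agree(self, tmp_path):
        R, _ = make_ld_blocks(6, 3, 0.6)
        vids = [f"rs{i}" for i in range(6)]
        sq = tmp_path / "sq.tsv"
        pd.DataFrame(R ** 2, index=vids, columns=vids).to_csv(sq, sep="\t")
        trip_rows = [(vids[i], vids[j], R[i, j] ** 2)
                     for i, j in itertools.combinations_with_replacement(range(6), 2)
                     if R[i, j] != 0]
        tr = tmp_path / "trip.tsv"
        pd.DataFrame(trip_rows, columns=["id_i", "id_j", "r2"]).to_csv(
            tr, sep="\t", index=False)
        a = load_ld(sq)
        b = load_ld(tr).loc[a.index, a.columns]
        assert np.allclose(a.to_numpy(), b.to_numpy())


class TestStrength:
    @pytest.mark.parametrize("beta,se,expected", [
        (0.10, 0.05, 4.0),
        (0.03, 0.003, 100.0),
        (-0.10, 0.05, 4.0),
    ])
    def test_f_statistic_arithmetic(self, beta, se, expected):
        assert f_statistic(beta, se) == pytest.approx(expected, rel=1e-12)

    def test_zero_se_rejected(self):
        with pytest.raises(ValueError):
            f_statistic(0.1, 0.0)

    def test_weak_instruments_excluded(self):
        sset = make_sumstats(["rs1", "rs2"], ["A"] * 2, ["G"] * 2, [0.3] * 2,
                             [0.10, 0.10], [0.05, 0.01])
        kept = filter_by_f(sset, f_min=10)
        assert list(kept.df["variant_id"]) == ["rs2"]  # F=4 excluded, F=100 kept

    @pytest.mark.parametrize("eaf,beta,expected", [
        (0.5, 1.0, 0.5),
        (0.1, 0.2, 0.0072),
        (0.9, 0.2, 0.0072),  # MAF symmetry
    ])
    def test_variance_explained(self, eaf, beta, expected):
        assert variance_explained(eaf, beta) == pytest.approx(expected, rel=1e-12)

    def test_variance_explained_rejects_bad_eaf(self):
        with pytest.raises(ValueError):
            variance_explained(0.0, 0.1)


class TestSteiger:
    def test_keeps_exposure_dominant_and_drops_reverse(self):
        h, _ = simulate_harmonized_panel(4, theta=0.2, seed=1)
        # force one SNP to explain far more outcome than exposure variance
        h.df.loc[0, "beta_y"] = 50 * h.df.loc[0, "se_y"]
        h.df.loc[0, "beta_x"] = 0.5 * h.df.loc[0, "se_x"]
        filtered, record = steiger_filter(h)
        assert not record.loc[0, "steiger_keep"]
        assert record.loc[1:, "steiger_keep"].all()
        assert len(filtered) == 3
        assert ((record["steiger_p"] > 0) & (record["steiger_p"] <= 1)).all()

    def test_correct_direction_rarely_dropped(self):
        dropped = []
        for seed in range(5):
            h, _ = simulate_harmonized_panel(100, theta=0.3, seed=seed)
            filtered, _ = steiger_filter(h)
            dropped.append(1 - len(filtered) / len(h))
        assert np.mean(dropped) <= 0.05

    def test_missing_sample_size_raises(self):
        h, _ = simulate_harmonized_panel(5, theta=0.1, seed=0)
        h.n_y = float("nan")
        with pytest.raises(ValueError, match="outcome"):
            steiger_filter(h)


class TestPipelineOrder:
    def test_selection_steps_shrink_monotonically(self, synthetic_pair):
        cfg, exposure, outcome, _ = synthetic_pair
        sig = select_significant(exposure)
        strong = filter_by_f(sig)
        h = harmonize_pair(strong, outcome)
        filtered, _ = steiger_filter(h)
        counts = [len(exposure), len(sig), len(strong), len(h), len(filtered)]
        assert counts == sorted(counts, reverse=True)
        assert counts[-1] > 0

    def test_surviving_instruments_are_strong(self, synthetic_pair):
        _, exposure, _, _ = synthetic_pair
        strong = filter_by_f(select_significant(exposure))
        f = f_statistic(strong.df["beta"].to_numpy(), strong.df["se"].to_numpy())
        assert f.min() > 10
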