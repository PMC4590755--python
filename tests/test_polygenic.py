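"""LD pruning, region exclusion, score construction, sweep and OR conversion."""

import numpy as np
import pandas as pd
import pytest

from asherit.genotype_io import MISSING, SnpRecord
from asherit.grm import compute_grm
from asherit.polygenic import (PolygenicModel, beta_to_or, build_model,
                               compute_scores, exclude_region, ld_prune,
                               or_with_ci, snp_accounting, threshold_sweep)
from conftest import make_genotypes


def toy_model(entries):
    return PolygenicModel(pd.DataFrame(entries),
                          {"training_sample_ids": ["tr0", "tr1"]})


class TestLdPrune:
    def test_duplicate_snps_one_retained(self):
        rng = np.random.default_rng(1)
        col = rng.binomial(2, 0.3, 200).astype(np.int8)
        other = rng.binomial(2, 0.4, 200).astype(np.int8)
        g = make_genotypes(np.column_stack([col, col, other]))
        kept = ld_prune(g, r2_max=0.2)
        assert len([s for s in kept if s in ("snp0", "snp1")]) == 1
        assert "snp2" in kept

    def test_independent_snps_all_retained(self):
        rng = np.random.default_rng(2)
        g = make_genotypes(rng.binomial(2, 0.3, size=(500, 20)).astype(np.int8))
        assert len(ld_prune(g, r2_max=0.2)) == 20

    def test_block_panel_prunes_to_few_per_block(self, unrelated_dataset):
        g = unrelated_dataset["g"].subset(snp_idx=np.arange(200))
        blk = unrelated_dataset["config"].ld_block_len
        kept = ld_prune(g, r2_max=0.2)
        # heavy within-block LD: most SNPs pruned away
        assert len(kept) < 0.5 * g.n_snps
        # retained set has no within-window pair above the cap
        idx = [g.snp_index(s) for s in kept]
        sub = g.dosages[:, idx].astype(float)
        sub = sub[:, sub.std(axis=0) > 0]  # r^2 undefined for monomorphic
        idx = list(range(sub.shape[1]))
        r = np.corrcoef(sub, rowvar=False)
        r2 = r * r
        np.fill_diagonal(r2, 0)
        for i in range(len(idx)):
            for j in range(i + 1, min(i + 50, len(idx))):
                assert r2[i, j] <= 0.2 + 1e-9


class TestExcludeRegion:
    def snps(self):
        return [SnpRecord(f"s{i}", 10, pos, "A", "G")
                for i, pos in enumerate([1_000_000, 2_000_000, 3_000_000,
                                         5_000_001])] + \
               [SnpRecord("other_chrom", 11, 3_000_000, "A", "G")]

    def test_inclusive_boundary(self):
        # region [3_000_000, 4_000_000], flank 1 Mb: cut [2e6, 5e6] inclusive
        kept = exclude_region(self.snps(), 10, 3_000_000, 4_000_000)
        assert kept == ["s0", "s3", "other_chrom"]

    def test_other_chromosome_retained(self):
        kept = exclude_region(self.snps(), 10, 2_900_000, 3_100_000)
        assert "other_chrom" in kept

    def test_constructed_36_of_100(self):
        snps = [SnpRecord(f"r{i}", 1, 10_000_000 + i * 1000, "A", "G")
                for i in range(36)]
        snps += [SnpRecord(f"k{i}", 2, 10_000_000 + i * 1000, "A", "G")
                 for i in range(64)]
        kept = exclude_region(snps, 1, 9_000_000, 12_000_000, flank_bp=1_000_000)
        assert len(kept) == 64

    def test_bad_interval_rejected(self):
        with pytest.raises(ValueError):
            exclude_region([], 1, 10, 5)


class TestSnpAccounting:
    def test_published_filter_arithmetic(self):
        assert snp_accounting(257_747, 170_512, 36, 9_852) == 77_347

    def test_over_exclusion_rejected(self):
        with pytest.raises(ValueError):
            snp_accounting(100, 90, 20, 0)


class TestBuildModel:
    def test_null_training_pvalues_uniform(self):
        from scipy.stats import kstest
        rng = np.random.default_rng(3)
        g = make_genotypes(rng.binomial(2, 0.3, size=(400, 300)).astype(np.int8))
        y = rng.standard_normal(400)
        model = build_model(g, y, g.snp_ids, maf_min=0.05)
        assert kstest(model.entries["p"], "uniform").pvalue > 0.01

    def test_causal_snp_beta_sign(self, unrelated_dataset):
        g = unrelated_dataset["g"]
        truth = unrelated_dataset["truth"]
        pheno = unrelated_dataset["pheno"]
        model = build_model(g, pheno.df["dma_pct"].to_numpy(), g.snp_ids,
                            covariates=pheno.covariate_design(), maf_min=0.05)
        row = model.entries.set_index("snp_id").loc[truth.major_causal_snp_id]
        assert np.sign(row["beta"]) == np.sign(truth.major_effect)
        assert row["p"] < 1e-3

    def test_maf_floor_applied(self):
        rng = np.random.default_rng(4)
        common = rng.binomial(2, 0.3, size=(300, 5)).astype(np.int8)
        rare = rng.binomial(2, 0.01, size=(300, 3)).astype(np.int8)
        g = make_genotypes(np.hstack([common, rare]))
        model = build_model(g, rng.standard_normal(300), g.snp_ids,
                            maf_min=0.05)
        assert len(model.entries) == 5

    def test_empty_retained_set_rejected(self):
        g = make_genotypes(np.zeros((10, 2)))
        with pytest.raises(ValueError):
            build_model(g, np.zeros(10), [])


class TestComputeScores:
    def test_hand_example(self):
        g = make_genotypes([[2, 1]])
        model = toy_model({"snp_id": ["snp0", "snp1"], "a1": ["A", "A"],
                           "beta": [0.5, -1.0], "p": [0.01, 0.01]})
        ss = compute_scores(g, model, 0.05)
        assert ss.scores.iloc[0] == pytest.approx(0.0)
        assert ss.n_snps_used == 2

    def test_missing_genotype_denominator(self):
        g = make_genotypes([[2, MISSING]])
        model = toy_model({"snp_id": ["snp0", "snp1"], "a1": ["A", "A"],
                           "beta": [0.5, -1.0], "p": [0.01, 0.01]})
        ss = compute_scores(g, model, 0.05)
        assert ss.scores.iloc[0] == pytest.approx(1.0)  # denominator 1

    def test_all_zero_betas(self):
        g = make_genotypes([[1, 2], [0, 1]])
        model = toy_model({"snp_id": ["snp0", "snp1"], "a1": ["A", "A"],
                           "beta": [0.0, 0.0], "p": [0.01, 0.01]})
        assert (compute_scores(g, model, 0.05).scores == 0).all()

    def test_zero_passing_snps_raises(self):
        g = make_genotypes([[1]])
        model = toy_model({"snp_id": ["snp0"], "a1": ["A"],
                           "beta": [0.5], "p": [0.5]})
        with pytest.raises(ValueError, match="0.001"):
            compute_scores(g, model, 0.001)

    def test_absent_model_snps_dropped(self):
        g = make_genotypes([[1]])
        model = toy_model({"snp_id": ["snp0", "ghost"], "a1": ["A", "A"],
                           "beta": [0.5, 9.9], "p": [0.01, 0.01]})
        ss = compute_scores(g, model, 0.05)
        assert ss.n_dropped == 1
        assert ss.scores.iloc[0] == pytest.approx(0.5)

    def test_order_invariance(self):
        rng = np.random.default_rng(5)
        g = make_genotypes(rng.binomial(2, 0.3, size=(20, 6)).astype(np.int8))
        entries = {"snp_id": g.snp_ids, "a1": ["A"] * 6,
                   "beta": rng.standard_normal(6).tolist(),
                   "p": rng.uniform(0.001, 0.04, 6).tolist()}
        m1 = toy_model(entries)
        df = pd.DataFrame(entries).iloc[::-1].reset_index(drop=True)
        m2 = PolygenicModel(df, m1.provenance)
        s1 = compute_scores(g, m1, 0.05).scores
        s2 = compute_scores(g, m2, 0.05).scores
        np.testing.assert_allclose(s1, s2)


class TestBetaToOr:
    def test_zero_beta_unity(self):
        assert beta_to_or(0.0, 10, 20) == pytest.approx(1.0)

    def test_published_conversion(self):
        # beta -0.04 per SD, 2,014 cases / 1,285 controls -> OR 0.85
        assert beta_to_or(-0.04, 2014, 1285) == pytest.approx(0.85, abs=0.005)

    def test_reciprocal_symmetry(self):
        orr = beta_to_or(0.04, 2014, 1285)
        assert orr == pytest.approx(1.0 / beta_to_or(-0.04, 2014, 1285))

    def test_degenerate_counts_rejected(self):
        with pytest.raises(ValueError):
            beta_to_or(0.1, 0, 10)

    def test_ci_ordering(self):
        orr, lo, hi = or_with_ci(-0.04, 0.02, 2014, 1285)
        assert lo < orr < hi


@pytest.fixture(scope="module")
def sweep_setup(unrelated_dataset):
    g = unrelated_dataset["g"]
    pheno = unrelated_dataset["pheno"]
    outcome = unrelated_dataset["outcome"]
    n = g.n_samples
    train, test = np.arange(n // 2), np.arange(n // 2, n)
    g_tr, g_te = g.subset(sample_idx=train), g.subset(sample_idx=test)
    model = build_model(g_tr, pheno.df["dma_pct"].to_numpy()[train],
                        g_tr.snp_ids, maf_min=0.05)
    grm_te = compute_grm(g_te)
    tab = threshold_sweep(model, g_te, np.asarray(outcome)[test],
                          None, grm_te)
    return model, g_te, tab


class TestThresholdSweep:
    def test_n_snps_nested_in_threshold(self, sweep_setup):
        _, _, tab = sweep_setup
        counts = tab["n_snps"].to_numpy()
        assert np.all(np.diff(counts) >= 0)

    def test_or_consistent_with_beta(self, sweep_setup):
        model, g_te, tab = sweep_setup
        ok = tab.dropna(subset=["beta"])
        n = g_te.n_samples
        for _, row in ok.iterrows():
            assert np.isfinite(row["OR"])
            assert (row["OR"] < 1) == (row["beta"] < 0) or row["beta"] == 0

    def test_leakage_guard(self, unrelated_dataset):
        g = unrelated_dataset["g"]
        pheno = unrelated_dataset["pheno"]
        model = build_model(g, pheno.df["dma_pct"].to_numpy(), g.snp_ids,
                            maf_min=0.05)
        with pytest.raises(ValueError, match="training and testing"):
            threshold_sweep(model, g, np.zeros(g.n_samples), None,
                            compute_grm(g))

    def test_threshold_set_nesting_property(self, sweep_setup):
        model, _, _ = sweep_setup
        small = set(model.at_threshold(0.01)["snp_id"])
        large = set(model.at_threshold(0.3)["snp_id"])
        assert small <= large
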