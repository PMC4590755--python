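"""Generator contracts: determinism, relatedness structure, planted effects."""

import numpy as np
import pytest

from asherit.grm import compute_grm
from asherit.simulate import (SimulationConfig, simulate_genotypes,
                              simulate_outcome, simulate_phenotype)


class TestConfigValidation:
    def test_fraction_sum_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(major_locus_pve=0.5, polygenic_pve=0.3,
                             rare_pve=0.2, shared_env_var=0.1)

    def test_zero_founders_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_families=0, n_unrelated=0,
                             n_families_with_parent=0)

    def test_bad_case_fraction_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(case_fraction=1.5)


class TestDeterminism:
    def test_same_seed_identical_triple(self):
        cfg = SimulationConfig(n_families=20, sibs_per_family=2,
                               n_unrelated=20, n_families_with_parent=5,
                               n_snps_typed=500, ld_block_len=10,
                               n_snps_rare_untyped=50, seed=77)
        g1, t1 = simulate_genotypes(cfg)
        g2, t2 = simulate_genotypes(cfg)
        np.testing.assert_array_equal(g1.dosages, g2.dosages)
        p1 = simulate_phenotype(g1, t1, cfg)
        p2 = simulate_phenotype(g2, t2, cfg)
        np.testing.assert_array_equal(p1.df["dma_pct"], p2.df["dma_pct"])
        o1 = simulate_outcome(p1, t1, cfg)
        o2 = simulate_outcome(p2, t2, cfg)
        np.testing.assert_array_equal(o1, o2)


class TestGenotypeStructure:
    def test_sib_pair_grm_near_half(self, family_dataset):
        a = compute_grm(family_dataset["g"])
        truth = family_dataset["truth"]
        pos = {s: i for i, s in enumerate(a.sample_ids)}
        parents_to_sibs = {}
        for sid, fa, mo in truth.pedigree:
            if fa != "0":
                parents_to_sibs.setdefault((fa, mo), []).append(sid)
        vals = [a.values[pos[s[0]], pos[s[1]]]
                for s in parents_to_sibs.values() if len(s) == 2]
        assert len(vals) >= 100
        assert 0.40 <= np.mean(vals) <= 0.60

    def test_unrelated_offdiagonal_tail(self):
        cfg = SimulationConfig(n_families=0, sibs_per_family=0,
                               n_unrelated=250, n_families_with_parent=0,
                               n_snps_typed=20_000, ld_block_len=50,
                               n_snps_rare_untyped=0, seed=12)
        g, _ = simulate_genotypes(cfg)
        a = compute_grm(g)
        off = a.values[np.triu_indices(a.n, 1)]
        assert np.percentile(off, 99) < 0.05

    def test_ld_decays_within_block_zero_across(self, family_dataset):
        from asherit.association import ld_r2
        g = family_dataset["g"]
        blk = family_dataset["config"].ld_block_len
        adjacent, across = [], []
        for start in range(0, 40 * blk, blk):
            ids = [g.snps[start + k].snp_id for k in range(blk)]
            adjacent.append(ld_r2(g, ids[0], ids[1]))
            if start + 2 * blk <= g.n_snps:
                across.append(ld_r2(g, ids[0], g.snps[start + blk].snp_id))
        adjacent = [v for v in adjacent if not np.isnan(v)]
        across = [v for v in across if not np.isnan(v)]
        assert np.mean(adjacent) > 0.3
        assert np.mean(across) < 0.05

    def test_rare_variants_are_rare_and_untyped(self, family_dataset):
        truth = family_dataset["truth"]
        g = family_dataset["g"]
        freqs = truth.rare_dosages.mean(axis=0) / 2.0
        assert freqs.max() < 0.05
        assert not set(truth.rare_ids) & set(g.snp_ids)


class TestPhenotype:
    def test_null_architecture_greml_near_zero(self):
        from asherit.reml import VarianceComponentModel, fit_reml
        cfg = SimulationConfig(n_families=100, sibs_per_family=2,
                               n_unrelated=100, n_families_with_parent=0,
                               n_snps_typed=2000, ld_block_len=10,
                               n_snps_rare_untyped=0, major_locus_pve=0,
                               polygenic_pve=0, rare_pve=0, shared_env_var=0,
                               seed=21)
        g, truth = simulate_genotypes(cfg)
        ph = simulate_phenotype(g, truth, cfg)
        fit = fit_reml(VarianceComponentModel(
            ph.df["dma_pct"].to_numpy(), ph.covariate_design(),
            [compute_grm(g)], ["g"]))
        assert fit.pve[0] < 0.15

    def test_major_locus_r2_near_seven_percent(self):
        cfg = SimulationConfig(n_families=0, sibs_per_family=0,
                               n_unrelated=2000, n_families_with_parent=0,
                               n_snps_typed=1000, ld_block_len=10,
                               n_snps_rare_untyped=0, major_locus_pve=0.07,
                               polygenic_pve=0, rare_pve=0, shared_env_var=0,
                               seed=22)
        g, truth = simulate_genotypes(cfg)
        ph = simulate_phenotype(g, truth, cfg)
        x = g.dosages[:, g.snp_index(truth.major_causal_snp_id)].astype(float)
        y = ph.df["dma_pct"].to_numpy()
        r2 = np.corrcoef(x, y)[0, 1] ** 2
        assert 0.04 <= r2 <= 0.10

    def test_shared_env_sib_icc(self):
        cfg = SimulationConfig(n_families=300, sibs_per_family=2,
                               n_unrelated=0, n_families_with_parent=0,
                               n_snps_typed=1000, ld_block_len=10,
                               n_snps_rare_untyped=0, major_locus_pve=0,
                               polygenic_pve=0, rare_pve=0, shared_env_var=0.2,
                               seed=23)
        g, truth = simulate_genotypes(cfg)
        ph = simulate_phenotype(g, truth, cfg)
        y = ph.df["dma_pct"].to_numpy()
        resid = y - np.poly1d(np.polyfit(ph.df["age"], y, 1))(ph.df["age"])
        pairs = resid.reshape(-1, 2)
        icc = np.corrcoef(pairs[:, 0], pairs[:, 1])[0, 1]
        assert 0.10 <= icc <= 0.30

    def test_realized_fractions_near_targets(self):
        fracs = []
        for seed in range(10):
            cfg = SimulationConfig(n_families=150, sibs_per_family=2,
                                   n_unrelated=100, n_families_with_parent=0,
                                   n_snps_typed=1000, ld_block_len=10,
                                   n_snps_rare_untyped=0, major_locus_pve=0,
                                   polygenic_pve=0.15, rare_pve=0,
                                   shared_env_var=0, n_causal_common=100,
                                   seed=800 + seed)
            g, truth = simulate_genotypes(cfg)
            simulate_phenotype(g, truth, cfg)
            fracs.append(truth.realized_fractions["polygenic"])
        assert abs(np.mean(fracs) - 0.15) < 0.02

    def test_species_percentages_consistent(self, family_dataset):
        df = family_dataset["pheno"].df
        total = df[["dma_pct", "mma_pct", "ias_pct"]].sum(axis=1)
        np.testing.assert_allclose(total, 100.0, atol=1e-9)


class TestOutcome:
    def test_case_count_bookkeeping(self, family_dataset):
        cfg, out = family_dataset["config"], family_dataset["outcome"]
        assert out.sum() == round(cfg.case_fraction * len(out))

    def test_independent_outcome_when_k_zero(self):
        import dataclasses
        cfg = SimulationConfig(n_families=0, sibs_per_family=0,
                               n_unrelated=1500, n_families_with_parent=0,
                               n_snps_typed=500, ld_block_len=10,
                               n_snps_rare_untyped=0, major_locus_pve=0.2,
                               polygenic_pve=0, rare_pve=0, shared_env_var=0,
                               liability_genetic_weight=0.0, seed=25)
        g, truth = simulate_genotypes(cfg)
        ph = simulate_phenotype(g, truth, cfg)
        out = simulate_outcome(ph, truth, cfg)
        x = g.dosages[:, g.snp_index(truth.major_causal_snp_id)].astype(float)
        r = np.corrcoef(x, out)[0, 1]
        assert abs(r) < 0.06

    def test_major_locus_predicts_outcome_when_k_large(self):
        cfg = SimulationConfig(n_families=0, sibs_per_family=0,
                               n_unrelated=1500, n_families_with_parent=0,
                               n_snps_typed=500, ld_block_len=10,
                               n_snps_rare_untyped=0, major_locus_pve=0.3,
                               polygenic_pve=0, rare_pve=0, shared_env_var=0,
                               liability_genetic_weight=0.9, seed=26)
        g, truth = simulate_genotypes(cfg)
        ph = simulate_phenotype(g, truth, cfg)
        out = simulate_outcome(ph, truth, cfg)
        x = g.dosages[:, g.snp_index(truth.major_causal_snp_id)].astype(float)
        r = np.corrcoef(x, out)[0, 1]
        assert r < -0.15  # phenotype-raising alleles are protective
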