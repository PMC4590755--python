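import numpy as np
import pytest

from asherit.genotype_io import GenotypeMatrix, SampleRecord, SnpRecord
from asherit.simulate import (SimulationConfig, simulate_genotypes,
                              simulate_outcome, simulate_phenotype)


def make_genotypes(dosages, chrom=None, positions=None):
    """GenotypeMatrix from a raw dosage array with auto-generated metadata."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n, m = dosages.shape
    chrom = chrom or [1] * m
    positions = positions or [1000 * (j + 1) for j in range(m)]
    snps = [SnpRecord(f"snp{j}", chrom[j], positions[j], "A", "G")
            for j in range(m)]
    samples = [SampleRecord(f"s{i}", f"f{i}") for i in range(n)]
    return GenotypeMatrix(dosages, snps, samples)


@pytest.fixture(scope="session")
def family_dataset():
    """Mid-size family-structured dataset with all variance components."""
    cfg = SimulationConfig(
        n_families=120, sibs_per_family=2, n_unrelated=160,
        n_families_with_parent=10, n_snps_typed=3000, ld_block_len=10,
        n_snps_rare_untyped=150, major_locus_pve=0.07, polygenic_pve=0.10,
        rare_pve=0.20, shared_env_var=0.10, n_causal_common=200, seed=202,
    )
    g, truth = simulate_genotypes(cfg)
    pheno = simulate_phenotype(g, truth, cfg)
    outcome = simulate_outcome(pheno, truth, cfg)
    return {"config": cfg, "g": g, "truth": truth, "pheno": pheno,
            "outcome": outcome}


@pytest.fixture(scope="session")
def unrelated_dataset():
    """Unrelated-only panel for association/LD tests."""
    cfg = SimulationConfig(
        n_families=0, sibs_per_family=0, n_unrelated=400,
        n_families_with_parent=0, n_snps_typed=2000, ld_block_len=10,
        n_snps_rare_untyped=0, major_locus_pve=0.07, polygenic_pve=0.10,
        rare_pve=0.0, shared_env_var=0.0, n_causal_common=150, seed=303,
    )
    g, truth = simulate_genotypes(cfg)
    pheno = simulate_phenotype(g, truth, cfg)
    outcome = simulate_outcome(pheno, truth, cfg)
    return {"config": cfg, "g": g, "truth": truth, "pheno": pheno,
            "outcome": outcome}
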