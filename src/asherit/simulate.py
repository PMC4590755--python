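"""Synthetic genotype/phenotype/outcome data with family structure.

The generator emulates the statistical structure that family-vs-unrelated
heritability contrasts rely on:

* typed SNPs in LD blocks (finite pool of founder haplotypes per block,
  latent-AR(1) correlation within a block, independence across blocks);
* families of full sibs (optionally with a genotyped parent) produced by
  Mendelian transmission with free recombination at block boundaries, plus
  unrelated singletons;
* one major-effect locus with two tightly linked, named tag SNPs (the
  analog of a 10q24.32/AS3MT signal);
* rare causal variants withheld from the typed panel — they contribute to
  sib resemblance (narrow-sense h2) but not to typed-SNP GRMs (h_g2),
  which is the mechanism behind family estimates exceeding unrelated ones;
* sibship-level shared environment, covariates with DMA%-oriented effects,
  and a liability-threshold binary outcome in which alleles that raise the
  phenotype are protective.

Each genetic/environmental component is rescaled in-sample to its target
variance fraction, so realized fractions match targets up to the clipping
of extreme phenotype values.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
import pandas as pd
from scipy.stats import norm

from .genotype_io import GenotypeMatrix, SampleRecord, SnpRecord
from .phenotype import PhenotypeTable

_SNP_SPACING_BP = 5_000
_CHR_START_BP = 100_000

#: covariate effect sizes on DMA%, oriented as in the source cohort
#: (older age, female sex and lower water arsenic raise DMA%)
COVARIATE_EFFECTS = {
    "age": 0.09,                       # per year
    "sex": 1.6,                        # female vs male
    "batch": 0.5,
    "water_as_quartile": (0.0, -0.2, -1.25, -2.74),
    "smoking": (0.0, -0.3, -0.6),
    "bmi_cat": (0.0, 0.9, 2.2),
}


@dataclasses.dataclass
class SimulationConfig:
    n_families: int = 700
    sibs_per_family: int = 2
    n_unrelated: int = 600
    n_snps_typed: int = 20_000
    n_snps_rare_untyped: int = 300
    ld_block_len: int = 50
    major_locus_pve: float = 0.07
    polygenic_pve: float = 0.08
    rare_pve: float = 0.30
    shared_env_var: float = 0.15
    n_causal_common: int = 500
    case_fraction: float = 0.61
    seed: int = 42
    # generator mechanics
    n_families_with_parent: int = 50
    ld_pool_haplotypes: int = 20
    ld_latent_rho: float = 0.95
    liability_genetic_weight: float = 0.6
    phenotype_mean: float = 75.0
    phenotype_sd: float = 8.5

    def __post_init__(self) -> None:
        fracs = (self.major_locus_pve, self.polygenic_pve, self.rare_pve,
                 self.shared_env_var)
        if any(not 0 <= f < 1 for f in fracs):
            raise ValueError("variance fractions must lie in [0, 1)")
        if sum(fracs) >= 1:
            raise ValueError("variance fractions must sum to < 1")
        if not 0 < self.case_fraction < 1:
            raise ValueError("case_fraction must be in (0, 1)")
        if self.n_families < 0 or self.n_unrelated < 0:
            raise ValueError("counts must be non-negative")
        if self.n_families + self.n_unrelated == 0:
            raise ValueError("no samples requested")
        if self.n_families_with_parent > self.n_families:
            raise ValueError("n_families_with_parent exceeds n_families")
        if self.ld_block_len < 3:
            raise ValueError("ld_block_len must be at least 3")

    @property
    def n_samples(self) -> int:
        return (self.n_families * self.sibs_per_family
                + self.n_families_with_parent + self.n_unrelated)


@dataclasses.dataclass
class SimulationTruth:
    """Generative ledger: what was planted, for recovery tests."""

    pedigree: list  # (sample_id, father_id, mother_id); founders use "0"
    major_locus_window: tuple  # (chromosome, start_bp, end_bp)
    major_causal_snp_id: str
    tag_snp_ids: list
    rare_ids: list
    rare_dosages: np.ndarray  # n_samples x n_rare, untyped causal dosages
    family_of: list  # family id per sample, sibship-level env assignment
    major_effect: float = 0.0
    causal_common_ids: list = dataclasses.field(default_factory=list)
    causal_common_effects: np.ndarray | None = None
    rare_effects: np.ndarray | None = None
    realized_fractions: dict = dataclasses.field(default_factory=dict)
    genetic_values: np.ndarray | None = None

    def to_json(self, path) -> None:
        payload = {
            "pedigree": self.pedigree,
            "major_locus_window": list(self.major_locus_window),
            "major_causal_snp_id": self.major_causal_snp_id,
            "tag_snp_ids": self.tag_snp_ids,
            "rare_ids": self.rare_ids,
            "n_rare": len(self.rare_ids),
            "major_effect": self.major_effect,
            "causal_common_ids": self.causal_common_ids,
            "causal_common_effects": (
                None if self.causal_common_effects is None
                else self.causal_common_effects.tolist()),
            "rare_effects": (None if self.rare_effects is None
                             else self.rare_effects.tolist()),
            "realized_fractions": self.realized_fractions,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _block_pool(rng, n_snps, pool_size, rho, freqs):
    """Finite haplotype pool for one block: latent AR(1), thresholded.

    Adjacent-SNP correlation decays as rho^distance within the block and is
    zero across blocks (blocks are drawn independently).
    """
    z = np.empty((pool_size, n_snps))
    z[:, 0] = rng.standard_normal(pool_size)
    innov = rng.standard_normal((pool_size, n_snps - 1))
    scale = np.sqrt(1 - rho**2)
    for j in range(1, n_snps):
        z[:, j] = rho * z[:, j - 1] + scale * innov[:, j - 1]
    return (z < norm.ppf(freqs)[None, :]).astype(np.int8)


def simulate_genotypes(config: SimulationConfig):
    """Generate the typed genotype panel, pedigree and untyped rare variants."""
    rng = np.random.default_rng([config.seed, 0])
    m = config.n_snps_typed
    block_len = config.ld_block_len
    n_blocks = (m + block_len - 1) // block_len
    block_slices = [slice(b * block_len, min((b + 1) * block_len, m))
                    for b in range(n_blocks)]
    block_sizes = [sl.stop - sl.start for sl in block_slices]

    # chromosome layout: blocks split as evenly as possible over 22 autosomes
    n_chrom = min(22, n_blocks)
    block_chrom = np.array([(b * n_chrom) // n_blocks + 1 for b in range(n_blocks)])
    # the major locus sits on chromosome 10 when it exists, else mid-panel
    major_candidates = np.flatnonzero(block_chrom == 10)
    major_block = int(major_candidates[len(major_candidates) // 2]) \
        if major_candidates.size else n_blocks // 2

    # haplotype pools
    pools = []
    freqs_all = rng.uniform(0.05, 0.5, size=m)
    for b, sl in enumerate(block_slices):
        pools.append(_block_pool(rng, block_sizes[b], config.ld_pool_haplotypes,
                                 config.ld_latent_rho, freqs_all[sl]))
    # plant the major causal SNP mid-block with two flanking high-LD tags
    c_local = block_sizes[major_block] // 2
    pool_mb = pools[major_block]
    carriers = rng.permutation(config.ld_pool_haplotypes)[
        : max(2, int(round(0.35 * config.ld_pool_haplotypes)))]
    pool_mb[:, c_local] = 0
    pool_mb[carriers, c_local] = 1
    for off in (-1, 1):
        tag = pool_mb[:, c_local].copy()
        flip = rng.choice(config.ld_pool_haplotypes, size=1, replace=False)
        tag[flip] = 1 - tag[flip]
        pool_mb[:, c_local + off] = tag

    # founders ---------------------------------------------------------------
    n_founders = 2 * config.n_families + config.n_unrelated
    if n_founders == 0:
        raise ValueError("configuration yields zero founders")
    K = config.ld_pool_haplotypes
    founder_idx = rng.integers(0, K, size=(n_founders, 2, n_blocks))

    n_rare = config.n_snps_rare_untyped
    rare_freq = rng.uniform(0.001, 0.01, size=n_rare)
    rare_block = rng.integers(0, n_blocks, size=n_rare)
    founder_rare = (rng.random((n_founders, 2, n_rare))
                    < rare_freq[None, None, :]).astype(np.int8)

    # assemble samples -------------------------------------------------------
    sample_idx_blocks = []   # per sample: (2, n_blocks) pool indices
    sample_rare = []         # per sample: (n_rare,) dosage
    samples: list[SampleRecord] = []
    pedigree = []
    family_of = []

    def transmit(parent):
        """One gamete: per block pick a parental haplotype; rare alleles ride along."""
        fidx, frare = parent
        choice = rng.integers(0, 2, size=n_blocks)
        hap = fidx[choice, np.arange(n_blocks)]
        rare = frare[choice[rare_block], np.arange(n_rare)] if n_rare else \
            np.zeros(0, dtype=np.int8)
        return hap, rare

    for f in range(config.n_families):
        fam = f"F{f:05d}"
        father = (founder_idx[2 * f], founder_rare[2 * f])
        mother = (founder_idx[2 * f + 1], founder_rare[2 * f + 1])
        father_id, mother_id = f"{fam}_FA", f"{fam}_MO"
        if f < config.n_families_with_parent:
            samples.append(SampleRecord(father_id, fam, "male"))
            sample_idx_blocks.append(founder_idx[2 * f])
            sample_rare.append(founder_rare[2 * f].sum(axis=0))
            pedigree.append((father_id, "0", "0"))
            family_of.append(fam)
        for s in range(config.sibs_per_family):
            sid = f"{fam}_S{s + 1}"
            hap_f, rare_f = transmit(father)
            hap_m, rare_m = transmit(mother)
            samples.append(SampleRecord(sid, fam,
                                        "female" if rng.random() < 0.5 else "male"))
            sample_idx_blocks.append(np.stack([hap_f, hap_m]))
            sample_rare.append(rare_f + rare_m)
            pedigree.append((sid, father_id, mother_id))
            family_of.append(fam)
    for u in range(config.n_unrelated):
        i = 2 * config.n_families + u
        sid = f"U{u:05d}"
        samples.append(SampleRecord(sid, sid,
                                    "female" if rng.random() < 0.5 else "male"))
        sample_idx_blocks.append(founder_idx[i])
        sample_rare.append(founder_rare[i].sum(axis=0))
        pedigree.append((sid, "0", "0"))
        family_of.append(sid)

    n = len(samples)
    H = np.stack(sample_idx_blocks)           # n x 2 x n_blocks
    rare_dosages = (np.stack(sample_rare) if n_rare
                    else np.zeros((n, 0), dtype=np.int8))

    dosages = np.empty((n, m), dtype=np.int8)
    for b, sl in enumerate(block_slices):
        pool = pools[b]
        dosages[:, sl] = pool[H[:, 0, b]] + pool[H[:, 1, b]]

    # SNP metadata: sequential positions per chromosome
    snps = []
    pos_in_chrom = {}
    for b, sl in enumerate(block_slices):
        ch = int(block_chrom[b])
        for j in range(sl.start, sl.stop):
            k = pos_in_chrom.get(ch, 0)
            pos_in_chrom[ch] = k + 1
            snps.append(SnpRecord(f"snp_c{ch}_{k:06d}", ch,
                                  _CHR_START_BP + k * _SNP_SPACING_BP, "A", "G"))

    g = GenotypeMatrix(dosages, snps, samples)
    # orient to minor allele in the realized sample
    from .genotype_io import _orient_to_minor
    g = _orient_to_minor(g)

    sl = block_slices[major_block]
    causal_j = sl.start + c_local
    window = (int(block_chrom[major_block]),
              g.snps[sl.start].position_bp, g.snps[sl.stop - 1].position_bp)
    truth = SimulationTruth(
        pedigree=pedigree,
        major_locus_window=window,
        major_causal_snp_id=g.snps[causal_j].snp_id,
        tag_snp_ids=[g.snps[causal_j - 1].snp_id, g.snps[causal_j + 1].snp_id],
        rare_ids=[f"rare_{v:05d}" for v in range(n_rare)],
        rare_dosages=rare_dosages,
        family_of=family_of,
    )
    return g, truth


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        raise ValueError("component with zero variance cannot be standardized")
    return (v - v.mean()) / sd


def simulate_phenotype(g: GenotypeMatrix, truth: SimulationTruth,
                       config: SimulationConfig) -> PhenotypeTable:
    """DMA%-like phenotype over the simulated genotypes.

    phenotype = mean + sd * (major + polygenic + rare + shared-env + noise)
               + covariate effects,
    with every component rescaled in-sample to its target fraction of the
    residual (non-covariate) variance.
    """
    total_pve = (config.major_locus_pve + config.polygenic_pve
                 + config.rare_pve + config.shared_env_var)
    if total_pve >= 1:
        raise ValueError("requested variance fractions sum to >= 1")
    rng = np.random.default_rng([config.seed, 1])
    n = g.n_samples
    dos = g.dosages.astype(float)

    genetic = np.zeros(n)
    resid = np.zeros(n)
    if config.major_locus_pve > 0:
        j = g.snp_index(truth.major_causal_snp_id)
        comp = _standardize(dos[:, j]) * np.sqrt(config.major_locus_pve)
        truth.major_effect = float(np.sqrt(config.major_locus_pve)
                                   / dos[:, j].std())
        genetic += comp
        resid += comp
    if config.polygenic_pve > 0:
        chrom_major = truth.major_locus_window[0]
        eligible = [j for j, s in enumerate(g.snps)
                    if not (s.chromosome == chrom_major
                            and truth.major_locus_window[1] <= s.position_bp
                            <= truth.major_locus_window[2])]
        k = min(config.n_causal_common, len(eligible))
        causal = rng.choice(eligible, size=k, replace=False)
        eff = rng.standard_normal(k)
        raw = dos[:, causal] @ eff
        comp = _standardize(raw) * np.sqrt(config.polygenic_pve)
        scale = np.sqrt(config.polygenic_pve) / raw.std()
        truth.causal_common_ids = [g.snps[j].snp_id for j in causal]
        truth.causal_common_effects = eff * scale
        genetic += comp
        resid += comp
    if config.rare_pve > 0:
        if truth.rare_dosages.shape[1] == 0:
            raise ValueError("rare_pve > 0 but no rare variants simulated")
        eff = rng.standard_normal(truth.rare_dosages.shape[1])
        raw = truth.rare_dosages.astype(float) @ eff
        comp = _standardize(raw) * np.sqrt(config.rare_pve)
        truth.rare_effects = eff * np.sqrt(config.rare_pve) / raw.std()
        genetic += comp
        resid += comp
    if config.shared_env_var > 0:
        fams = pd.Series(truth.family_of)
        fam_dev = {f: rng.standard_normal() for f in fams.unique()}
        comp = _standardize(fams.map(fam_dev).to_numpy()) \
            * np.sqrt(config.shared_env_var)
        resid += comp
    noise = _standardize(rng.standard_normal(n)) * np.sqrt(1 - total_pve)
    resid += noise

    # covariates, with effect orientation as in the source cohort
    age = rng.uniform(18, 75, size=n)
    sex = np.array([1.0 if s.sex == "female" else 0.0 for s in g.samples])
    batch = rng.integers(0, 2, size=n).astype(float)
    water_q = rng.integers(1, 5, size=n)
    smoking = rng.integers(0, 3, size=n)
    bmi_cat = rng.integers(0, 3, size=n)
    cov_effect = (
        COVARIATE_EFFECTS["age"] * (age - age.mean())
        + COVARIATE_EFFECTS["sex"] * sex
        + COVARIATE_EFFECTS["batch"] * batch
        + np.asarray(COVARIATE_EFFECTS["water_as_quartile"])[water_q - 1]
        + np.asarray(COVARIATE_EFFECTS["smoking"])[smoking]
        + np.asarray(COVARIATE_EFFECTS["bmi_cat"])[bmi_cat]
    )

    dma = config.phenotype_mean + config.phenotype_sd * resid + cov_effect
    dma = np.clip(dma, 0.5, 99.5)
    remainder = 100.0 - dma
    w = np.clip(rng.normal(0.55, 0.05, size=n), 0.05, 0.95)
    mma = remainder * w
    ias = remainder * (1 - w)

    var_resid = resid.var()
    truth.realized_fractions = {
        "major_locus": float(config.major_locus_pve / var_resid)
        if config.major_locus_pve else 0.0,
        "polygenic": float(config.polygenic_pve / var_resid)
        if config.polygenic_pve else 0.0,
        "rare": float(config.rare_pve / var_resid) if config.rare_pve else 0.0,
        "shared_env": float(config.shared_env_var / var_resid)
        if config.shared_env_var else 0.0,
    }
    truth.genetic_values = genetic

    df = pd.DataFrame({
        "sample_id": g.sample_ids,
        "dma_pct": dma, "mma_pct": mma, "ias_pct": ias,
        "age": age, "sex": sex, "batch": batch,
        "water_as_quartile": water_q, "smoking": smoking, "bmi_cat": bmi_cat,
    })
    return PhenotypeTable(df)


def simulate_outcome(pheno: PhenotypeTable, truth: SimulationTruth,
                     config: SimulationConfig) -> np.ndarray:
    """Liability-threshold binary outcome (skin-lesion analog).

    liability = -k * (genetic component of the phenotype) + noise; the top
    ``case_fraction`` of liability are cases, so phenotype-raising alleles
    are protective.
    """
    if not 0 < config.case_fraction < 1:
        raise ValueError("case_fraction must be in (0, 1)")
    if truth.genetic_values is None:
        raise ValueError("simulate_phenotype must run before simulate_outcome")
    rng = np.random.default_rng([config.seed, 2])
    n = len(pheno.df)
    k = config.liability_genetic_weight
    gvals = truth.genetic_values
    gstd = _standardize(gvals) if gvals.std() > 0 else np.zeros(n)
    liability = -k * gstd + np.sqrt(max(1 - k**2, 0.0)) * rng.standard_normal(n)
    n_cases = int(round(config.case_fraction * n))
    order = np.argsort(liability)[::-1]
    outcome = np.zeros(n, dtype=int)
    outcome[order[:n_cases]] = 1
    return outcome
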