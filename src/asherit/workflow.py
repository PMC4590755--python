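"""End-to-end orchestration of the three analyses.

``run_heritability`` reproduces the study's estimate grid — {full IBS GRM,
thresholded (IBD-approximating) GRM} x {no adjustment, + covariates,
+ ancestry PCs, + the two major-locus tag SNPs} plus the unrelated-subset
estimate; ``run_regional`` scans overlapping SNP windows; ``run_polygenic``
sweeps score thresholds against the binary outcome with and without the
major-locus region.  All three run on the bundled synthetic dataset by
default, or on any conforming PLINK + TSV inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .genotype_io import GenotypeMatrix, read_plink
from .grm import compute_grm, grm_pca, select_unrelated, threshold_grm
from .phenotype import PhenotypeTable
from .polygenic import (DEFAULT_THRESHOLDS, build_model, exclude_region,
                        ld_prune, threshold_sweep)
from .regional import (bonferroni_threshold, make_windows, manhattan_plot,
                       regional_scan, results_table)
from .reml import (REMLError, VarianceComponentModel, add_snp_covariates,
                   fit_with_lrt)
from .simulate import (SimulationConfig, simulate_genotypes,
                       simulate_outcome, simulate_phenotype)

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class PipelineConfig:
    simulation: SimulationConfig = dataclasses.field(default_factory=SimulationConfig)
    plink_prefix: str | None = None      # use files instead of simulating
    phenotype_tsv: str | None = None
    outcome_tsv: str | None = None
    run_heritability: bool = True
    run_regional: bool = True
    run_polygenic: bool = True
    grm_cutoff: float = 0.05
    window_size: int = 100
    window_overlap: int = 50
    score_thresholds: tuple = DEFAULT_THRESHOLDS
    prune_r2: float = 0.2
    prune_window: int = 50
    prune_step: int = 5
    score_maf_min: float = 0.05
    region_flank_bp: int = 1_000_000
    n_pcs: int = 20
    train_fraction: float = 0.6
    seed: int = 42

    def __post_init__(self) -> None:
        if not (self.run_heritability or self.run_regional or self.run_polygenic):
            raise ValueError("at least one analysis must be enabled")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(open(path)) or {}
        sim = SimulationConfig(**raw.pop("simulation", {}))
        if "score_thresholds" in raw:
            raw["score_thresholds"] = tuple(raw["score_thresholds"])
        return cls(simulation=sim, **raw)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


def build_dataset(config: PipelineConfig) -> dict:
    """Load or simulate the genotype/phenotype/outcome triple."""
    if config.plink_prefix:
        g = read_plink(config.plink_prefix)
        pheno = PhenotypeTable.from_tsv(config.phenotype_tsv).aligned_to(g.sample_ids)
        outcome = None
        if config.outcome_tsv:
            out_df = pd.read_csv(config.outcome_tsv, sep="\t").set_index("sample_id")
            outcome = out_df.loc[g.sample_ids, "outcome"].to_numpy()
        truth = None
    else:
        sim = dataclasses.replace(config.simulation, seed=config.seed)
        g, truth = simulate_genotypes(sim)
        pheno = simulate_phenotype(g, truth, sim)
        outcome = simulate_outcome(pheno, truth, sim)
    logger.info("dataset: %d samples, %d SNPs", g.n_samples, g.n_snps)
    return {"g": g, "pheno": pheno, "outcome": outcome, "truth": truth}


def _fit_row(y, X, grm, name, adjustment):
    try:
        model = VarianceComponentModel(y, X, [grm], ["genome"])
        fit = fit_with_lrt(model)
        return {"design": name, "adjustment": adjustment,
                "pve": fit.pve[0], "se": fit.pve_se[0],
                "p": fit.lrt_p, "n": fit.n,
                "converged": fit.converged, "flag": ""}
    except REMLError as exc:
        return {"design": name, "adjustment": adjustment,
                "pve": np.nan, "se": np.nan, "p": np.nan,
                "n": len(y), "converged": False, "flag": str(exc)}


def run_heritability(config: PipelineConfig, data: dict | None = None) -> pd.DataFrame:
    """The PVE estimate grid over GRM designs and covariate adjustments."""
    data = data or build_dataset(config)
    g, pheno, truth = data["g"], data["pheno"], data["truth"]
    y = pheno.df["dma_pct"].to_numpy()
    n = g.n_samples

    grm_full = compute_grm(g)
    grm_thr = threshold_grm(grm_full, config.grm_cutoff)
    pcs = grm_pca(grm_full, min(config.n_pcs, n - 1))
    X_cov = pheno.covariate_design()
    X_pcs = np.hstack([X_cov, pcs])
    tag_ids = truth.tag_snp_ids if truth is not None else []

    rows = []
    for name, grm in (("full_grm", grm_full), ("thresholded_grm", grm_thr)):
        designs = [("none", np.ones((n, 1))), ("covariates", X_cov),
                   ("covariates+pcs", X_pcs)]
        for adj, X in designs:
            rows.append(_fit_row(y, X, grm, name, adj))
        if tag_ids:
            model = VarianceComponentModel(y, X_pcs, [grm], ["genome"])
            model = add_snp_covariates(model, g, tag_ids)
            rows.append(_fit_row(y, model.X, grm, name,
                                 "covariates+pcs+major_snps"))

    # unrelated-subset estimate (h_g^2): PCs recomputed on the subset
    keep = select_unrelated(grm_full, config.grm_cutoff)
    idx = [g.sample_ids.index(s) for s in keep]
    g_u = g.subset(sample_idx=idx)
    grm_u = compute_grm(g_u)
    pheno_u = pheno.aligned_to(keep)
    X_u = pheno_u.covariate_design()
    if len(idx) > config.n_pcs + X_u.shape[1] + 2:
        X_u = np.hstack([X_u, grm_pca(grm_u, min(config.n_pcs, len(idx) - 1))])
    rows.append(_fit_row(pheno_u.df["dma_pct"].to_numpy(), X_u, grm_u,
                         "unrelated_subset", "covariates+pcs"))
    table = pd.DataFrame(rows)
    logger.info("heritability grid:\n%s", table)
    return table


def run_regional(config: PipelineConfig, data: dict | None = None,
                 plot_path=None):
    """Windowed scan on the unrelated subset; Bonferroni from realized count."""
    data = data or build_dataset(config)
    g, pheno = data["g"], data["pheno"]
    grm_full = compute_grm(g)
    keep = select_unrelated(grm_full, config.grm_cutoff)
    idx = [g.sample_ids.index(s) for s in keep]
    g_u = g.subset(sample_idx=idx)
    pheno_u = pheno.aligned_to(keep)
    windows = make_windows(g_u.snps, config.window_size, config.window_overlap)
    results = regional_scan(g_u, pheno_u.df["dma_pct"].to_numpy(), windows,
                            covariates=pheno_u.covariate_design())
    table = results_table(g_u, results)
    n_tests = int((~table["skipped"]).sum())
    thr = bonferroni_threshold(0.05, max(n_tests, 1))
    table["significant"] = table["p"] < thr
    if plot_path is not None:
        manhattan_plot(table, thr, plot_path)
    logger.info("regional scan: %d windows, Bonferroni %.3g, %d significant",
                len(windows), thr, int(table["significant"].sum()))
    return table, thr


def _train_test_split(g: GenotypeMatrix, frac: float, seed: int):
    """Family-aware split: whole families assigned to one side (no leakage)."""
    rng = np.random.default_rng([seed, 9])
    fams = pd.Series([s.family_id for s in g.samples])
    unique = fams.unique()
    n_train_f = int(round(frac * len(unique)))
    train_f = set(rng.permutation(unique)[:n_train_f])
    train_idx = np.flatnonzero(fams.isin(train_f))
    test_idx = np.flatnonzero(~fams.isin(train_f))
    return train_idx, test_idx


def run_polygenic(config: PipelineConfig, data: dict | None = None) -> pd.DataFrame:
    """Threshold sweep with and without the major-locus region excluded."""
    data = data or build_dataset(config)
    g, pheno, outcome, truth = (data["g"], data["pheno"], data["outcome"],
                                data["truth"])
    if outcome is None:
        raise ValueError("polygenic analysis needs a binary outcome")
    train_idx, test_idx = _train_test_split(g, config.train_fraction, config.seed)
    g_tr, g_te = g.subset(sample_idx=train_idx), g.subset(sample_idx=test_idx)
    pheno_tr = pheno.aligned_to(g_tr.sample_ids)
    pheno_te = pheno.aligned_to(g_te.sample_ids)
    y_tr = pheno_tr.df["dma_pct"].to_numpy()
    out_te = np.asarray(outcome)[test_idx]

    pruned = ld_prune(g_tr, config.prune_r2, config.prune_window,
                      config.prune_step)
    cov_tr = pheno_tr.covariate_design(["age", "sex", "batch",
                                        "water_as_quartile"])
    cov_te = pheno_te.covariate_design(["age", "sex", "batch"])
    grm_te = compute_grm(g_te)

    sweeps = []
    variants = {"with_major_region": pruned}
    if truth is not None:
        chrom, start, end = truth.major_locus_window
        kept = set(exclude_region(g_tr.snps, chrom, start, end,
                                  config.region_flank_bp))
        variants["non_major_region"] = [s for s in pruned if s in kept]
    for label, snp_set in variants.items():
        model = build_model(g_tr, y_tr, snp_set, covariates=cov_tr,
                            maf_min=config.score_maf_min)
        tab = threshold_sweep(model, g_te, out_te, cov_te, grm_te,
                              config.score_thresholds)
        tab.insert(0, "snp_set", label)
        sweeps.append(tab)
    table = pd.concat(sweeps, ignore_index=True)
    logger.info("polygenic sweep:\n%s", table)
    return table


def run_all(config: PipelineConfig, out_dir: str | Path,
            plot: bool = False) -> dict:
    """Run the enabled analyses; write tables and a run manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    data = build_dataset(config)
    manifest = {"config_hash": self_hash(config), "seed": config.seed,
                "version": __version__,
                "n_samples": data["g"].n_samples, "n_snps": data["g"].n_snps}
    outputs = {}
    if config.run_heritability:
        tab = run_heritability(config, data)
        tab.to_csv(out_dir / "heritability.tsv", sep="\t", index=False)
        outputs["heritability"] = tab
    if config.run_regional:
        plot_path = out_dir / "regional.png" if plot else None
        tab, thr = run_regional(config, data, plot_path=plot_path)
        tab.to_csv(out_dir / "regional.tsv", sep="\t", index=False)
        manifest["bonferroni_threshold"] = thr
        outputs["regional"] = tab
    if config.run_polygenic:
        tab = run_polygenic(config, data)
        tab.to_csv(out_dir / "polygenic.tsv", sep="\t", index=False)
        outputs["polygenic"] = tab
    with open(out_dir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return outputs


def self_hash(config: PipelineConfig) -> str:
    return config.config_hash()
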