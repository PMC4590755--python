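"""Pruning-and-thresholding polygenic scores and odds-ratio conversion.

A training cohort supplies per-SNP betas (phenotype units per minor allele,
adjusted for covariates); scores in a disjoint testing cohort are mean
weighted allele counts over the SNPs passing each p-value threshold.  Betas
from the linear-scale score-outcome regression are converted to odds ratios
by dividing by x(1-x) (x the case proportion) and exponentiating.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from .genotype_io import MISSING, GenotypeMatrix, SnpRecord, allele_frequencies
from .grm import RelatednessMatrix
from .association import MixedModelNull

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = (1e-4, 1e-3, 0.01, 0.1, 0.3, 0.5)


@dataclasses.dataclass
class PolygenicModel:
    """Per-SNP training betas with p-values (PLINK --score compatible)."""

    entries: pd.DataFrame  # columns snp_id, a1, beta, p
    provenance: dict

    def __post_init__(self) -> None:
        need = {"snp_id", "a1", "beta", "p"}
        if not need <= set(self.entries.columns):
            raise ValueError(f"model entries need columns {sorted(need)}")
        if self.entries["snp_id"].duplicated().any():
            raise ValueError("duplicate snp_ids in polygenic model")
        p = self.entries["p"]
        if ((p <= 0) | (p > 1)).any():
            raise ValueError("model p-values must lie in (0, 1]")

    def at_threshold(self, threshold: float) -> pd.DataFrame:
        return self.entries[self.entries["p"] < threshold]

    def to_tsv(self, path) -> None:
        out = self.entries.rename(columns={"snp_id": "SNP", "a1": "A1",
                                           "beta": "BETA", "p": "P"})
        out[["SNP", "A1", "BETA", "P"]].to_csv(path, sep="\t", index=False)


@dataclasses.dataclass
class ScoreSet:
    scores: pd.Series  # index sample_id
    threshold: float
    n_snps_used: int
    n_dropped: int = 0  # model SNPs absent from the testing panel


def ld_prune(g: GenotypeMatrix, r2_max: float = 0.2, window: int = 50,
             step: int = 5) -> list[str]:
    """Sliding-window greedy LD pruning (PLINK --indep-pairwise semantics).

    Within each window, while any retained pair has r^2 > r2_max, the
    member of the worst offending pair with the lower MAF is removed (ties
    broken against the later position).  Returns retained snp_ids in order.
    """
    if not 0 < r2_max < 1:
        raise ValueError("r2_max must be in (0, 1)")
    dos = g.dosages.astype(float)
    miss = g.dosages == MISSING
    if miss.any():
        col_mean = np.where(miss, np.nan, dos).astype(float)
        means = np.nanmean(col_mean, axis=0)
        dos[miss] = np.take(means, np.where(miss)[1])
    freq = allele_frequencies(g)
    maf = np.minimum(freq, 1 - freq)
    m = g.n_snps
    keep = np.ones(m, dtype=bool)
    start = 0
    while start < m:
        idx = np.flatnonzero(keep[start:start + window]) + start
        if idx.size > 1:
            sub = dos[:, idx]
            sd = sub.std(axis=0)
            ok = sd > 0
            with np.errstate(invalid="ignore"):
                r = np.corrcoef(sub[:, ok], rowvar=False)
            r2 = np.zeros((idx.size, idx.size))
            r2[np.ix_(ok, ok)] = r * r
            np.fill_diagonal(r2, 0.0)
            active = np.ones(idx.size, dtype=bool)
            while True:
                masked = np.where(np.outer(active, active), r2, 0.0)
                worst = masked.max()
                if worst <= r2_max:
                    break
                i, j = np.unravel_index(np.argmax(masked), masked.shape)
                a, b = idx[i], idx[j]
                if maf[a] < maf[b]:
                    drop = i
                elif maf[b] < maf[a]:
                    drop = j
                else:  # tie: drop the later position
                    drop = i if a > b else j
                active[drop] = False
                keep[idx[drop]] = False
        if start + window >= m:
            break
        start += step
    return [g.snps[j].snp_id for j in np.flatnonzero(keep)]


def exclude_region(snps: list[SnpRecord], chromosome: int, start_bp: int,
                   end_bp: int, flank_bp: int = 1_000_000) -> list[str]:
    """Drop SNPs within +-flank of a region (inclusive bounds); return kept ids."""
    if start_bp > end_bp:
        raise ValueError("start_bp must not exceed end_bp")
    lo, hi = start_bp - flank_bp, end_bp + flank_bp
    return [s.snp_id for s in snps
            if not (s.chromosome == chromosome and lo <= s.position_bp <= hi)]


def snp_accounting(n_genotyped: int, n_pruned: int, n_region: int,
                   n_low_maf: int) -> int:
    """Model-SNP bookkeeping: genotyped minus pruned, region-excluded, low-MAF."""
    remaining = n_genotyped - n_pruned - n_region - n_low_maf
    if remaining < 0:
        raise ValueError("exclusions exceed the genotyped SNP count")
    return remaining


def build_model(training_g: GenotypeMatrix, training_y, retained_snps,
                covariates=None, maf_min: float = 0.05) -> PolygenicModel:
    """Per-SNP training regressions over the retained, MAF-filtered SNPs.

    Each SNP's beta is the OLS coefficient of the phenotype on its
    minor-allele count given the training covariates (residual regression,
    vectorized over SNPs); missing dosages are mean-imputed per SNP.
    """
    if len(retained_snps) == 0:
        raise ValueError("retained SNP set is empty")
    idx = [training_g.snp_index(s) for s in retained_snps]
    freq = allele_frequencies(training_g)
    maf = np.minimum(freq, 1 - freq)
    idx = [j for j in idx if maf[j] >= maf_min]
    if not idx:
        raise ValueError("no SNPs remain after the MAF filter")
    y = np.asarray(training_y, dtype=float).ravel()
    n = y.shape[0]
    C = (np.ones((n, 1)) if covariates is None
         else np.atleast_2d(np.asarray(covariates, dtype=float)))
    dos = training_g.dosages[:, idx].astype(float)
    miss = training_g.dosages[:, idx] == MISSING
    if miss.any():
        tmp = np.where(miss, np.nan, dos)
        means = np.nanmean(tmp, axis=0)
        dos[miss] = np.take(means, np.where(miss)[1])
    # residualize on covariates once (Frisch-Waugh)
    Q, _ = np.linalg.qr(C)
    y_r = y - Q @ (Q.T @ y)
    X_r = dos - Q @ (Q.T @ dos)
    ssx = np.einsum("ij,ij->j", X_r, X_r)
    ok = ssx > 0
    beta = np.full(len(idx), np.nan)
    se = np.full(len(idx), np.nan)
    beta[ok] = (X_r[:, ok].T @ y_r) / ssx[ok]
    dof = n - C.shape[1] - 1
    resid_ss = np.maximum(
        float(y_r @ y_r) - beta[ok] ** 2 * ssx[ok], 0.0)
    sigma2 = resid_ss / dof
    se[ok] = np.sqrt(sigma2 / ssx[ok])
    with np.errstate(invalid="ignore", divide="ignore"):
        tval = beta / se
    p = 2.0 * t_dist.sf(np.abs(tval), dof)
    p = np.where(np.isfinite(p), np.clip(p, np.finfo(float).tiny, 1.0), np.nan)
    entries = pd.DataFrame({
        "snp_id": [training_g.snps[j].snp_id for j in idx],
        "a1": [training_g.snps[j].allele_minor for j in idx],
        "beta": beta,
        "p": p,
    }).dropna(subset=["beta", "p"])
    return PolygenicModel(entries, {
        "maf_min": maf_min,
        "n_training": n,
        "training_sample_ids": list(training_g.sample_ids),
    })


def compute_scores(testing_g: GenotypeMatrix, model: PolygenicModel,
                   threshold: float) -> ScoreSet:
    """Mean weighted minor-allele count over SNPs passing the threshold.

    Per individual the denominator counts scored SNPs with a non-missing
    genotype; model SNPs absent from the testing panel are dropped with a
    logged count.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    sub = model.at_threshold(threshold)
    if len(sub) == 0:
        raise ValueError(f"zero model SNPs pass threshold {threshold}")
    testing_ids = set(testing_g.snp_ids)
    present = sub[sub["snp_id"].isin(testing_ids)]
    n_dropped = len(sub) - len(present)
    if n_dropped:
        logger.info("compute_scores: %d model SNPs absent from testing panel",
                    n_dropped)
    if len(present) == 0:
        raise ValueError(
            f"no model SNPs passing threshold {threshold} are present "
            "in the testing panel")
    idx = [testing_g.snp_index(s) for s in present["snp_id"]]
    dos = testing_g.dosages[:, idx].astype(float)
    obs = testing_g.dosages[:, idx] != MISSING
    dos[~obs] = 0.0
    betas = present["beta"].to_numpy()
    num = dos @ betas
    denom = obs.sum(axis=1).astype(float)
    scores = np.where(denom > 0, num / np.maximum(denom, 1), np.nan)
    return ScoreSet(pd.Series(scores, index=testing_g.sample_ids),
                    threshold, len(present), n_dropped)


def beta_to_or(beta: float, n_cases: int, n_controls: int) -> float:
    """Per-SD linear-model beta -> odds ratio via the case-proportion rescaling.

    x = n_cases / (n_cases + n_controls); OR = exp(beta / (x (1 - x))).
    """
    if n_cases < 1 or n_controls < 1:
        raise ValueError("need at least one case and one control")
    x = n_cases / (n_cases + n_controls)
    return float(np.exp(beta / (x * (1 - x))))


def or_with_ci(beta: float, se: float, n_cases: int, n_controls: int):
    """(OR, lower, upper) with the CI transformed from beta +- 1.96 se."""
    return (beta_to_or(beta, n_cases, n_controls),
            beta_to_or(beta - 1.96 * se, n_cases, n_controls),
            beta_to_or(beta + 1.96 * se, n_cases, n_controls))


def threshold_sweep(model: PolygenicModel, testing_g: GenotypeMatrix,
                    testing_outcome, covariates, grm: RelatednessMatrix,
                    thresholds=DEFAULT_THRESHOLDS) -> pd.DataFrame:
    """Score-outcome association at each p-value threshold (Table-3 style).

    Scores are standardized to unit SD in the testing set, so betas are per
    SD of score; the binary outcome is analyzed with the linear mixed model
    under the supplied GRM.  Thresholds passed by zero SNPs yield an
    n_snps = 0 row with NaN statistics.  Any overlap between training and
    testing samples is refused (leakage guard).
    """
    train_ids = set(model.provenance.get("training_sample_ids", ()))
    overlap = train_ids & set(testing_g.sample_ids)
    if overlap:
        raise ValueError(
            f"{len(overlap)} samples appear in both training and testing sets")
    outcome = np.asarray(testing_outcome, dtype=float).ravel()
    n_cases = int(outcome.sum())
    n_controls = int(len(outcome) - n_cases)
    null_fit = MixedModelNull(outcome, covariates, grm)
    rows = []
    for thr in thresholds:
        try:
            ss = compute_scores(testing_g, model, thr)
        except ValueError:
            rows.append({"threshold": thr, "n_snps": 0, "beta": np.nan,
                         "se": np.nan, "p": np.nan, "OR": np.nan,
                         "OR_lo": np.nan, "OR_hi": np.nan})
            continue
        sc = ss.scores.to_numpy()
        sd = np.nanstd(sc)
        sc_std = (sc - np.nanmean(sc)) / sd if sd > 0 else sc
        res = null_fit.test(sc_std, predictor_id=f"score_p<{thr}")
        if np.isfinite(res.beta):
            orr, lo, hi = or_with_ci(res.beta, res.se, n_cases, n_controls)
        else:
            orr = lo = hi = np.nan
        rows.append({"threshold": thr, "n_snps": ss.n_snps_used,
                     "beta": res.beta, "se": res.se, "p": res.p,
                     "OR": orr, "OR_lo": lo, "OR_hi": hi})
    return pd.DataFrame(rows)
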