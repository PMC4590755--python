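"""Regional heritability mapping: windowed two-variance-component scans.

Each window of consecutive SNPs contributes a local GRM that is fitted
jointly with the genome-wide GRM (built from all SNPs, window included):

    y = X beta + g_region + g_genome + e.

The regional PVE and a boundary-mixture LRT p-value against the
genome-only model are reported per window; significance is judged against
a Bonferroni threshold for the realized number of windows.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, SnpRecord, allele_frequencies
from .grm import compute_grm
from .reml import (GenomeRotation, fit_genome_rotated,
                   fit_two_component_rotated, lrt_pvalue, pve_with_se)


@dataclasses.dataclass(frozen=True)
class Window:
    chromosome: int
    snp_index_start: int  # 0-based half-open, into the full sorted SNP list
    snp_index_end: int
    snp_ids: tuple

    @property
    def n_snps(self) -> int:
        return self.snp_index_end - self.snp_index_start


@dataclasses.dataclass
class RegionalResult:
    window: Window
    pve_regional: float
    se: float
    lrt_p: float
    pve_genomewide: float
    skipped: bool = False


def make_windows(snps: list[SnpRecord], window_size: int = 100,
                 overlap: int = 50) -> list[Window]:
    """Overlapping windows per chromosome over position-sorted SNPs.

    Starts advance by (window_size - overlap); a trailing window clipped at
    the chromosome end is emitted only when it covers SNPs no earlier
    window reached.  Windows never span chromosomes.
    """
    if overlap >= window_size:
        raise ValueError("overlap must be smaller than window_size")
    order = sorted(range(len(snps)),
                   key=lambda i: (snps[i].chromosome, snps[i].position_bp))
    by_chrom: dict[int, list[int]] = {}
    for i in order:
        by_chrom.setdefault(snps[i].chromosome, []).append(i)
    stride = window_size - overlap
    windows: list[Window] = []
    for chrom in sorted(by_chrom):
        idx = by_chrom[chrom]
        n = len(idx)
        chrom_windows: list[Window] = []
        covered = 0
        start = 0
        while start < n:
            end = min(start + window_size, n)
            if end <= covered:
                break
            if end - start >= overlap or not chrom_windows:
                chrom_windows.append(Window(
                    chrom, start, end,
                    tuple(snps[idx[i]].snp_id for i in range(start, end))))
                covered = end
            else:
                # too short to stand alone: absorb into the previous window
                prev = chrom_windows[-1]
                chrom_windows[-1] = Window(
                    chrom, prev.snp_index_start, end,
                    prev.snp_ids + tuple(snps[idx[i]].snp_id
                                         for i in range(prev.snp_index_end, end)))
                covered = end
            start += stride
        windows.extend(chrom_windows)
    return windows


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    if n_tests < 1:
        raise ValueError("n_tests must be at least 1")
    return alpha / n_tests


def _window_design(g: GenotypeMatrix, window: Window):
    """Standardized, 1/sqrt(m)-scaled window dosages so Z Z' is the local GRM."""
    idx = [g.snp_index(s) for s in window.snp_ids]
    dos = g.dosages[:, idx].astype(float)
    miss = g.dosages[:, idx] == MISSING
    if miss.any():
        tmp = np.where(miss, np.nan, dos)
        means = np.nanmean(tmp, axis=0)
        dos[miss] = np.take(means, np.where(miss)[1])
    freq = dos.mean(axis=0) / 2.0
    poly = (freq > 0) & (freq < 1)
    if poly.sum() < 2:
        return None
    dos = dos[:, poly]
    p = freq[poly]
    z = (dos - 2 * p) / np.sqrt(2 * p * (1 - p))
    return z / np.sqrt(z.shape[1])


def regional_scan(g: GenotypeMatrix, y, windows: list[Window],
                  covariates=None, genome_grm=None,
                  tol: float = 1e-6) -> list[RegionalResult]:
    """Two-component REML over every window.

    The genome-wide GRM (all SNPs, computed here unless supplied) is
    eigendecomposed once; each window then adds a low-rank local component,
    making the per-window fit O(n m_window).  The LRT compares each full
    fit against the genome-only model fitted once.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.shape[0]
    X = (np.ones((n, 1)) if covariates is None
         else np.atleast_2d(np.asarray(covariates, dtype=float)))
    if genome_grm is None:
        genome_grm = compute_grm(g)
    rot = GenomeRotation(genome_grm)
    y_rot = rot.rotate(y[:, None]).ravel()
    X_rot = rot.rotate(X)
    reduced = fit_genome_rotated(rot, y_rot, X_rot, tol=tol)
    results = []
    for w in windows:
        Z = _window_design(g, w)
        if Z is None:
            results.append(RegionalResult(w, np.nan, np.nan, np.nan,
                                          np.nan, skipped=True))
            continue
        fit = fit_two_component_rotated(rot, y_rot, X_rot, rot.rotate(Z),
                                        tol=tol)
        p = lrt_pvalue(max(fit.loglik_reml, reduced.loglik_reml),
                       reduced.loglik_reml)
        pve_r, se_r = pve_with_se(fit, 0)
        pve_g, _ = pve_with_se(fit, 1)
        results.append(RegionalResult(w, pve_r, se_r, p, pve_g))
    return results


def results_table(g: GenotypeMatrix, results: list[RegionalResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        first = g.snps[g.snp_index(r.window.snp_ids[0])]
        last = g.snps[g.snp_index(r.window.snp_ids[-1])]
        rows.append({
            "chrom": r.window.chromosome,
            "start_bp": first.position_bp,
            "end_bp": last.position_bp,
            "n_snps": r.window.n_snps,
            "pve": r.pve_regional,
            "se": r.se,
            "p": r.lrt_p,
            "skipped": r.skipped,
        })
    return pd.DataFrame(rows)


def manhattan_plot(table: pd.DataFrame, threshold: float, path) -> None:
    """Minus-log10 p per window with the Bonferroni line (file output only)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ok = table[~table["skipped"] & table["p"].notna()]
    fig, ax = plt.subplots(figsize=(9, 3))
    colors = np.where(ok["chrom"] % 2 == 0, "tab:blue", "tab:gray")
    ax.scatter(range(len(ok)), -np.log10(ok["p"]), s=8, c=colors)
    ax.axhline(-np.log10(threshold), color="red", lw=1)
    ax.set_xlabel("window")
    ax.set_ylabel("-log10 p")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
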