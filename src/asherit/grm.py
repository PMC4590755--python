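"""Genetic relationship matrices: construction, modification, PCA, GCTA I/O.

The GRM estimator is the standard standardized-dosage average: for samples
j, k and SNP i with minor-allele dosage x_ij and sample frequency p_i,

    A_jk = (1/m_jk) sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i))
    A_jj = 1 + (1/m_jj) sum_i [x_ij^2 - (1 + 2 p_i) x_ij + 2 p_i^2] / (2 p_i (1 - p_i))

with sums over SNPs non-missing for the pair and m the per-pair SNP count.
Thresholding small off-diagonal entries to zero turns the identity-by-state
matrix into an approximate identity-by-descent matrix for close relatives.
"""

from __future__ import annotations

import dataclasses
import hashlib
from pathlib import Path

import numpy as np

from .genotype_io import MISSING, GenotypeMatrix, allele_frequencies


@dataclasses.dataclass
class RelatednessMatrix:
    values: np.ndarray                  # n x n, float64, symmetric
    sample_ids: list[str]
    n_snps_used: np.ndarray             # n x n per-pair non-missing SNP counts
    provenance: dict
    family_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("GRM shape does not match sample_ids")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("GRM must be symmetric")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def subset(self, idx) -> "RelatednessMatrix":
        idx = np.asarray(idx)
        prov = dict(self.provenance, modification="subset")
        return RelatednessMatrix(
            self.values[np.ix_(idx, idx)],
            [self.sample_ids[i] for i in idx],
            self.n_snps_used[np.ix_(idx, idx)],
            prov,
            [self.family_ids[i] for i in idx] if self.family_ids else None,
        )


def compute_grm(g: GenotypeMatrix) -> RelatednessMatrix:
    """IBS relationship matrix from minor-allele dosages.

    Allele frequencies are estimated from the input sample itself; missing
    genotypes are excluded pairwise; monomorphic SNPs are skipped.
    """
    if g.n_samples < 2:
        raise ValueError("need at least two samples")
    freq = allele_frequencies(g)
    poly = (freq > 0) & (freq < 1) & ~np.isnan(freq)
    if not poly.any():
        raise ValueError("no polymorphic SNPs")
    x = g.dosages[:, poly].astype(np.float64)
    obs = g.dosages[:, poly] != MISSING
    p = freq[poly]
    denom = 2.0 * p * (1.0 - p)

    w = np.where(obs, (x - 2.0 * p) / np.sqrt(denom), 0.0)
    num = w @ w.T
    counts = obs.astype(np.float64) @ obs.T.astype(np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = np.where(counts > 0, num / counts, 0.0)

    diag_terms = np.where(obs, (x * x - (1.0 + 2.0 * p) * x + 2.0 * p * p) / denom, 0.0)
    m_jj = obs.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        diag = 1.0 + np.where(m_jj > 0, diag_terms.sum(axis=1) / m_jj, 0.0)
    np.fill_diagonal(a, diag)
    a = (a + a.T) / 2.0

    snp_hash = hashlib.sha1("\n".join(g.snp_ids).encode()).hexdigest()[:12]
    return RelatednessMatrix(
        a,
        g.sample_ids,
        counts.astype(np.int64),
        {"estimator": "ibs_standardized", "snp_set_hash": snp_hash,
         "n_snps": int(poly.sum()), "modification": "none"},
        [s.family_id for s in g.samples],
    )


def threshold_grm(a: RelatednessMatrix, cutoff: float = 0.05) -> RelatednessMatrix:
    """Zero every off-diagonal entry strictly below ``cutoff``.

    This discards apparent distant relatedness, approximating an IBD matrix
    in which only close relatives are related; the diagonal is untouched.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be non-negative")
    vals = a.values.copy()
    off = ~np.eye(a.n, dtype=bool)
    vals[off & (vals < cutoff)] = 0.0
    return RelatednessMatrix(
        vals, list(a.sample_ids), a.n_snps_used.copy(),
        dict(a.provenance, modification="thresholded", threshold=cutoff),
        list(a.family_ids) if a.family_ids else None,
    )


def select_unrelated(a: RelatednessMatrix, cutoff: float = 0.05) -> list[str]:
    """Greedy maximal subset with all pairwise relatedness below ``cutoff``.

    While any off-diagonal entry >= cutoff remains, drop the sample in the
    most offending pairs (ties broken by lexicographically smallest id).
    Returns retained sample_ids in the original order.
    """
    vals = a.values.copy()
    np.fill_diagonal(vals, 0.0)
    active = np.ones(a.n, dtype=bool)
    adj = vals >= cutoff
    while True:
        deg = (adj & active[None, :] & active[:, None]).sum(axis=1)
        deg[~active] = 0
        if deg.max() == 0:
            break
        worst = deg.max()
        candidates = np.flatnonzero(deg == worst)
        drop = min(candidates, key=lambda i: a.sample_ids[i])
        active[drop] = False
    return [a.sample_ids[i] for i in np.flatnonzero(active)]


def grm_pca(a: RelatednessMatrix, k: int = 20) -> np.ndarray:
    """Top-k GRM eigenvectors (ancestry principal components).

    Columns are unit-norm eigenvectors for the k largest eigenvalues, with
    the deterministic sign convention that the largest-magnitude loading of
    each column is positive.
    """
    if k >= a.n:
        raise ValueError("k must be smaller than the number of samples")
    if not np.allclose(a.values, a.values.T, atol=1e-10):
        raise ValueError("GRM must be symmetric")
    evals, evecs = np.linalg.eigh(a.values)
    order = np.argsort(evals)[::-1][:k]
    pcs = evecs[:, order]
    for j in range(pcs.shape[1]):
        i = np.argmax(np.abs(pcs[:, j]))
        if pcs[i, j] < 0:
            pcs[:, j] = -pcs[:, j]
    return pcs


def write_grm(a: RelatednessMatrix, prefix: str | Path) -> None:
    """GCTA triple: .grm.bin / .grm.N.bin (float32 lower triangle) / .grm.id."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    idx = np.tril_indices(a.n)
    a.values[idx].astype("<f4").tofile(f"{prefix}.grm.bin")
    a.n_snps_used[idx].astype("<f4").tofile(f"{prefix}.grm.N.bin")
    fids = a.family_ids or a.sample_ids
    with open(f"{prefix}.grm.id", "w") as fh:
        for fid, iid in zip(fids, a.sample_ids):
            fh.write(f"{fid}\t{iid}\n")


def read_grm(prefix: str | Path) -> RelatednessMatrix:
    prefix = Path(prefix)
    ids = [line.split() for line in open(f"{prefix}.grm.id")]
    n = len(ids)
    n_tri = n * (n + 1) // 2
    tri = np.fromfile(f"{prefix}.grm.bin", dtype="<f4")
    if tri.size != n_tri:
        raise ValueError(
            f"{prefix}.grm.bin holds {tri.size} values; {n_tri} expected for n={n}"
        )
    counts = np.fromfile(f"{prefix}.grm.N.bin", dtype="<f4")
    if counts.size != n_tri:
        raise ValueError(f"{prefix}.grm.N.bin size mismatch")
    vals = np.zeros((n, n))
    nmat = np.zeros((n, n))
    idx = np.tril_indices(n)
    vals[idx] = tri
    nmat[idx] = counts
    vals = vals + np.tril(vals, -1).T
    nmat = nmat + np.tril(nmat, -1).T
    return RelatednessMatrix(
        vals, [iid for _, iid in ids], nmat.astype(np.int64),
        {"estimator": "ibs_standardized", "snp_set_hash": "unknown",
         "modification": "none"},
        [fid for fid, _ in ids],
    )
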