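"""PLINK 1.9 binary genotype I/O, QC filters and per-SNP summaries.

Genotypes are held as an additive dosage matrix (samples x SNPs) counting
copies of the *minor* allele, with a distinct missing sentinel.  The on-disk
format is the standard SNP-major bed/bim/fam triple; reading and writing are
bit-exact inverses of each other.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

MISSING = np.int8(-1)

_BED_MAGIC = bytes([0x6C, 0x1B])
_BED_SNP_MAJOR = 0x01

# 2-bit PLINK codes -> dosage of allele A1 (A1 = minor allele as written here).
# 00 = hom A1 (2 copies), 01 = missing, 10 = het, 11 = hom A2 (0 copies).
_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_DOSAGE_TO_CODE = {2: 0b00, -1: 0b01, 1: 0b10, 0: 0b11}


class PlinkFormatError(ValueError):
    """Malformed bed/bim/fam content (bad magic bytes, bad mode)."""


class PlinkConsistencyError(ValueError):
    """bed/bim/fam sizes disagree with each other."""


@dataclasses.dataclass(frozen=True)
class SnpRecord:
    snp_id: str
    chromosome: int
    position_bp: int
    allele_minor: str
    allele_major: str


@dataclasses.dataclass(frozen=True)
class SampleRecord:
    sample_id: str
    family_id: str
    sex: str = "unknown"  # {male, female, unknown}


_SEX_TO_FAM = {"male": "1", "female": "2", "unknown": "0"}
_FAM_TO_SEX = {"1": "male", "2": "female"}


@dataclasses.dataclass
class GenotypeMatrix:
    """Samples x SNPs minor-allele dosage matrix with metadata.

    ``dosages`` is int8 with entries in {0, 1, 2} or ``MISSING`` (-1).
    """

    dosages: np.ndarray
    snps: list[SnpRecord]
    samples: list[SampleRecord]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x SNPs)")
        n, m = self.dosages.shape
        if n != len(self.samples) or m != len(self.snps):
            raise PlinkConsistencyError(
                f"dosage shape {self.dosages.shape} does not match metadata "
                f"({len(self.samples)} samples, {len(self.snps)} SNPs)"
            )

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def dosages_float(self) -> np.ndarray:
        """Dosages as float64 with NaN at missing entries."""
        out = self.dosages.astype(np.float64)
        out[self.dosages == MISSING] = np.nan
        return out

    def snp_index(self, snp_id: str) -> int:
        try:
            return self.snp_ids.index(snp_id)
        except ValueError:
            raise KeyError(f"unknown snp_id {snp_id!r}") from None

    def subset(self, sample_idx=None, snp_idx=None) -> "GenotypeMatrix":
        sample_idx = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        snp_idx = np.arange(self.n_snps) if snp_idx is None else np.asarray(snp_idx)
        return GenotypeMatrix(
            self.dosages[np.ix_(sample_idx, snp_idx)],
            [self.snps[i] for i in snp_idx],
            [self.samples[i] for i in sample_idx],
        )


def _pack_snp(dosages: np.ndarray) -> np.ndarray:
    """Pack one SNP's dosage column into PLINK 2-bit codes (little-endian)."""
    codes = np.empty(dosages.shape[0], dtype=np.uint8)
    for dos, code in _DOSAGE_TO_CODE.items():
        codes[dosages == dos] = code
    n = codes.shape[0]
    nbytes = (n + 3) // 4
    padded = np.zeros(nbytes * 4, dtype=np.uint8)
    padded[:n] = codes
    shaped = padded.reshape(nbytes, 4)
    return (
        shaped[:, 0] | (shaped[:, 1] << 2) | (shaped[:, 2] << 4) | (shaped[:, 3] << 6)
    ).astype(np.uint8)


def _unpack_bed(data: np.ndarray, n_samples: int, n_snps: int) -> np.ndarray:
    """Decode the SNP-major byte stream into an int8 dosage matrix."""
    nbytes = (n_samples + 3) // 4
    data = data.reshape(n_snps, nbytes)
    # expand each byte into its four 2-bit fields, sample order from the LSB
    codes = np.empty((n_snps, nbytes * 4), dtype=np.uint8)
    codes[:, 0::4] = data & 0b11
    codes[:, 1::4] = (data >> 2) & 0b11
    codes[:, 2::4] = (data >> 4) & 0b11
    codes[:, 3::4] = (data >> 6) & 0b11
    return _CODE_TO_DOSAGE[codes[:, :n_samples]].T


def write_plink(g: GenotypeMatrix, prefix: str | Path) -> None:
    """Write the bed/bim/fam triple for ``g`` (SNP-major, mode 0x01)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(bytes([_BED_SNP_MAJOR]))
        for j in range(g.n_snps):
            fh.write(_pack_snp(g.dosages[:, j]).tobytes())
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for s in g.snps:
            fh.write(
                f"{s.chromosome}\t{s.snp_id}\t0\t{s.position_bp}\t"
                f"{s.allele_minor}\t{s.allele_major}\n"
            )
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for s in g.samples:
            fh.write(
                f"{s.family_id}\t{s.sample_id}\t0\t0\t{_SEX_TO_FAM[s.sex]}\t-9\n"
            )


def read_plink(prefix: str | Path) -> GenotypeMatrix:
    """Read a bed/bim/fam triple; dosages oriented to the minor allele.

    The stored A1 allele of each SNP is treated as the counted allele; if its
    sample frequency exceeds 0.5 the orientation is flipped so that the
    returned matrix counts minor alleles.
    """
    prefix = Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": int, "snp_id": str, "pos": int, "a1": str, "a2": str},
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"],
        dtype=str,
    )
    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if raw.size < 3 or bytes(raw[:2]) != _BED_MAGIC:
        raise PlinkFormatError(f"{prefix}.bed: bad magic bytes")
    if raw[2] != _BED_SNP_MAJOR:
        raise PlinkFormatError(f"{prefix}.bed: not SNP-major (mode byte {raw[2]:#x})")
    n, m = len(fam), len(bim)
    expected = m * ((n + 3) // 4)
    if raw.size - 3 != expected:
        raise PlinkConsistencyError(
            f"{prefix}.bed payload is {raw.size - 3} bytes; "
            f"{expected} expected for {n} samples x {m} SNPs"
        )
    dosages = _unpack_bed(raw[3:], n, m) if m else np.zeros((n, 0), dtype=np.int8)

    snps = []
    for j, row in enumerate(bim.itertuples(index=False)):
        a1, a2 = row.a1, row.a2
        col = dosages[:, j]
        obs = col != MISSING
        if obs.any() and col[obs].sum() > obs.sum():  # freq of A1 > 0.5: flip
            dosages[obs, j] = 2 - col[obs]
            a1, a2 = a2, a1
        snps.append(SnpRecord(row.snp_id, int(row.chrom), int(row.pos), a1, a2))
    samples = [
        SampleRecord(row.iid, row.fid, _FAM_TO_SEX.get(row.sex, "unknown"))
        for row in fam.itertuples(index=False)
    ]
    return GenotypeMatrix(dosages, snps, samples)


def allele_frequencies(g: GenotypeMatrix) -> np.ndarray:
    """Per-SNP frequency of the counted (minor) allele.

    Missing calls are excluded from numerator and denominator.  SNPs with no
    non-missing calls get NaN (undefined), never a silent 0.
    """
    obs = g.dosages != MISSING
    n_obs = obs.sum(axis=0)
    total = np.where(obs, g.dosages, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_obs > 0, total / (2.0 * n_obs), np.nan)
    return freq


def hwe_exact_p(n_hom_minor: int, n_het: int, n_hom_major: int) -> float:
    """Two-sided exact Hardy-Weinberg test.

    Enumerates every heterozygote count compatible with the observed allele
    counts and sums the probabilities of configurations no more likely than
    the observed one (conditional exact test, no mid-p correction).
    Monomorphic SNPs return 1.
    """
    if min(n_hom_minor, n_het, n_hom_major) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_minor + n_het + n_hom_major
    if n < 1:
        raise ValueError("at least one genotype required")
    n_minor = 2 * n_hom_minor + n_het
    if n_minor == 0 or n_minor == 2 * n:
        return 1.0
    # heterozygote counts share the parity of the minor-allele count
    hets = np.arange(n_minor % 2, min(n_minor, 2 * n - n_minor) + 1, 2)
    hom_minor = (n_minor - hets) // 2
    hom_major = n - hom_minor - hets
    logp = (
        hets * np.log(2.0)
        - gammaln(hom_minor + 1)
        - gammaln(hets + 1)
        - gammaln(hom_major + 1)
    )
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    p_obs = prob[hets == n_het][0]
    return float(prob[prob <= p_obs * (1 + 1e-12)].sum())


def _snp_genotype_counts(col: np.ndarray) -> tuple[int, int, int]:
    return int((col == 2).sum()), int((col == 1).sum()), int((col == 0).sum())


def _orient_to_minor(g: GenotypeMatrix) -> GenotypeMatrix:
    """Flip any SNP whose counted-allele frequency exceeds 0.5."""
    freq = allele_frequencies(g)
    flip = freq > 0.5
    if not flip.any():
        return g
    dosages = g.dosages.copy()
    snps = list(g.snps)
    for j in np.flatnonzero(flip):
        obs = dosages[:, j] != MISSING
        dosages[obs, j] = 2 - dosages[obs, j]
        s = snps[j]
        snps[j] = SnpRecord(s.snp_id, s.chromosome, s.position_bp,
                            s.allele_major, s.allele_minor)
    return GenotypeMatrix(dosages, snps, g.samples)


def qc_filter(
    g: GenotypeMatrix,
    sample_call_min: float = 0.97,
    snp_call_min: float = 0.95,
    hwe_p_min: float = 1e-10,
    maf_min: float = 0.01,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Standard array QC: sample call rate first, then SNP filters.

    SNP statistics (call rate, HWE, MAF) are computed on the retained
    samples, and allele orientation is recomputed afterwards.  Returns the
    filtered matrix and an exclusion report (columns id, type, reason, value).
    """
    for t in (sample_call_min, snp_call_min, maf_min):
        if not 0 <= t <= 1:
            raise ValueError("call-rate/MAF thresholds must be in [0, 1]")
    rows = []
    obs = g.dosages != MISSING
    sample_cr = obs.mean(axis=1) if g.n_snps else np.ones(g.n_samples)
    keep_samples = sample_cr >= sample_call_min
    for i in np.flatnonzero(~keep_samples):
        rows.append((g.samples[i].sample_id, "sample", "sample_call_rate",
                     sample_cr[i]))
    if not keep_samples.any():
        raise ValueError("qc_filter excluded every sample")
    g2 = g.subset(sample_idx=np.flatnonzero(keep_samples))

    obs2 = g2.dosages != MISSING
    snp_cr = obs2.mean(axis=0)
    freq = allele_frequencies(g2)
    maf = np.minimum(freq, 1 - freq)
    keep_snps = np.ones(g2.n_snps, dtype=bool)
    for j in range(g2.n_snps):
        sid = g2.snps[j].snp_id
        if snp_cr[j] < snp_call_min:
            rows.append((sid, "snp", "snp_call_rate", snp_cr[j]))
            keep_snps[j] = False
            continue
        hom_min, het, hom_maj = _snp_genotype_counts(g2.dosages[:, j])
        if hom_min + het + hom_maj > 0:
            p_hwe = hwe_exact_p(hom_min, het, hom_maj)
            if p_hwe < hwe_p_min:
                rows.append((sid, "snp", "hwe", p_hwe))
                keep_snps[j] = False
                continue
        if np.isnan(maf[j]) or maf[j] < maf_min:
            rows.append((sid, "snp", "maf", maf[j]))
            keep_snps[j] = False
    g3 = _orient_to_minor(g2.subset(snp_idx=np.flatnonzero(keep_snps)))
    report = pd.DataFrame(rows, columns=["id", "type", "reason", "value"])
    return g3, report


def write_exclusion_report(report: pd.DataFrame, path: str | Path) -> None:
    report.to_csv(path, sep="\t", index=False)
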