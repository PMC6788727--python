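"""Additive genotype matrix with marker/subject quality control.

QC rules follow standard GWAS practice on this chip-genotyped design:
subjects below a 97% call rate are dropped, and markers are dropped for >5%
missingness, minor-allele frequency <= 0.05 (computed over all retained
subjects, cases and controls pooled), or Hardy-Weinberg exact-test
P <= 1e-6.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

MISSING = -1  # sentinel in int8 call matrices


@dataclass
class GenotypeMatrix:
    """Subjects x SNPs minor-allele counts in {0,1,2}, -1 for missing.

    ``snp_meta`` is indexed by SNP id with columns gene, chrom, pos; every
    SNP maps to exactly one gene symbol.
    """

    calls: np.ndarray
    snp_meta: pd.DataFrame
    subject_ids: list[str]

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValueError("calls must be a 2-D subjects x SNPs array")
        if self.calls.shape != (len(self.subject_ids), len(self.snp_meta)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.subject_ids)} subjects x {len(self.snp_meta)} SNPs"
            )
        valid = np.isin(self.calls, (MISSING, 0, 1, 2))
        if not valid.all():
            raise ValueError("genotype calls must be in {0,1,2} or -1 (missing)")
        for col in ("gene", "chrom", "pos"):
            if col not in self.snp_meta.columns:
                raise ValueError(f"snp_meta missing required column {col!r}")

    @property
    def n_subjects(self) -> int:
        return self.calls.shape[0]

    @property
    def n_snps(self) -> int:
        return self.calls.shape[1]

    @property
    def snp_ids(self) -> pd.Index:
        return self.snp_meta.index

    def subject_call_rate(self) -> np.ndarray:
        return (self.calls != MISSING).mean(axis=1)

    def marker_missing_rate(self) -> np.ndarray:
        return (self.calls == MISSING).mean(axis=0)

    def maf(self) -> np.ndarray:
        """Minor-allele frequency per marker over non-missing calls, folded to <= 0.5."""
        obs = self.calls != MISSING
        counts = np.where(obs, self.calls, 0).sum(axis=0).astype(float)
        denom = 2.0 * obs.sum(axis=0)
        with np.errstate(invalid="ignore"):
            freq = counts / denom
        freq = np.where(np.isnan(freq), 0.0, freq)
        return np.minimum(freq, 1.0 - freq)

    def genotype_counts(self) -> np.ndarray:
        """Per-marker (n0, n1, n2) genotype counts over non-missing calls."""
        out = np.empty((self.n_snps, 3), dtype=int)
        for g in (0, 1, 2):
            out[:, g] = (self.calls == g).sum(axis=0)
        return out

    def take_subjects(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        return replace(
            self,
            calls=self.calls[keep],
            subject_ids=[self.subject_ids[i] for i in keep],
            snp_meta=self.snp_meta,
        )

    def take_markers(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        return replace(
            self,
            calls=self.calls[:, keep],
            snp_meta=self.snp_meta.iloc[keep],
            subject_ids=list(self.subject_ids),
        )


def hwe_exact_p(n_het: int, n_hom_minor: int, n_hom_major: int) -> float:
    """Exact Hardy-Weinberg test P-value on genotype counts.

    Sums, over all heterozygote counts consistent with the observed allele
    counts, the conditional probabilities no larger than that of the observed
    configuration (Wigginton-style enumeration, stable in log space).
    """
    for v in (n_het, n_hom_minor, n_hom_major):
        if v < 0:
            raise ValueError("genotype counts must be non-negative")
    n = n_het + n_hom_minor + n_hom_major
    if n == 0:
        return 1.0
    n_minor = 2 * n_hom_minor + n_het
    n_major = 2 * n_hom_major + n_het
    if n_minor > n_major:
        n_minor, n_major = n_major, n_minor
    # log P(het = h | allele counts) up to a shared constant
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    lg = math.lgamma
    logp = np.array(
        [
            lg(n + 1)
            - lg(h + 1)
            - lg((n_minor - h) // 2 + 1)
            - lg((n_major - h) // 2 + 1)
            + h * math.log(2.0)
            for h in hets
        ]
    )
    p = np.exp(logp - logp.max())
    p /= p.sum()
    obs = p[np.searchsorted(hets, n_het)]
    return float(min(1.0, p[p <= obs * (1 + 1e-12)].sum()))


def hwe_chi2_p(n_het: int, n_hom_minor: int, n_hom_major: int) -> float:
    """Chi-squared (1 df) Hardy-Weinberg test; offered as a faster alternative."""
    from scipy import stats

    n = n_het + n_hom_minor + n_hom_major
    if n == 0:
        return 1.0
    q = (2 * n_hom_minor + n_het) / (2 * n)
    exp = np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2]) * n
    obs = np.array([n_hom_major, n_het, n_hom_minor], dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.nansum(np.where(exp > 0, (obs - exp) ** 2 / exp, 0.0))
    return float(stats.chi2.sf(chi2, df=1))


def qc_subjects(g: GenotypeMatrix, min_call_rate: float = 0.97) -> GenotypeMatrix:
    """Drop subjects whose genotyping rate is strictly below ``min_call_rate``."""
    rates = g.subject_call_rate()
    keep = np.flatnonzero(rates >= min_call_rate)
    if keep.size == 0:
        raise ValueError("subject QC removed every subject")
    return g.take_subjects(keep)


def qc_markers(
    g: GenotypeMatrix,
    max_missing: float = 0.05,
    min_maf: float = 0.05,
    hwe_alpha: float = 1e-6,
    hwe_method: str = "exact",
) -> GenotypeMatrix:
    """Drop markers with >max_missing missingness, MAF <= min_maf, or HWE P <= hwe_alpha.

    MAF is computed over all retained subjects (cases and controls pooled).
    The boundary conventions are deliberate: missingness strictly greater
    than the cap, MAF less than *or equal to* the cap, HWE P less than or
    equal to alpha all remove the marker.
    """
    if g.n_subjects < 1:
        raise ValueError("marker QC requires at least one subject")
    hwe = hwe_exact_p if hwe_method == "exact" else hwe_chi2_p
    missing = g.marker_missing_rate()
    maf = g.maf()
    counts = g.genotype_counts()
    # fold so the minor allele is the one counted by '2'
    hwe_p = np.empty(g.n_snps)
    for i, (n0, n1, n2) in enumerate(counts):
        hom_minor, hom_major = (n2, n0) if n2 <= n0 else (n0, n2)
        hwe_p[i] = hwe(n1, hom_minor, hom_major)
    keep = (missing <= max_missing) & (maf > min_maf) & (hwe_p > hwe_alpha)
    if not keep.any():
        raise ValueError("marker QC removed every marker")
    return g.take_markers(np.flatnonzero(keep))


def warn_monomorphic(g: GenotypeMatrix) -> None:
    mono = g.maf() == 0
    if mono.any():
        warnings.warn(f"{int(mono.sum())} monomorphic markers present", stacklevel=2)
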