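"""Variant- and sample-level quality control and the MHC region selector.

Default thresholds follow the usual GWAS practice for hard-called arrays:
remove SNPs with minor-allele frequency < 1%, per-SNP missingness > 1%, or
Hardy-Weinberg exact-test P < 5e-6 in controls, and samples with
missingness > 1%. All comparisons are strict, so a SNP at MAF exactly 0.01
survives. Samples are filtered first so that per-SNP statistics reflect the
retained samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .data import MISSING, GenotypeData

MHC_CHROM = "6"
MHC_START_BP = 29_700_000
MHC_END_BP = 33_300_000


@dataclass(frozen=True)
class QCThresholds:
    maf_min: float = 0.01
    snp_missing_max: float = 0.01
    hwe_p_min: float = 5e-6
    sample_missing_max: float = 0.01

    def __post_init__(self) -> None:
        for name in ("maf_min", "snp_missing_max", "hwe_p_min", "sample_missing_max"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class QCReport:
    thresholds: QCThresholds
    n_samples_in: int = 0
    n_snps_in: int = 0
    samples_removed_missingness: int = 0
    snps_removed_missingness: int = 0
    snps_removed_maf: int = 0
    snps_removed_hwe: int = 0
    n_samples_out: int = 0
    n_snps_out: int = 0
    hwe_test: str = "exact two-sided (not mid-p)"
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["thresholds"] = dict(self.thresholds.__dict__)
        return d


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact Hardy-Weinberg test p-value.

    Conditional on the observed allele counts, sums the probabilities of all
    heterozygote counts that are no more probable than the observed one.
    Monomorphic sites have a single possible outcome and return p = 1.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("total genotype count is zero")
    n_A = 2 * n_AA + n_Aa
    n_a = 2 * n_aa + n_Aa
    rare = min(n_A, n_a)
    if rare == 0:
        return 1.0

    # heterozygote counts share the parity of the rare-allele count
    hets = np.arange(rare % 2, rare + 1, 2)
    homr = (rare - hets) // 2
    homc = n - hets - homr
    # log P(het = h | n, n_A) = log n! - log homr! - log h! - log homc!
    #                           + h log 2 + log n_A! + log n_a! - log (2n)!
    logp = (
        gammaln(n + 1)
        - gammaln(homr + 1)
        - gammaln(hets + 1)
        - gammaln(homc + 1)
        + hets * np.log(2.0)
        + gammaln(n_A + 1)
        + gammaln(n_a + 1)
        - gammaln(2 * n + 1)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    obs = np.searchsorted(hets, n_Aa)
    if obs >= len(hets) or hets[obs] != n_Aa:
        raise ValueError(
            f"heterozygote count {n_Aa} inconsistent with allele counts"
        )
    p = probs[probs <= probs[obs] * (1.0 + 1e-12)].sum()
    return float(min(p, 1.0))


def _snp_genotype_counts(dosages: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    return (
        (dosages == 2).sum(axis=0),
        (dosages == 1).sum(axis=0),
        (dosages == 0).sum(axis=0),
    )


def apply_qc(
    data: GenotypeData, thresholds: QCThresholds | None = None
) -> tuple[GenotypeData, QCReport]:
    """Apply sample-missingness, SNP-missingness, MAF and HWE-in-controls filters.

    Filter order: samples first, then SNPs by missingness, MAF and HWE. All
    thresholds are strict (removed only when strictly beyond the limit). If
    no controls are present the HWE filter is skipped with a warning.

    Removing SNPs changes per-sample missingness denominators (and vice
    versa), so the filter sequence is iterated to a fixed point; the filtered
    output therefore passes QC unchanged (idempotence). The report
    accumulates removal counts over all passes.
    """
    thr = thresholds or QCThresholds()
    report = QCReport(
        thresholds=thr, n_samples_in=data.n_samples, n_snps_in=data.n_snps
    )
    while True:
        data, changed = _qc_pass(data, thr, report)
        if not changed:
            break
    report.n_samples_out = data.n_samples
    report.n_snps_out = data.n_snps
    return data, report


def _qc_pass(
    data: GenotypeData, thr: QCThresholds, report: QCReport
) -> tuple[GenotypeData, bool]:
    n0, p0 = data.n_samples, data.n_snps

    miss = data.missing_mask()
    sample_missing = miss.mean(axis=1) if data.n_snps else np.zeros(data.n_samples)
    keep_samples = sample_missing <= thr.sample_missing_max
    report.samples_removed_missingness += int((~keep_samples).sum())
    data = data.subset(sample_idx=np.flatnonzero(keep_samples))

    miss = data.missing_mask()
    snp_missing = miss.mean(axis=0) if data.n_samples else np.zeros(data.n_snps)
    keep = snp_missing <= thr.snp_missing_max
    report.snps_removed_missingness += int((~keep).sum())
    data = data.subset(snp_idx=np.flatnonzero(keep))

    valid = data.dosages != MISSING
    with np.errstate(invalid="ignore"):
        freq = np.where(
            valid.sum(axis=0) > 0,
            np.where(data.dosages == MISSING, 0, data.dosages).sum(axis=0)
            / np.maximum(2 * valid.sum(axis=0), 1),
            0.0,
        )
    maf = np.minimum(freq, 1.0 - freq)
    keep = maf >= thr.maf_min
    report.snps_removed_maf += int((~keep).sum())
    data = data.subset(snp_idx=np.flatnonzero(keep))

    controls = np.flatnonzero(data.phenotype == -1)
    if controls.size == 0:
        if "no controls present; HWE filter skipped" not in report.warnings:
            report.warnings.append("no controls present; HWE filter skipped")
    elif data.n_snps:
        ctrl = data.dosages[controls]
        ctrl = np.where(ctrl == MISSING, MISSING, ctrl)
        nAA, nAa, naa = _snp_genotype_counts(ctrl)
        pvals = np.array(
            [
                hwe_exact_test(int(a), int(b), int(c)) if a + b + c > 0 else 1.0
                for a, b, c in zip(nAA, nAa, naa)
            ]
        )
        keep = pvals >= thr.hwe_p_min
        report.snps_removed_hwe += int((~keep).sum())
        data = data.subset(snp_idx=np.flatnonzero(keep))

    return data, (data.n_samples, data.n_snps) != (n0, p0)


def mhc_filter(data: GenotypeData, mode: str = "all") -> GenotypeData:
    """Select SNPs by MHC membership (chr6, 29.7-33.3 Mb, bounds inclusive).

    ``mode`` is one of ``all`` (identity), ``mhc_only`` or ``non_mhc``.
    """
    if mode == "all":
        return data
    chrom = data.variants["chrom"].astype(str).str.removeprefix("chr")
    pos = data.variants["pos"].astype(np.int64)
    in_mhc = (chrom == MHC_CHROM) & (pos >= MHC_START_BP) & (pos <= MHC_END_BP)
    if mode == "mhc_only":
        return data.subset(snp_idx=np.flatnonzero(in_mhc.to_numpy()))
    if mode == "non_mhc":
        return data.subset(snp_idx=np.flatnonzero(~in_mhc.to_numpy()))
    raise ValueError(f"unknown mhc_filter mode {mode!r}")
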