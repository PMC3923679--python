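"""In-memory containers for case/control SNP genotype data.

Dosages are stored as ``int8`` counts of the A1 allele in {0, 1, 2}, with
``-1`` marking a missing call. Phenotypes are coded {-1, +1} (control/case),
with 0 meaning unknown.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MISSING: int = -1

VARIANT_COLUMNS = ["chrom", "id", "cm", "pos", "a1", "a2"]
SAMPLE_COLUMNS = ["fid", "iid", "phenotype"]


@dataclass
class GenotypeData:
    """A samples x SNPs dosage matrix plus variant and sample metadata.

    Attributes
    ----------
    dosages
        ``(n_samples, n_snps)`` int8 array; entries in {0, 1, 2} count copies
        of the A1 allele, ``-1`` is missing.
    variants
        DataFrame with columns ``chrom, id, cm, pos, a1, a2`` (bim order);
        ``pos`` is the 1-based basepair position.
    samples
        DataFrame with columns ``fid, iid, phenotype``; phenotype is
        -1 (control), +1 (case) or 0 (unknown).
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D samples x SNPs array")
        n, p = self.dosages.shape
        if len(self.samples) != n:
            raise ValueError(
                f"sample metadata rows ({len(self.samples)}) != matrix rows ({n})"
            )
        if len(self.variants) != p:
            raise ValueError(
                f"variant metadata rows ({len(self.variants)}) != matrix columns ({p})"
            )
        ids = self.variants["id"]
        if ids.duplicated().any():
            dups = ids[ids.duplicated()].tolist()[:5]
            raise ValueError(f"duplicate variant ids: {dups}")
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosages must be in {0, 1, 2} or -1 (missing)")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def phenotype(self) -> np.ndarray:
        return self.samples["phenotype"].to_numpy(dtype=np.int8)

    def missing_mask(self) -> np.ndarray:
        return self.dosages == MISSING

    def dosage_matrix(self, impute_means: np.ndarray | None = None) -> np.ndarray:
        """Dosages as float64, optionally mean-imputing missing entries.

        ``impute_means`` is a per-SNP vector (e.g. training-fold means); when
        omitted, missing entries are left as NaN.
        """
        X = self.dosages.astype(np.float64)
        miss = self.dosages == MISSING
        if impute_means is None:
            X[miss] = np.nan
        else:
            means = np.asarray(impute_means, dtype=np.float64)
            if means.shape != (self.n_snps,):
                raise ValueError("impute_means length must equal n_snps")
            X[miss] = np.broadcast_to(means, X.shape)[miss]
        return X

    def snp_means(self) -> np.ndarray:
        """Per-SNP mean dosage over non-missing calls (NaN if all missing)."""
        X = self.dosages.astype(np.float64)
        X[self.dosages == MISSING] = np.nan
        with np.errstate(invalid="ignore"):
            return np.nanmean(X, axis=0)

    def subset(
        self,
        sample_idx: np.ndarray | slice | None = None,
        snp_idx: np.ndarray | slice | None = None,
    ) -> "GenotypeData":
        if sample_idx is None:
            sample_idx = slice(None)
        if snp_idx is None:
            snp_idx = slice(None)
        return GenotypeData(
            dosages=self.dosages[sample_idx][:, snp_idx],
            variants=self.variants.iloc[snp_idx].reset_index(drop=True),
            samples=self.samples.iloc[sample_idx].reset_index(drop=True),
        )
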