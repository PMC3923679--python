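"""Model containers shared between the solver, CV machinery and file I/O."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class SparseModel:
    """An L1-penalized squared-hinge SVM solution.

    ``beta`` is the per-SNP weight vector (mostly zero), ``beta0`` the
    unpenalized intercept, ``lam`` the L1 penalty at which it was fitted.
    """

    beta: np.ndarray
    beta0: float
    lam: float
    objective: float = np.nan
    converged: bool = True
    n_iters: int = 0
    objective_path: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.beta))


@dataclass
class ConsensusModel:
    """Cross-validation consensus risk-score model.

    Weights are arithmetic means over all fold-models (zeros included);
    ``stability`` is the percentage of fold-models in which each SNP had a
    non-zero weight. ``mean_dosage`` stores the training mean dosage per SNP
    so that missing genotypes can be scored deterministically.
    """

    snp_id: np.ndarray
    effect_allele: np.ndarray
    weights: np.ndarray
    stability: np.ndarray
    intercept: float
    mean_dosage: np.ndarray | None = None
    other_allele: np.ndarray | None = None
    target_size: int | None = None

    def __post_init__(self) -> None:
        self.snp_id = np.asarray(self.snp_id, dtype=object)
        self.effect_allele = np.asarray(self.effect_allele, dtype=object)
        self.weights = np.asarray(self.weights, dtype=np.float64)
        self.stability = np.asarray(self.stability, dtype=np.float64)
        if self.other_allele is not None:
            self.other_allele = np.asarray(self.other_allele, dtype=object)
        if self.mean_dosage is not None:
            self.mean_dosage = np.asarray(self.mean_dosage, dtype=np.float64)
        n = len(self.snp_id)
        for name in ("effect_allele", "weights", "stability"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length != number of model SNPs")
        if len(np.unique(self.snp_id.astype(str))) != n:
            raise ValueError("duplicate SNP ids in model")
        if np.any(self.stability < 0) or np.any(self.stability > 100):
            raise ValueError("stability must lie in [0, 100]")

    @property
    def n_snps(self) -> int:
        return len(self.snp_id)
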