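"""Repeated stratified cross-validation, model-size selection and the
consensus model.

The penalized SVM is evaluated over a decreasing penalty grid in k-fold
cross-validation repeated ``replicates`` times (10x10 by default). Folds
are stratified by case/control status; all per-fold statistics (mean-dosage
imputation) are computed on the training portion only, and the held-out AUC
is recorded per penalty. The model size with the highest mean AUC across all
fold x replicate models determines the target size; the consensus model
averages the weights of every fold-model at the selected penalty (zeros
included) and reports, per SNP, the percentage of fold-models that gave it a
non-zero weight (the selection stability).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from statsmodels.nonparametric.smoothers_lowess import lowess

from . import svm
from .data import GenotypeData
from .models import ConsensusModel

CV_SOLVER_TOL = 1e-4
CV_SOLVER_MAX_ITERS = 2000


@dataclass
class FoldModel:
    """Sparse fold-model storage: support indices + weights per penalty."""

    replicate: int
    fold: int
    nz_idx: list[np.ndarray]
    nz_val: list[np.ndarray]
    beta0: np.ndarray


@dataclass
class CVResult:
    lambdas: np.ndarray
    auc: np.ndarray  # (replicates, k, n_lambda)
    n_nonzero: np.ndarray  # (replicates, k, n_lambda)
    fold_models: list[FoldModel]
    test_indices: list[np.ndarray]  # parallel to fold_models
    n_snps: int
    seed: int
    k: int
    replicates: int

    @property
    def n_models(self) -> int:
        return len(self.fold_models)

    def mean_auc(self) -> np.ndarray:
        return self.auc.mean(axis=(0, 1))

    def mean_size(self) -> np.ndarray:
        return self.n_nonzero.mean(axis=(0, 1))


def run_cv(
    data: GenotypeData,
    k: int = 10,
    replicates: int = 10,
    grid: np.ndarray | None = None,
    grid_size: int = 25,
    min_ratio: float = 0.01,
    seed: int = 0,
    tol: float = CV_SOLVER_TOL,
    max_iters: int = CV_SOLVER_MAX_ITERS,
) -> CVResult:
    """Repeated stratified k-fold CV of the penalty path.

    Missing dosages are imputed to training-fold SNP means; the held-out fold
    is imputed with the same training means (no leakage). The penalty grid is
    computed once on the full data so AUC curves are comparable across folds.
    """
    y = data.phenotype.astype(np.float64)
    if np.any(y == 0):
        raise ValueError("all samples must have known phenotype for CV")
    n_cases = int((y == 1).sum())
    n_controls = int((y == -1).sum())
    if n_cases < k or n_controls < k:
        raise ValueError(
            f"need at least k={k} cases and controls; have {n_cases}/{n_controls}"
        )

    full_means = data.snp_means()
    X_full = data.dosage_matrix(impute_means=np.nan_to_num(full_means))
    if grid is None:
        grid = svm.lambda_grid(X_full, y, grid_size=grid_size, min_ratio=min_ratio)
    grid = np.asarray(grid, dtype=np.float64)
    nl = grid.size

    auc = np.empty((replicates, k, nl))
    nnz = np.empty((replicates, k, nl), dtype=np.int64)
    fold_models: list[FoldModel] = []
    test_indices: list[np.ndarray] = []

    rng = np.random.default_rng(seed)
    for rep in range(replicates):
        skf = StratifiedKFold(
            n_splits=k, shuffle=True, random_state=int(rng.integers(2**31 - 1))
        )
        for fold, (tr, te) in enumerate(skf.split(np.zeros(len(y)), y)):
            sub_tr = data.subset(sample_idx=tr)
            means = np.nan_to_num(sub_tr.snp_means())
            Xtr = sub_tr.dosage_matrix(impute_means=means)
            Xte = data.subset(sample_idx=te).dosage_matrix(impute_means=means)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # non-convergence at loose CV tol
                path = svm.fit_path(
                    Xtr, y[tr], grid, tol=tol, max_iters=max_iters
                )
            fm = FoldModel(
                replicate=rep,
                fold=fold,
                nz_idx=[np.flatnonzero(m.beta) for m in path],
                nz_val=[m.beta[np.flatnonzero(m.beta)] for m in path],
                beta0=np.array([m.beta0 for m in path]),
            )
            fold_models.append(fm)
            test_indices.append(te)
            for li, m in enumerate(path):
                scores = Xte @ m.beta + m.beta0
                nnz[rep, fold, li] = m.n_nonzero
                if np.unique(scores).size == 1:
                    auc[rep, fold, li] = 0.5
                else:
                    auc[rep, fold, li] = roc_auc_score((y[te] == 1).astype(int), scores)
    return CVResult(
        lambdas=grid,
        auc=auc,
        n_nonzero=nnz,
        fold_models=fold_models,
        test_indices=test_indices,
        n_snps=data.n_snps,
        seed=seed,
        k=k,
        replicates=replicates,
    )


@dataclass
class ModelSizeSelection:
    target_size: int
    lambda_index: int
    lambda_value: float
    curve: pd.DataFrame  # per-lambda mean size, mean AUC, smoothed AUC


def select_model_size(cv: CVResult, span: float = 0.75) -> ModelSizeSelection:
    """Pick the model size whose penalty maximizes the mean held-out AUC.

    Ties are broken toward the smaller model (parsimony). The returned curve
    carries a local-regression smooth of AUC against mean model size, for
    diagnostics/plotting.
    """
    mean_auc = cv.mean_auc()
    mean_size = cv.mean_size()
    best_auc = mean_auc.max()
    candidates = np.flatnonzero(mean_auc >= best_auc - 1e-12)
    lambda_index = int(candidates[np.argmin(mean_size[candidates])])

    order = np.argsort(mean_size)
    if np.unique(mean_size).size >= 4:
        sm = lowess(
            mean_auc[order], mean_size[order], frac=span, return_sorted=False
        )
        smoothed = np.empty_like(mean_auc)
        smoothed[order] = sm
    else:
        smoothed = mean_auc.copy()
    curve = pd.DataFrame(
        {
            "lambda": cv.lambdas,
            "mean_size": mean_size,
            "mean_auc": mean_auc,
            "sd_auc": cv.auc.std(axis=(0, 1)),
            "smoothed_auc": smoothed,
        }
    )
    target = int(round(mean_size[lambda_index]))
    return ModelSizeSelection(
        target_size=max(target, 1) if mean_size[lambda_index] > 0 else 0,
        lambda_index=lambda_index,
        lambda_value=float(cv.lambdas[lambda_index]),
        curve=curve,
    )


def build_consensus(
    cv: CVResult,
    data: GenotypeData,
    lambda_index: int,
    target_size: int | None = None,
) -> ConsensusModel:
    """Average the fold-models at one penalty into a consensus model.

    Weights are the arithmetic mean over all fold-models with zeros counted;
    stability is the percentage of fold-models in which the SNP was selected.
    The SNP set is truncated to the ``target_size`` SNPs with largest
    absolute mean weight (``None`` keeps every ever-selected SNP).
    """
    p = cv.n_snps
    if p != data.n_snps:
        raise ValueError("data does not match the CV result (different SNP count)")
    n_models = cv.n_models
    mean_w = np.zeros(p)
    sel_count = np.zeros(p)
    intercepts = np.empty(n_models)
    for mi, fm in enumerate(cv.fold_models):
        idx = fm.nz_idx[lambda_index]
        mean_w[idx] += fm.nz_val[lambda_index]
        sel_count[idx] += 1
        intercepts[mi] = fm.beta0[lambda_index]
    mean_w /= n_models
    stability = 100.0 * sel_count / n_models

    ever = np.flatnonzero(sel_count > 0)
    if target_size is None or target_size >= ever.size:
        if target_size is not None and target_size > ever.size:
            warnings.warn(
                f"target_size {target_size} exceeds the {ever.size} SNPs ever "
                "selected; keeping all of them",
                stacklevel=2,
            )
        selected = ever
    else:
        rank = np.argsort(-np.abs(mean_w[ever]), kind="stable")
        selected = np.sort(ever[rank[:target_size]])

    means = np.nan_to_num(data.snp_means())
    return ConsensusModel(
        snp_id=data.variants["id"].to_numpy()[selected],
        effect_allele=data.variants["a1"].to_numpy()[selected],
        other_allele=data.variants["a2"].to_numpy()[selected],
        weights=mean_w[selected],
        stability=stability[selected],
        intercept=float(intercepts.mean()),
        mean_dosage=means[selected],
        target_size=target_size,
    )


def stability_table(cv: CVResult, data: GenotypeData, lambda_index: int) -> pd.DataFrame:
    """Per-SNP mean weight and stability at one penalty, sorted by |weight|."""
    model = build_consensus(cv, data, lambda_index, target_size=None)
    df = pd.DataFrame(
        {
            "snp_id": model.snp_id,
            "weight": model.weights,
            "stability": model.stability,
        }
    )
    return df.reindex(df["weight"].abs().sort_values(ascending=False).index).reset_index(
        drop=True
    )
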