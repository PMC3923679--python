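"""Diagnostic performance: ROC/AUC, prevalence re-sampling, PPV/NPV,
misdiagnosis odds, screening tables and a coarse stratum-risk baseline.

Case/control panels over-represent cases, so raw precision is meaningless
for a target population. Performance at a population prevalence K is
estimated by down-sampling cases (keeping every control) until the case
fraction equals K, repeating the subsampling and averaging the
sensitivity/precision/NPV curves across replicates at a fixed common grid
of score cutoffs (threshold averaging). Precision measured in data whose
case fraction equals K is the PPV at prevalence K; sensitivity and
specificity are prevalence-invariant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

DEFAULT_PREVALENCES = (0.01, 0.03, 0.10, 0.20)
DEFAULT_REPLICATES = 50
DEFAULT_THRESHOLD_GRID = 101


@dataclass
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def sensitivity(self) -> float:
        d = self.TP + self.FN
        return self.TP / d if d else np.nan

    @property
    def specificity(self) -> float:
        d = self.TN + self.FP
        return self.TN / d if d else np.nan

    @property
    def precision(self) -> float:
        d = self.TP + self.FP
        return self.TP / d if d else np.nan

    @property
    def npv(self) -> float:
        d = self.TN + self.FN
        return self.TN / d if d else np.nan


def confusion_at(scores: np.ndarray, labels: np.ndarray, cutoff: float) -> ConfusionCounts:
    """Counts for the rule 'positive iff score >= cutoff'."""
    scores = np.asarray(scores, dtype=float)
    pos = labels == 1
    called = scores >= cutoff
    return ConfusionCounts(
        TP=int((called & pos).sum()),
        FP=int((called & ~pos).sum()),
        TN=int((~called & ~pos).sum()),
        FN=int((~called & pos).sum()),
    )


def _check_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    if not np.all(np.isin(labels, (-1, 1))):
        raise ValueError("labels must be coded {-1, +1}")
    if np.all(labels == labels[0]):
        raise ValueError("both classes must be present")
    return labels


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> tuple[pd.DataFrame, float]:
    """Full ROC step curve and AUC (Mann-Whitney; ties count one half)."""
    labels = _check_labels(labels)
    scores = np.asarray(scores, dtype=float)
    fpr, tpr, thr = roc_curve((labels == 1).astype(int), scores)
    auc = float(roc_auc_score((labels == 1).astype(int), scores))
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr}), auc


def ppv_npv(sens: float, spec: float, prev: float) -> tuple[float, float]:
    """Closed-form predictive values at a target prevalence.

    PPV = sens*prev / (sens*prev + (1-spec)(1-prev));
    NPV = spec(1-prev) / (spec(1-prev) + (1-sens)prev).
    Undefined ratios (zero denominators) come back as NaN rather than
    raising, so curves can carry them through.
    """
    for name, v in (("sens", sens), ("spec", spec), ("prev", prev)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    ppv_den = sens * prev + (1.0 - spec) * (1.0 - prev)
    npv_den = spec * (1.0 - prev) + (1.0 - sens) * prev
    ppv = sens * prev / ppv_den if ppv_den > 0 else np.nan
    npv = spec * (1.0 - prev) / npv_den if npv_den > 0 else np.nan
    return ppv, npv


def misdiagnosis_odds(ppv: float) -> float:
    """Non-cases wrongly implicated per true case: (1 - PPV)/PPV."""
    if not 0.0 <= ppv <= 1.0:
        raise ValueError(f"PPV must be in [0, 1], got {ppv}")
    if ppv == 0.0:
        return np.inf
    return (1.0 - ppv) / ppv


def downsample_prevalence(
    labels: np.ndarray, K: float, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Indices of a subsample whose case fraction equals K.

    All controls are kept; cases are drawn without replacement so that
    n_cases = floor(n_controls * K / (1 - K)).
    """
    labels = _check_labels(labels)
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    cases = np.flatnonzero(labels == 1)
    controls = np.flatnonzero(labels == -1)
    observed = cases.size / labels.size
    if K > observed:
        raise ValueError(
            f"target prevalence {K} exceeds the observed case fraction {observed:.4f}"
        )
    n_keep = int(np.floor(controls.size * K / (1.0 - K)))
    keep_cases = rng.choice(cases, size=n_keep, replace=False)
    return np.sort(np.concatenate([keep_cases, controls]))


@dataclass
class PrevalenceEvaluation:
    prevalence: float
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    ppv: np.ndarray  # replicate-averaged empirical precision
    npv: np.ndarray
    misdiagnosis: np.ndarray
    auc_mean: float
    replicates: int
    averaging: str = "threshold"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "prevalence": self.prevalence,
                "threshold": self.thresholds,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
                "ppv": self.ppv,
                "npv": self.npv,
                "misdiagnosis_odds": self.misdiagnosis,
            }
        )


def threshold_grid(scores: np.ndarray, n: int = DEFAULT_THRESHOLD_GRID) -> np.ndarray:
    """Common cutoff grid: evenly spaced quantiles of the full score cohort."""
    return np.quantile(np.asarray(scores, dtype=float), np.linspace(0.0, 1.0, n))


def prevalence_evaluation(
    scores: np.ndarray,
    labels: np.ndarray,
    prevalences=DEFAULT_PREVALENCES,
    replicates: int = DEFAULT_REPLICATES,
    seed: int = 0,
    grid: np.ndarray | None = None,
) -> dict[float, PrevalenceEvaluation]:
    """Threshold-averaged performance curves at each target prevalence.

    For every prevalence K the cases are down-sampled ``replicates`` times;
    sensitivity, specificity, empirical precision (= PPV at that prevalence)
    and NPV are computed on a common cutoff grid and averaged across
    replicates at fixed cutoffs.
    """
    labels = _check_labels(labels)
    scores = np.asarray(scores, dtype=float)
    if grid is None:
        grid = threshold_grid(scores)
    rng = np.random.default_rng(seed)
    out: dict[float, PrevalenceEvaluation] = {}
    for K in prevalences:
        sens = np.zeros((replicates, grid.size))
        spec = np.zeros((replicates, grid.size))
        prec = np.full((replicates, grid.size), np.nan)
        npv = np.full((replicates, grid.size), np.nan)
        aucs = np.empty(replicates)
        few_cases_warned = False
        for r in range(replicates):
            idx = downsample_prevalence(labels, K, rng)
            s, l = scores[idx], labels[idx]
            n_cases = int((l == 1).sum())
            if n_cases < 10 and not few_cases_warned:
                warnings.warn(
                    f"only {n_cases} cases at prevalence {K}; "
                    "replicate curves will be noisy",
                    stacklevel=2,
                )
                few_cases_warned = True
            pos = l == 1
            # vectorized confusion counts over the cutoff grid
            called = s[None, :] >= grid[:, None]  # (grid, n)
            tp = (called & pos).sum(axis=1)
            fp = (called & ~pos).sum(axis=1)
            fn = (~called & pos).sum(axis=1)
            tn = (~called & ~pos).sum(axis=1)
            sens[r] = tp / np.maximum(tp + fn, 1)
            spec[r] = tn / np.maximum(tn + fp, 1)
            with np.errstate(invalid="ignore", divide="ignore"):
                prec[r] = np.where(tp + fp > 0, tp / np.maximum(tp + fp, 1), np.nan)
                npv[r] = np.where(tn + fn > 0, tn / np.maximum(tn + fn, 1), np.nan)
            aucs[r] = roc_auc_score(pos.astype(int), s) if n_cases else np.nan
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean_prec = np.nanmean(prec, axis=0)
            out[K] = PrevalenceEvaluation(
                prevalence=K,
                thresholds=grid,
                sensitivity=sens.mean(axis=0),
                specificity=spec.mean(axis=0),
                ppv=mean_prec,
                npv=np.nanmean(npv, axis=0),
                misdiagnosis=np.where(
                    mean_prec > 0, (1.0 - mean_prec) / np.maximum(mean_prec, 1e-300), np.inf
                ),
                auc_mean=float(np.nanmean(aucs)),
                replicates=replicates,
            )
    return out


def screening_table(
    scores: np.ndarray,
    labels: np.ndarray,
    prevalences=DEFAULT_PREVALENCES,
    cutoffs=(0.05, 0.10, 0.15, 0.20, 0.30, 0.40),
    replicates: int = DEFAULT_REPLICATES,
    seed: int = 0,
) -> pd.DataFrame:
    """Screening summary: rows are (prevalence, population-percent cutoff).

    Cutoffs are population fractions flagged positive; the decision boundary
    is the (1 - cutoff) score quantile of the down-sampled population. Each
    cell averages over the down-sampling replicates.
    """
    labels = _check_labels(labels)
    scores = np.asarray(scores, dtype=float)
    rng = np.random.default_rng(seed)
    rows = []
    for K in prevalences:
        acc = {c: [] for c in cutoffs}
        for _ in range(replicates):
            idx = downsample_prevalence(labels, K, rng)
            s, l = scores[idx], labels[idx]
            pos = l == 1
            order = np.sort(s)[::-1]
            for c in cutoffs:
                kth = order[int(np.ceil(c * s.size)) - 1]
                cc = confusion_at(s, l, kth)
                acc[c].append(
                    (cc.sensitivity, cc.specificity, cc.precision, cc.npv)
                )
        for c in cutoffs:
            arr = np.array(acc[c], dtype=float)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                sens, spec, ppv, npv = np.nanmean(arr, axis=0)
            rows.append(
                {
                    "prevalence": K,
                    "cutoff": c,
                    "sensitivity": sens,
                    "specificity": spec,
                    "ppv": ppv,
                    "npv": npv,
                    "non_cases_per_case": misdiagnosis_odds(ppv)
                    if ppv > 0
                    else np.inf,
                }
            )
    return pd.DataFrame(rows)


def stratum_risk_score(
    strata: np.ndarray,
    labels: np.ndarray,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
) -> np.ndarray:
    """Coarse baseline: empirical per-stratum log-odds of disease.

    Risk levels (e.g. carrier categories of a major locus) are scored by the
    training-set log-odds of case within each stratum, with a +0.5
    continuity correction, and applied to the test set. Strata unseen in
    training receive the pooled log-odds.
    """
    strata = np.asarray(strata)
    labels = _check_labels(labels)
    tr_s, tr_y = strata[train_idx], labels[train_idx]
    if np.unique(tr_s).size < 1:
        raise ValueError("no strata in training data")
    pooled = np.log(((tr_y == 1).sum() + 0.5) / ((tr_y == -1).sum() + 0.5))
    log_odds = {}
    for s in np.unique(tr_s):
        m = tr_s == s
        log_odds[s] = np.log(
            ((tr_y[m] == 1).sum() + 0.5) / ((tr_y[m] == -1).sum() + 0.5)
        )
    unseen = [s for s in np.unique(strata[test_idx]) if s not in log_odds]
    if unseen:
        warnings.warn(
            f"strata unseen in training assigned pooled log-odds: {unseen}",
            stacklevel=2,
        )
    return np.array([log_odds.get(s, pooled) for s in strata[test_idx]])
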