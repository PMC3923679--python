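"""Risk-score calibration: quantile-bin reliability curves with
Agresti-Coull intervals, a local-regression correction map, and split-half
validation.

A predicted probability is well calibrated when, within each 5% quantile bin
of the predictions, the observed case proportion matches the bin's mean
prediction. The correction fits a LOESS smooth to the (mean predicted,
observed proportion) pairs, cleans it up with isotonic regression so the
raw->probability map is monotone, and interpolates between the bin knots.
Because calibration depends on prevalence, the split-half protocol assesses
it both at the data's own case fraction and after down-sampling cases.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.proportion import proportion_confint

from .evaluate import downsample_prevalence

N_BINS = 20  # 5% quantile bins
LOESS_SPAN = 0.75


def raw_to_probability(
    scores: np.ndarray,
    reference_scores: np.ndarray,
    reference_labels: np.ndarray,
) -> np.ndarray:
    """Naive raw-score -> probability transform from a reference cohort.

    Estimates the empirical case rate as a monotone function of score rank in
    the reference distribution (isotonic regression of case status on score)
    and evaluates it at each query score. Output is always in [0, 1]; with
    constant reference scores every sample maps to the case fraction.
    """
    reference_scores = np.asarray(reference_scores, dtype=float)
    reference_labels = np.asarray(reference_labels)
    if reference_scores.size == 0:
        raise ValueError("reference distribution is empty")
    y01 = (reference_labels == 1).astype(float)
    iso = IsotonicRegression(y_min=0.0, y_max=1.0, out_of_bounds="clip")
    iso.fit(reference_scores, y01)
    return np.clip(iso.predict(np.asarray(scores, dtype=float)), 0.0, 1.0)


def agresti_coull_interval(successes: int, n: int, alpha: float = 0.05):
    """95% (by default) Agresti-Coull interval for a binomial proportion."""
    lo, hi = proportion_confint(successes, n, alpha=alpha, method="agresti_coull")
    return float(np.clip(lo, 0, 1)), float(np.clip(hi, 0, 1))


@dataclass
class CalibrationMap:
    bin_edges: np.ndarray
    bin_mean_predicted: np.ndarray
    bin_observed: np.ndarray
    bin_ci_low: np.ndarray
    bin_ci_high: np.ndarray
    bin_n: np.ndarray
    knots_x: np.ndarray  # raw predicted value
    knots_y: np.ndarray  # calibrated probability (monotone)
    prevalence: float

    def apply(self, predicted: np.ndarray) -> np.ndarray:
        """Map raw predictions to calibrated probabilities (clipped [0,1])."""
        out = np.interp(np.asarray(predicted, dtype=float), self.knots_x, self.knots_y)
        return np.clip(out, 0.0, 1.0)

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mean_predicted": self.bin_mean_predicted,
                "observed": self.bin_observed,
                "ci_low": self.bin_ci_low,
                "ci_high": self.bin_ci_high,
                "n": self.bin_n,
            }
        )


def fit_calibration(
    predicted: np.ndarray,
    labels: np.ndarray,
    n_bins: int = N_BINS,
    span: float = LOESS_SPAN,
) -> CalibrationMap:
    """Reliability curve in 5% quantile bins plus a monotone correction map.

    Observed case proportions per bin carry 95% Agresti-Coull intervals; a
    LOESS smooth through the bin means, post-processed with isotonic
    regression, becomes the raw->probability correction. Bins emptied by
    ties in the predictions are merged into their left neighbor.
    """
    predicted = np.asarray(predicted, dtype=float)
    labels = np.asarray(labels)
    y01 = (labels == 1).astype(float)
    if predicted.size < 5 * n_bins:
        raise ValueError(
            f"need at least {5 * n_bins} samples for {n_bins} quantile bins"
        )
    edges = np.quantile(predicted, np.linspace(0.0, 1.0, n_bins + 1))
    edges = np.unique(edges)
    if edges.size - 1 < n_bins:
        warnings.warn(
            f"tied predictions collapsed {n_bins} bins into {edges.size - 1}; "
            "merged empty bins with neighbors",
            stacklevel=2,
        )
    n_eff = edges.size - 1
    which = np.clip(np.searchsorted(edges, predicted, side="right") - 1, 0, n_eff - 1)

    occupied = [b for b in range(n_eff) if np.any(which == b)]
    mean_pred = np.empty(len(occupied))
    observed = np.empty(len(occupied))
    ci_lo = np.empty(len(occupied))
    ci_hi = np.empty(len(occupied))
    counts = np.empty(len(occupied), dtype=int)
    for out_i, b in enumerate(occupied):
        m = which == b
        counts[out_i] = int(m.sum())
        mean_pred[out_i] = predicted[m].mean()
        observed[out_i] = y01[m].mean()
        ci_lo[out_i], ci_hi[out_i] = agresti_coull_interval(
            int(y01[m].sum()), counts[out_i]
        )
    n_eff = len(occupied)

    if n_eff >= 4:
        smooth = lowess(observed, mean_pred, frac=span, return_sorted=False)
    else:
        smooth = observed.copy()
    iso = IsotonicRegression(y_min=0.0, y_max=1.0, out_of_bounds="clip")
    order = np.argsort(mean_pred)
    knots_y = iso.fit_transform(mean_pred[order], np.clip(smooth[order], 0, 1))
    return CalibrationMap(
        bin_edges=edges,
        bin_mean_predicted=mean_pred,
        bin_observed=observed,
        bin_ci_low=ci_lo,
        bin_ci_high=ci_hi,
        bin_n=counts,
        knots_x=mean_pred[order],
        knots_y=np.asarray(knots_y),
        prevalence=float(y01.mean()),
    )


def binned_calibration_error(
    predicted: np.ndarray, labels: np.ndarray, n_bins: int = N_BINS
) -> float:
    """Mean absolute |observed - mean predicted| over quantile bins."""
    predicted = np.asarray(predicted, dtype=float)
    y01 = (np.asarray(labels) == 1).astype(float)
    edges = np.unique(np.quantile(predicted, np.linspace(0, 1, n_bins + 1)))
    n_eff = max(edges.size - 1, 1)
    which = np.clip(np.searchsorted(edges, predicted, side="right") - 1, 0, n_eff - 1)
    errs = []
    for b in range(n_eff):
        m = which == b
        if m.any():
            errs.append(abs(y01[m].mean() - predicted[m].mean()))
    return float(np.mean(errs))


@dataclass
class SplitHalfReport:
    prevalence: float
    pre_error: float
    post_error: float
    calibration: CalibrationMap
    n_fit: int
    n_test: int

    @property
    def improved(self) -> bool:
        return self.post_error < self.pre_error


def split_half_validate(
    predicted: np.ndarray,
    labels: np.ndarray,
    prevalences=(0.40, 0.10),
    seed: int = 0,
    n_bins: int = N_BINS,
) -> dict[float, SplitHalfReport]:
    """Fit the correction on one random half, assess it on the other.

    For each target prevalence the cases are first down-sampled (when the
    observed case fraction exceeds the target), the data are split into two
    stratified halves, the calibration map is fitted on half 1 and the
    binned absolute calibration error of half 2 is reported before and after
    applying the map. Half 2 never enters the fitting step.
    """
    predicted = np.asarray(predicted, dtype=float)
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    out: dict[float, SplitHalfReport] = {}
    for K in prevalences:
        observed = float((labels == 1).mean())
        if K < observed:
            idx = downsample_prevalence(labels, K, rng)
        else:
            idx = np.arange(labels.size)
        pred_K, lab_K = predicted[idx], labels[idx]
        # stratified half split
        half = np.zeros(lab_K.size, dtype=bool)
        for cls in (-1, 1):
            members = np.flatnonzero(lab_K == cls)
            pick = rng.permutation(members)[: members.size // 2]
            half[pick] = True
        cal = fit_calibration(pred_K[half], lab_K[half], n_bins=n_bins)
        pre = binned_calibration_error(pred_K[~half], lab_K[~half], n_bins=n_bins)
        post = binned_calibration_error(
            cal.apply(pred_K[~half]), lab_K[~half], n_bins=n_bins
        )
        out[K] = SplitHalfReport(
            prevalence=K,
            pre_error=pre,
            post_error=post,
            calibration=cal,
            n_fit=int(half.sum()),
            n_test=int((~half).sum()),
        )
    return out
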