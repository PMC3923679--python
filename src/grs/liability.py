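"""Liability-threshold conversions between AUC and variance explained.

Under the liability-threshold model a standard-normal latent liability
causes disease when it exceeds the upper-K quantile T, where K is the
population prevalence. For a risk score explaining a fraction ``rho2`` of
liability variance, the case/control AUC is

    AUC = Phi( (i - i2) * sqrt(rho2) / sqrt(2 - rho2*(i*(i-T) + i2*(i2-T))) )

with i = z/K the mean liability of cases, i2 = -z/(1-K) that of controls
and z the normal density at T. The inverse map (AUC -> rho2) is obtained by
root finding on this strictly increasing relation; dividing by an assumed
heritability h2 converts phenotypic variance explained into the fraction of
genetic variance captured.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from scipy.optimize import brentq
from scipy.stats import norm


@dataclass(frozen=True)
class LiabilityParams:
    """Threshold-model constants at prevalence ``K`` (and optional ``h2``)."""

    K: float
    h2: float | None = None
    T: float = field(init=False)
    z: float = field(init=False)
    i: float = field(init=False)
    i2: float = field(init=False)

    def __post_init__(self) -> None:
        if not 0.0 < self.K < 1.0:
            raise ValueError(f"prevalence K must be in (0, 1), got {self.K}")
        if self.h2 is not None and not 0.0 < self.h2 <= 1.0:
            raise ValueError(f"heritability h2 must be in (0, 1], got {self.h2}")
        object.__setattr__(self, "T", float(norm.ppf(1.0 - self.K)))
        object.__setattr__(self, "z", float(norm.pdf(self.T)))
        object.__setattr__(self, "i", self.z / self.K)
        object.__setattr__(self, "i2", -self.z / (1.0 - self.K))


def auc_from_variance(rho2: float, K: float) -> float:
    """AUC of a score explaining liability variance ``rho2`` at prevalence ``K``."""
    if not 0.0 <= rho2 < 1.0:
        raise ValueError(f"rho2 must be in [0, 1), got {rho2}")
    p = LiabilityParams(K)
    mean_diff = (p.i - p.i2) * rho2**0.5
    var_term = 2.0 - rho2 * (p.i * (p.i - p.T) + p.i2 * (p.i2 - p.T))
    return float(norm.cdf(mean_diff / var_term**0.5))


def variance_from_auc(auc: float, K: float, xtol: float = 1e-10) -> float:
    """Liability-scale variance explained corresponding to an observed AUC.

    Inverts :func:`auc_from_variance` by bisection; the relation is strictly
    increasing in ``rho2`` for fixed ``K``.
    """
    if auc < 0.5:
        raise ValueError(
            f"AUC {auc} < 0.5: the score ranks worse than chance; negate it first"
        )
    if auc >= 1.0:
        raise ValueError("AUC must be < 1")
    if auc == 0.5:
        return 0.0
    return float(
        brentq(lambda r: auc_from_variance(r, K) - auc, 0.0, 1.0 - 1e-12, xtol=xtol)
    )


def genetic_variance(rho2: float, h2: float) -> float:
    """Fraction of genetic (heritable) variance explained: rho2 / h2."""
    if not 0.0 < h2 <= 1.0:
        raise ValueError(f"h2 must be in (0, 1], got {h2}")
    if rho2 < 0.0:
        raise ValueError("rho2 must be nonnegative")
    if rho2 > h2:
        import warnings

        warnings.warn(
            f"rho2={rho2:.3f} exceeds assumed heritability h2={h2:.3f}; "
            "the score explains more variance than attributed to genetics",
            stacklevel=2,
        )
    return rho2 / h2
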