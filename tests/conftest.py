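import numpy as np
import pytest

from grs import synth


@pytest.fixture(scope="session")
def small_cohort():
    """A 400-sample, 300-SNP cohort with a strong MHC-like block."""
    cfg = synth.SimConfig(
        n_samples=400,
        n_snps=300,
        prevalence_K=0.05,
        study_case_fraction=0.4,
        major_block=synth.BlockConfig(n_snps=3, r=0.5, effects=(1.0, 0.5, 0.3)),
        n_polygenic=5,
        polygenic_effect_sd=0.2,
        missing_rate=0.002,
        seed=7,
    )
    return synth.simulate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_svm_instance(rng, n=40, p=10):
    """A small random dosage classification instance with both classes."""
    while True:
        X = rng.integers(0, 3, size=(n, p)).astype(float)
        y = np.where(rng.random(n) < 0.5, -1.0, 1.0)
        if 0 < (y == 1).sum() < n:
            return X, y


def lbfgs_oracle(X, y, lam):
    """Generic convex-solver reference optimum of the penalized objective.

    Split-variable reformulation (beta = b+ - b-, both nonnegative) makes the
    problem smooth with box constraints, solved by L-BFGS-B.
    """
    from scipy.optimize import minimize

    n, p = X.shape

    def fun(z):
        bp, bm, b0 = z[:p], z[p : 2 * p], z[2 * p]
        h = np.maximum(1 - y * (b0 + X @ (bp - bm)), 0)
        return h @ h + lam * (bp.sum() + bm.sum())

    def jac(z):
        bp, bm, b0 = z[:p], z[p : 2 * p], z[2 * p]
        h = np.maximum(1 - y * (b0 + X @ (bp - bm)), 0)
        gb = -2 * (X.T @ (y * h))
        return np.concatenate([gb + lam, -gb + lam, [-2 * np.sum(y * h)]])

    res = minimize(
        fun,
        np.zeros(2 * p + 1),
        jac=jac,
        method="L-BFGS-B",
        bounds=[(0, None)] * (2 * p) + [(None, None)],
        options=dict(maxiter=20000, ftol=1e-15, gtol=1e-12),
    )
    return res.fun
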