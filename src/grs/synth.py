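"""Synthetic case/control genotype cohorts under a liability-threshold model.

The generator emulates the statistical structure of a strongly
immune-mediated disease study: a latent liability L = g + e with unit-normal
residual e, where the genetic value g combines a major-effect locus inside a
high-LD block (an MHC-like region on chromosome 6, 29.7-33.3 Mb) with a
polygenic tail of small independent effects. Disease occurs when L exceeds
the threshold T chosen so that the population prevalence is K. Case/control
cohorts are then ascertained to a study case fraction far above K (drawing
with replacement from the case and control strata of a finite
super-population pool), a small fraction of controls are relabeled cryptic
cases, per-cohort allele frequencies can be perturbed on the logit scale,
and dosages are masked missing at a configurable rate.

The threshold T is solved exactly from the generating mixture,
mean_i Phi(g_i - T) = K over the pool, so that the marginal disease
probability is K by construction rather than by a normality approximation.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from .data import MISSING, GenotypeData
from .plink import read_plink, write_plink
from .qc import MHC_CHROM, MHC_END_BP, MHC_START_BP


@dataclass(frozen=True)
class BlockConfig:
    """The MHC-like high-LD block of jointly drawn SNPs.

    ``r`` is the target pairwise dosage correlation (exchangeable, via a
    Gaussian copula); ``effects`` are per-SNP liability-scale effect sizes
    (broadcast from a scalar; padded with zeros to ``n_snps``).
    """

    chrom: str = MHC_CHROM
    n_snps: int = 5
    r: float = 0.6
    effects: tuple = (0.5, 0.25, 0.2, 0.15, 0.1)

    def effect_vector(self) -> np.ndarray:
        eff = np.atleast_1d(np.asarray(self.effects, dtype=np.float64))
        if eff.size == 1:
            eff = np.full(self.n_snps, eff[0])
        if eff.size > self.n_snps:
            raise ValueError("more block effects than block SNPs")
        return np.pad(eff, (0, self.n_snps - eff.size))


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for one simulated cohort."""

    n_samples: int = 2000
    n_snps: int = 5000
    prevalence_K: float = 0.01
    study_case_fraction: float = 0.4
    major_block: BlockConfig = field(default_factory=BlockConfig)
    n_polygenic: int = 15
    polygenic_effect_sd: float = 0.15
    cryptic_case_rate: float = 0.01
    cohort_af_shift_sd: float = 0.0
    missing_rate: float = 0.001
    pool_multiplier: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "prevalence_K",
            "study_case_fraction",
            "cryptic_case_rate",
            "missing_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        if self.prevalence_K <= 0.0:
            raise ValueError("prevalence_K must be positive")
        if not 0.0 <= self.major_block.r < 1.0:
            raise ValueError("block correlation r must be in [0, 1)")
        if self.major_block.n_snps + self.n_polygenic > self.n_snps:
            raise ValueError("n_block_snps + n_polygenic must not exceed n_snps")
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")


@dataclass
class TruthRecord:
    """Ground truth of a simulated cohort, for parameter-recovery tests."""

    causal_ids: np.ndarray
    effects: np.ndarray
    threshold: float
    achievable_auc: float
    genetic_variance: float  # Var(g); variance explained = Var(g)/(Var(g)+1)
    cryptic_idx: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    pool_disease_rate: float = float("nan")  # realized P(L > T) in the pool

    @property
    def achievable_rho2(self) -> float:
        return self.genetic_variance / (self.genetic_variance + 1.0)


def _copula_block(rng: np.random.Generator, n: int, freqs: np.ndarray, r: float) -> np.ndarray:
    """Dosages with exchangeable latent correlation r, HWE marginals."""
    m = freqs.size
    shared = rng.standard_normal(n)[:, None]
    z = np.sqrt(r) * shared + np.sqrt(1.0 - r) * rng.standard_normal((n, m))
    # threshold each latent normal at the genotype-distribution quantiles
    p_hom_ref = (1.0 - freqs) ** 2  # dosage 0
    p_het = 2.0 * freqs * (1.0 - freqs)
    lo = norm.ppf(p_hom_ref)
    hi = norm.ppf(p_hom_ref + p_het)
    return ((z > lo).astype(np.int8) + (z > hi).astype(np.int8))


def _draw_pool(
    cfg: SimConfig, freqs: np.ndarray, n_pool: int, rng: np.random.Generator
) -> np.ndarray:
    nb = cfg.major_block.n_snps
    X = np.empty((n_pool, cfg.n_snps), dtype=np.int8)
    if nb:
        X[:, :nb] = _copula_block(rng, n_pool, freqs[:nb], cfg.major_block.r)
    # all remaining SNPs are independent binomial draws under HWE
    for start in range(nb, cfg.n_snps, 1000):
        stop = min(start + 1000, cfg.n_snps)
        X[:, start:stop] = rng.binomial(
            2, freqs[start:stop], size=(n_pool, stop - start)
        ).astype(np.int8)
    return X


def _variant_table(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    nb = cfg.major_block.n_snps
    p = cfg.n_snps
    chroms = np.empty(p, dtype=object)
    pos = np.empty(p, dtype=np.int64)
    if nb:
        chroms[:nb] = cfg.major_block.chrom
        pos[:nb] = np.sort(
            rng.choice(np.arange(MHC_START_BP, MHC_END_BP), size=nb, replace=False)
        )
    # spread the remaining SNPs over the other autosomes
    rest = p - nb
    other_chrom = np.sort(rng.integers(1, 23, size=rest))
    other_chrom[other_chrom == 6] = 7
    chroms[nb:] = other_chrom.astype(str)
    pos[nb:] = rng.integers(1, 200_000_000, size=rest)
    alleles = np.array(["A", "C", "G", "T"])
    a1 = alleles[rng.integers(0, 4, size=p)]
    a2_choices = np.array([["C", "G"], ["A", "T"], ["T", "A"], ["G", "C"]])
    a2 = np.array([a2_choices[list("ACGT").index(x)][i % 2] for i, x in enumerate(a1)])
    return pd.DataFrame(
        {
            "chrom": chroms,
            "id": [f"snp{i:06d}" for i in range(p)],
            "cm": 0.0,
            "pos": pos,
            "a1": a1,
            "a2": a2,
        }
    )


def simulate_cohort(
    cfg: SimConfig, cohort: int = 0
) -> tuple[GenotypeData, TruthRecord]:
    """Simulate one ascertained case/control cohort plus its ground truth.

    ``cohort`` selects an independent cohort under the same generating model:
    base allele frequencies and effect sizes are shared (they derive from
    ``cfg.seed`` alone), while genotype sampling and the per-cohort
    allele-frequency perturbation differ.
    """
    ss = np.random.SeedSequence([cfg.seed, 2_000_003])
    base_rng = np.random.default_rng(ss.spawn(1)[0])
    cohort_rng = np.random.default_rng(
        np.random.SeedSequence([cfg.seed, 7_000_033, cohort])
    )

    nb = cfg.major_block.n_snps
    npoly = cfg.n_polygenic
    p = cfg.n_snps

    # base allele frequencies and effects are cohort-invariant
    freqs = np.empty(p)
    freqs[:nb] = base_rng.uniform(0.15, 0.5, size=nb)
    freqs[nb:] = base_rng.uniform(0.05, 0.95, size=p - nb)
    b = np.zeros(p)
    b[:nb] = cfg.major_block.effect_vector()
    b[nb : nb + npoly] = base_rng.normal(0.0, cfg.polygenic_effect_sd, size=npoly)
    variants = _variant_table(cfg, base_rng)

    # per-cohort logit-scale frequency perturbation
    if cfg.cohort_af_shift_sd > 0:
        shift = cohort_rng.normal(0.0, cfg.cohort_af_shift_sd, size=p)
        freqs_c = 1.0 / (1.0 + np.exp(-(np.log(freqs / (1 - freqs)) + shift)))
        freqs_c = np.clip(freqs_c, 1e-4, 1 - 1e-4)
    else:
        freqs_c = freqs

    n_cases_needed = int(round(cfg.study_case_fraction * cfg.n_samples))
    n_controls_needed = cfg.n_samples - n_cases_needed

    n_pool = max(cfg.pool_multiplier * cfg.n_samples, 2000)
    X_pool = _draw_pool(cfg, freqs_c, n_pool, cohort_rng)

    g = X_pool[:, : nb + npoly].astype(np.float64) @ b[: nb + npoly]
    g = g - g.mean()
    var_g = float(g.var())

    # threshold with P(disease) = K exactly under the generating mixture:
    # mean_i Phi(g_i - T) = K, with e ~ N(0,1)
    K = cfg.prevalence_K
    lo, hi = g.min() - 10.0, g.max() + 10.0
    T = float(brentq(lambda t: norm.sf(t - g).mean() - K, lo, hi, xtol=1e-10))

    liab = g + cohort_rng.standard_normal(n_pool)
    disease = liab > T

    case_idx = np.flatnonzero(disease)
    control_idx = np.flatnonzero(~disease)
    if case_idx.size == 0 or (n_cases_needed > 0 and case_idx.size < 10):
        raise ValueError(
            f"only {case_idx.size} cases arose in a pool of {n_pool}; "
            "increase n_samples/pool_multiplier or the prevalence K"
        )
    if control_idx.size == 0:
        raise ValueError("no controls in the simulated pool; lower K")

    # ascertain with replacement from the two strata
    take_cases = cohort_rng.choice(case_idx, size=n_cases_needed, replace=True)
    n_cryptic = int(round(cfg.cryptic_case_rate * n_controls_needed))
    take_ctrl_true = cohort_rng.choice(
        control_idx, size=n_controls_needed - n_cryptic, replace=True
    )
    take_cryptic = cohort_rng.choice(case_idx, size=n_cryptic, replace=True)

    rows = np.concatenate([take_cases, take_ctrl_true, take_cryptic])
    pheno = np.concatenate(
        [
            np.ones(n_cases_needed, dtype=np.int8),
            -np.ones(n_controls_needed, dtype=np.int8),
        ]
    )
    order = cohort_rng.permutation(rows.size)
    rows, pheno = rows[order], pheno[order]

    X = X_pool[rows].copy()
    g_sample = g[rows]

    # achievable AUC: the true genetic score on the ascertained sample,
    # scored against the observed labels (cryptic cases count as controls) —
    # the ceiling any fitted score evaluated on those labels can approach
    true_state = disease[rows]
    achievable_auc = _auc(g_sample, pheno == 1)

    if cfg.missing_rate > 0:
        mask = cohort_rng.random(X.shape) < cfg.missing_rate
        X[mask] = MISSING

    samples = pd.DataFrame(
        {
            "fid": [f"c{cohort}s{i:06d}" for i in range(rows.size)],
            "iid": [f"c{cohort}s{i:06d}" for i in range(rows.size)],
            "phenotype": pheno,
        }
    )
    data = GenotypeData(dosages=X, variants=variants, samples=samples)
    cryptic_positions = np.flatnonzero((pheno == -1) & true_state)
    truth = TruthRecord(
        causal_ids=variants["id"].to_numpy()[: nb + npoly],
        effects=b[: nb + npoly],
        threshold=T,
        achievable_auc=achievable_auc,
        genetic_variance=var_g,
        cryptic_idx=cryptic_positions,
        pool_disease_rate=float(disease.mean()),
    )
    return data, truth


def _auc(scores: np.ndarray, positive: np.ndarray) -> float:
    from sklearn.metrics import roc_auc_score

    if positive.all() or (~positive).all():
        return float("nan")
    return float(roc_auc_score(positive.astype(int), scores))


def write_fixture(
    data: GenotypeData, truth: TruthRecord, directory: str | os.PathLike
) -> dict[str, Path]:
    """Write a cohort as PLINK bed/bim/fam plus a tab-separated truth sidecar."""
    if data.n_samples == 0:
        raise ValueError("refusing to write a fixture with zero samples")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    prefix = directory / "cohort"
    write_plink(data, prefix)
    truth_path = directory / "truth.tsv"
    with open(truth_path, "w") as fh:
        fh.write(f"# threshold: {truth.threshold:.10g}\n")
        fh.write(f"# achievable_auc: {truth.achievable_auc:.10g}\n")
        fh.write(f"# genetic_variance: {truth.genetic_variance:.10g}\n")
        fh.write("snp_id\teffect\n")
        for sid, eff in zip(truth.causal_ids, truth.effects):
            fh.write(f"{sid}\t{eff:.10g}\n")
    return {
        "bed": prefix.with_suffix(".bed"),
        "bim": prefix.with_suffix(".bim"),
        "fam": prefix.with_suffix(".fam"),
        "truth": truth_path,
    }


def read_fixture(directory: str | os.PathLike) -> tuple[GenotypeData, pd.DataFrame]:
    directory = Path(directory)
    data = read_plink(directory / "cohort")
    truth = pd.read_csv(directory / "truth.tsv", sep="\t", comment="#")
    return data, truth
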