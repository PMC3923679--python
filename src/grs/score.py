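"""Genomic risk score computation and population-percent thresholding.

The score of a sample is ``intercept + sum_j weight_j * dosage_j`` over the
model SNPs, with the dosage counting the model's effect allele. When the
data file counts the other allele the dosage is flipped (2 - d); SNPs whose
alleles cannot be reconciled (strand-ambiguous A/T and C/G pairs that only
match via complement) are dropped with a warning. Missing dosages score at
the model's stored training mean dosage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data import MISSING, GenotypeData
from .models import ConsensusModel

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class RiskScores:
    sample_id: np.ndarray
    raw: np.ndarray
    probability: np.ndarray | None = None
    n_model_snps_used: int = 0
    dropped_snps: tuple = ()


def _complement(allele: str) -> str:
    return "".join(_COMPLEMENT.get(b, "N") for b in allele)


def score(data: GenotypeData, model: ConsensusModel) -> RiskScores:
    """Score every sample in ``data`` with a consensus model."""
    id_to_col = {sid: j for j, sid in enumerate(data.variants["id"])}
    a1 = data.variants["a1"].to_numpy()
    a2 = data.variants["a2"].to_numpy()

    missing_ids = [sid for sid in model.snp_id if sid not in id_to_col]
    if len(missing_ids) > 0.10 * model.n_snps:
        raise ValueError(
            f"{len(missing_ids)}/{model.n_snps} model SNPs absent from data: "
            f"{missing_ids[:10]}{'...' if len(missing_ids) > 10 else ''}"
        )
    if missing_ids:
        warnings.warn(
            f"{len(missing_ids)} model SNPs absent from data; they are skipped",
            stacklevel=2,
        )

    total = np.full(data.n_samples, model.intercept, dtype=np.float64)
    used = 0
    dropped: list[str] = []
    for j_model, sid in enumerate(model.snp_id):
        col = id_to_col.get(sid)
        if col is None:
            continue
        eff = model.effect_allele[j_model]
        oth = model.other_allele[j_model] if model.other_allele is not None else None
        flip = False
        if a1[col] == eff:
            flip = False
        elif a2[col] == eff:
            flip = True
        else:
            # try the strand complement; palindromic SNPs are unresolvable
            pair = {a1[col], a2[col]}
            if pair in ({"A", "T"}, {"C", "G"}):
                dropped.append(sid)
                continue
            if a1[col] == _complement(eff):
                flip = False
            elif a2[col] == _complement(eff):
                flip = True
            else:
                dropped.append(sid)
                continue
        if oth is not None and oth != "." and not flip and a2[col] not in (
            oth,
            _complement(oth),
        ):
            dropped.append(sid)
            continue

        d = data.dosages[:, col].astype(np.float64)
        miss = data.dosages[:, col] == MISSING
        if model.mean_dosage is not None and np.isfinite(model.mean_dosage[j_model]):
            fill = model.mean_dosage[j_model]
        else:
            fill = np.nanmean(np.where(miss, np.nan, d)) if (~miss).any() else 0.0
        d[miss] = (2.0 - fill) if flip else fill
        if flip:
            d[~miss] = 2.0 - d[~miss]
        total += model.weights[j_model] * d
        used += 1

    if dropped:
        warnings.warn(
            f"dropped {len(dropped)} model SNPs with unresolvable alleles: "
            f"{dropped[:10]}{'...' if len(dropped) > 10 else ''}",
            stacklevel=2,
        )
    return RiskScores(
        sample_id=data.samples["iid"].to_numpy(),
        raw=total,
        n_model_snps_used=used,
        dropped_snps=tuple(dropped),
    )


def threshold(
    scores: np.ndarray | RiskScores,
    cutoff: float,
    reference: np.ndarray | None = None,
) -> np.ndarray:
    """Classify the top ``cutoff`` population fraction as positive.

    The decision boundary is the (1 - cutoff) quantile of the reference score
    distribution (the scored cohort itself by default). Scores greater than
    or equal to the boundary are positive, so ties at the boundary all go
    positive; with distinct scores exactly ceil(cutoff * n) samples are
    flagged.
    """
    raw = scores.raw if isinstance(scores, RiskScores) else np.asarray(scores)
    if not 0.0 < cutoff < 1.0:
        raise ValueError(f"cutoff must be a population fraction in (0, 1), got {cutoff}")
    ref = raw if reference is None else np.asarray(reference)
    k = int(np.ceil(cutoff * ref.size))
    boundary = np.sort(ref)[::-1][k - 1]
    return raw >= boundary
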