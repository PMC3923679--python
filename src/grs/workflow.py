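"""End-to-end analysis orchestration: QC -> CV fit -> consensus ->
external-cohort scoring -> prevalence evaluation -> screening report.

The training cohort is quality-controlled and cross-validated; the selected
consensus model is then frozen and applied, without any re-tuning, to each
validation cohort. Validation phenotypes are only read after scoring
completes, so external AUCs cannot leak into model selection. Every stage
records its thresholds, seeds and sample/SNP counts in a run manifest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import cv as cvmod
from . import evaluate, plink, qc
from .data import GenotypeData
from .models import ConsensusModel
from .score import score as score_fn


@dataclass
class RunConfig:
    training: GenotypeData | str
    validation: list = field(default_factory=list)
    qc_thresholds: qc.QCThresholds = field(default_factory=qc.QCThresholds)
    k: int = 10
    replicates: int = 10
    grid_size: int = 25
    min_ratio: float = 0.01
    prevalences: tuple = evaluate.DEFAULT_PREVALENCES
    cutoffs: tuple = (0.05, 0.10, 0.15, 0.20, 0.30, 0.40)
    eval_replicates: int = evaluate.DEFAULT_REPLICATES
    mhc_mode: str = "all"
    seed: int = 0
    outdir: str | None = None


@dataclass
class RunResult:
    qc_report: qc.QCReport
    cv: cvmod.CVResult
    selection: cvmod.ModelSizeSelection
    model: ConsensusModel
    cv_auc: float
    validation_auc: list
    validation_scores: list
    manifest: dict


def _load(cohort) -> GenotypeData:
    return plink.read_plink(cohort) if isinstance(cohort, (str, Path)) else cohort


def fit_and_validate(config: RunConfig) -> RunResult:
    """Run the full training workflow and score validation cohorts."""
    train = _load(config.training)
    train = qc.mhc_filter(train, config.mhc_mode)
    train, report = qc.apply_qc(train, config.qc_thresholds)

    cv = cvmod.run_cv(
        train,
        k=config.k,
        replicates=config.replicates,
        grid_size=config.grid_size,
        min_ratio=config.min_ratio,
        seed=config.seed,
    )
    selection = cvmod.select_model_size(cv)
    model = cvmod.build_consensus(
        cv, train, selection.lambda_index, selection.target_size
    )
    cv_auc = float(cv.mean_auc()[selection.lambda_index])

    validation_auc = []
    validation_scores = []
    for cohort in config.validation:
        vdata = _load(cohort)
        # frozen model: scoring touches genotypes only; labels are read
        # afterwards purely for evaluation
        rs = score_fn(vdata, model)
        labels = vdata.phenotype
        if np.unique(labels[labels != 0]).size == 2:
            _, auc = evaluate.roc_auc(rs.raw[labels != 0], labels[labels != 0])
        else:
            auc = float("nan")
        validation_auc.append(auc)
        validation_scores.append(rs)

    manifest = {
        "seed": config.seed,
        "mhc_mode": config.mhc_mode,
        "qc": report.to_dict(),
        "cv": {
            "k": config.k,
            "replicates": config.replicates,
            "grid_size": config.grid_size,
            "min_ratio": config.min_ratio,
            "selected_lambda": selection.lambda_value,
            "target_size": selection.target_size,
            "mean_cv_auc": cv_auc,
        },
        "model_snps": int(model.n_snps),
        "validation_auc": [float(a) for a in validation_auc],
    }

    if config.outdir:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        plink.write_model(model, outdir / "model.tsv")
        selection.curve.to_csv(outdir / "cv_curve.tsv", sep="\t", index=False)
        for i, rs in enumerate(validation_scores):
            plink.write_scores(rs.sample_id, rs.raw, outdir / f"scores_cohort{i}.tsv")
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))

    return RunResult(
        qc_report=report,
        cv=cv,
        selection=selection,
        model=model,
        cv_auc=cv_auc,
        validation_auc=validation_auc,
        validation_scores=validation_scores,
        manifest=manifest,
    )


def screening_report(
    scores: np.ndarray,
    labels: np.ndarray,
    prevalences=evaluate.DEFAULT_PREVALENCES,
    cutoffs=(0.05, 0.10, 0.15, 0.20, 0.30, 0.40),
    target_npv: float = 0.996,
    replicates: int = evaluate.DEFAULT_REPLICATES,
    seed: int = 0,
    outdir: str | None = None,
) -> dict:
    """Screening summary across prevalences and population-percent cutoffs.

    Reports, per prevalence: the full screening table, the exclusion
    threshold (the highest cutoff achieving the requested NPV, or the
    maximum achievable NPV when the request is out of reach), and the
    PPV/sensitivity trade-off pairs.
    """
    table = evaluate.screening_table(
        scores, labels, prevalences, cutoffs, replicates=replicates, seed=seed
    )
    exclusion = {}
    for K in prevalences:
        sub = table[table["prevalence"] == K]
        ok = sub[sub["npv"] >= target_npv]
        defined = sub.dropna(subset=["npv"])
        if len(ok):
            row = ok.loc[ok["cutoff"].idxmax()]
            exclusion[K] = {
                "cutoff": float(row["cutoff"]),
                "npv": float(row["npv"]),
                "achieved": True,
            }
        elif len(defined):
            best = defined.loc[defined["npv"].idxmax()]
            exclusion[K] = {
                "cutoff": float(best["cutoff"]),
                "npv": float(best["npv"]),
                "achieved": False,
                "note": f"requested NPV {target_npv} unachievable; maximum reported",
            }
        else:
            exclusion[K] = {
                "cutoff": float("nan"),
                "npv": float("nan"),
                "achieved": False,
                "note": "NPV undefined at every cutoff (no negative calls)",
            }
    tradeoff = table[["prevalence", "cutoff", "sensitivity", "ppv"]].copy()
    report = {
        "table": table,
        "exclusion_threshold": exclusion,
        "ppv_sensitivity": tradeoff,
        "target_npv": target_npv,
        "seed": seed,
    }
    if outdir:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / "screening_table.tsv", sep="\t", index=False)
        (outdir / "screening_summary.json").write_text(
            json.dumps(
                {
                    "exclusion_threshold": exclusion,
                    "target_npv": target_npv,
                    "seed": seed,
                },
                indent=2,
            )
        )
    return report
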