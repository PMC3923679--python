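"""Repeated stratified CV, model-size selection, consensus construction."""

import numpy as np
import pytest

from grs import cv as cvmod
from grs import qc, synth
from grs.cv import CVResult, FoldModel
from grs.score import score


@pytest.fixture(scope="module")
def cohort_cv(small_cohort):
    data, truth = small_cohort
    clean, _ = qc.apply_qc(data)
    res = cvmod.run_cv(clean, k=3, replicates=2, grid_size=8, min_ratio=0.05, seed=42)
    return clean, truth, res


class TestRunCv:
    def test_each_sample_tested_once_per_replicate(self, cohort_cv):
        clean, _, res = cohort_cv
        for rep in range(res.replicates):
            seen = np.concatenate(
                [
                    te
                    for fm, te in zip(res.fold_models, res.test_indices)
                    if fm.replicate == rep
                ]
            )
            assert sorted(seen) == list(range(clean.n_samples))

    def test_deterministic_under_seed(self, cohort_cv):
        clean, _, res = cohort_cv
        res2 = cvmod.run_cv(
            clean, k=3, replicates=2, grid_size=8, min_ratio=0.05, seed=42
        )
        assert np.array_equal(res.auc, res2.auc)
        assert np.array_equal(res.n_nonzero, res2.n_nonzero)

    def test_strong_signal_detected(self, cohort_cv):
        _, truth, res = cohort_cv
        assert res.mean_auc().max() > 0.8

    def test_folds_stratified(self, cohort_cv):
        clean, _, res = cohort_cv
        y = clean.phenotype
        case_frac = (y == 1).mean()
        for te in res.test_indices:
            assert abs((y[te] == 1).mean() - case_frac) < 0.08

    def test_unknown_phenotype_rejected(self, small_cohort):
        data, _ = small_cohort
        bad = data.subset()
        bad.samples.loc[0, "phenotype"] = 0
        with pytest.raises(ValueError, match="phenotype"):
            cvmod.run_cv(bad, k=2, replicates=1)


class TestSelectModelSize:
    def test_selected_size_matches_mean_nonzero(self, cohort_cv):
        _, _, res = cohort_cv
        sel = cvmod.select_model_size(res)
        assert sel.target_size == round(res.mean_size()[sel.lambda_index])

    def test_tie_breaks_to_smaller_model(self):
        # two penalties, identical AUC everywhere: the sparser model wins
        fm = FoldModel(
            replicate=0,
            fold=0,
            nz_idx=[np.array([0]), np.array([0, 1])],
            nz_val=[np.array([1.0]), np.array([1.0, 0.5])],
            beta0=np.zeros(2),
        )
        res = CVResult(
            lambdas=np.array([2.0, 1.0]),
            auc=np.full((1, 1, 2), 0.8),
            n_nonzero=np.array([[[1, 2]]]),
            fold_models=[fm],
            test_indices=[np.arange(4)],
            n_snps=3,
            seed=0,
            k=1,
            replicates=1,
        )
        sel = cvmod.select_model_size(res)
        assert sel.lambda_index == 0 and sel.target_size == 1

    def test_null_data_smoothed_curve_near_chance(self):
        cfg = synth.SimConfig(
            n_samples=300,
            n_snps=80,
            prevalence_K=0.05,
            major_block=synth.BlockConfig(n_snps=2, r=0.3, effects=(0.0,)),
            n_polygenic=0,
            polygenic_effect_sd=0.0,
            missing_rate=0.0,
            seed=3,
        )
        data, _ = synth.simulate_cohort(cfg)
        res = cvmod.run_cv(data, k=3, replicates=2, grid_size=5, min_ratio=0.1, seed=1)
        sel = cvmod.select_model_size(res)
        sd = res.auc.std(axis=(0, 1)).max()
        assert np.all(np.abs(sel.curve["smoothed_auc"] - 0.5) < max(3 * sd, 0.12))


class TestBuildConsensus:
    def test_stability_definition(self):
        # a SNP nonzero in 37 of 100 fold-models has stability 37
        fms = []
        for i in range(100):
            idx = np.array([0, 1]) if i < 37 else np.array([1])
            val = np.array([0.5, 1.0]) if i < 37 else np.array([1.0])
            fms.append(
                FoldModel(
                    replicate=i // 10, fold=i % 10, nz_idx=[idx], nz_val=[val],
                    beta0=np.array([0.1]),
                )
            )
        res = CVResult(
            lambdas=np.array([1.0]),
            auc=np.full((10, 10, 1), 0.7),
            n_nonzero=np.full((10, 10, 1), 2),
            fold_models=fms,
            test_indices=[np.arange(2)] * 100,
            n_snps=3,
            seed=0,
            k=10,
            replicates=10,
        )
        import pandas as pd

        from grs.data import GenotypeData

        data = GenotypeData(
            dosages=np.zeros((4, 3), dtype=np.int8),
            variants=pd.DataFrame(
                {
                    "chrom": "1",
                    "id": ["a", "b", "c"],
                    "cm": 0.0,
                    "pos": [1, 2, 3],
                    "a1": "A",
                    "a2": "G",
                }
            ),
            samples=pd.DataFrame(
                {"fid": list("wxyz"), "iid": list("wxyz"), "phenotype": [1, -1, 1, -1]}
            ),
        )
        model = cvmod.build_consensus(res, data, 0, target_size=None)
        by_id = dict(zip(model.snp_id, model.stability))
        assert by_id["a"] == pytest.approx(37.0)
        assert by_id["b"] == pytest.approx(100.0)
        wt = dict(zip(model.snp_id, model.weights))
        assert wt["a"] == pytest.approx(0.37 * 0.5)
        assert wt["b"] == pytest.approx(1.0)
        assert model.intercept == pytest.approx(0.1)

        # truncation drops the SNP ranked below target_size by |mean weight|
        trunc = cvmod.build_consensus(res, data, 0, target_size=1)
        assert list(trunc.snp_id) == ["b"]

    def test_identical_fold_models_give_full_stability(self, cohort_cv):
        clean, _, res = cohort_cv
        model = cvmod.build_consensus(res, clean, len(res.lambdas) - 1, None)
        assert np.all(model.stability > 0)
        assert np.all(model.stability <= 100)

    def test_consensus_score_is_mean_of_fold_scores(self, cohort_cv):
        clean, _, res = cohort_cv
        li = len(res.lambdas) - 1
        model = cvmod.build_consensus(res, clean, li, target_size=None)
        rs = score(clean, model)
        X = clean.dosage_matrix(impute_means=np.nan_to_num(clean.snp_means()))
        per_model = np.zeros(clean.n_samples)
        for fm in res.fold_models:
            beta = np.zeros(clean.n_snps)
            beta[fm.nz_idx[li]] = fm.nz_val[li]
            per_model += X @ beta + fm.beta0[li]
        per_model /= res.n_models
        assert np.allclose(rs.raw, per_model, atol=1e-8)

    def test_oversized_target_keeps_all_with_warning(self, cohort_cv):
        clean, _, res = cohort_cv
        with pytest.warns(UserWarning, match="ever"):
            model = cvmod.build_consensus(res, clean, len(res.lambdas) - 1, 10_000)
        assert model.n_snps <= 10_000


def test_causal_snps_dominate_stability_ranks():
    """Parameter recovery on a modest cohort: causal stability > noise."""
    cfg = synth.SimConfig(
        n_samples=600,
        n_snps=400,
        prevalence_K=0.05,
        study_case_fraction=0.4,
        major_block=synth.BlockConfig(n_snps=4, r=0.4, effects=(1.2, 0.8, 0.6, 0.5)),
        n_polygenic=6,
        polygenic_effect_sd=0.35,
        missing_rate=0.0,
        seed=21,
    )
    data, truth = synth.simulate_cohort(cfg)
    res = cvmod.run_cv(data, k=3, replicates=2, grid_size=8, min_ratio=0.05, seed=5)
    sel = cvmod.select_model_size(res)
    model = cvmod.build_consensus(res, data, sel.lambda_index, target_size=None)
    stab = dict(zip(model.snp_id, model.stability))
    causal = set(truth.causal_ids)
    causal_stab = [stab.get(sid, 0.0) for sid in causal]
    noise_stab = [stab.get(sid, 0.0) for sid in data.variants["id"] if sid not in causal]
    assert np.median(causal_stab) > np.median(noise_stab)
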