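"""ROC/AUC, predictive values, prevalence re-sampling, screening tables."""

import numpy as np
import pytest

from grs import evaluate


def pair_counting_auc(scores, labels):
    """Brute-force Mann-Whitney AUC with ties counted one half."""
    pos = scores[labels == 1]
    neg = scores[labels == -1]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        _, auc = evaluate.roc_auc(
            np.array([1.0, 2, 3, 4]), np.array([-1, -1, 1, 1])
        )
        assert auc == 1.0

    def test_all_ties_is_chance(self):
        _, auc = evaluate.roc_auc(np.ones(10), np.resize([-1, 1], 10))
        assert auc == 0.5

    def test_matches_pair_counting_oracle(self, rng):
        scores = rng.integers(0, 8, size=30).astype(float)  # force ties
        labels = np.where(rng.random(30) < 0.5, 1, -1)
        if np.unique(labels).size < 2:
            labels[0] = -labels[0]
        _, auc = evaluate.roc_auc(scores, labels)
        assert auc == pytest.approx(pair_counting_auc(scores, labels))

    def test_invariant_to_monotone_transform(self, rng):
        scores = rng.normal(size=50)
        labels = np.where(rng.random(50) < 0.4, 1, -1)
        labels[:2] = [1, -1]
        _, a1 = evaluate.roc_auc(scores, labels)
        _, a2 = evaluate.roc_auc(np.exp(3 * scores), labels)
        assert a1 == pytest.approx(a2)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            evaluate.roc_auc(np.arange(4.0), np.ones(4))


class TestPpvNpv:
    def test_perfect_test(self):
        assert evaluate.ppv_npv(1.0, 1.0, 0.1) == (1.0, 1.0)

    def test_hla_screening_worked_example(self):
        # carrier-based screen flagging 65% of the population at 10%
        # prevalence: sens = 1, spec = (0.90 - 0.55)/0.90
        ppv, _ = evaluate.ppv_npv(1.0, (0.90 - 0.55) / 0.90, 0.10)
        assert evaluate.misdiagnosis_odds(ppv) == pytest.approx(5.5, abs=1e-9)

    def test_matches_confusion_counts_at_matched_prevalence(self, rng):
        for _ in range(20):
            n = 400
            labels = np.where(rng.random(n) < 0.3, 1, -1)
            scores = rng.normal(size=n) + 0.8 * (labels == 1)
            cut = np.quantile(scores, 0.7)
            cc = evaluate.confusion_at(scores, labels, cut)
            prev = (labels == 1).mean()
            ppv, npv = evaluate.ppv_npv(cc.sensitivity, cc.specificity, prev)
            if np.isfinite(cc.precision):
                assert ppv == pytest.approx(cc.precision, abs=1e-12)
            if np.isfinite(cc.npv):
                assert npv == pytest.approx(cc.npv, abs=1e-12)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            evaluate.ppv_npv(1.2, 0.5, 0.1)


class TestMisdiagnosisOdds:
    @pytest.mark.parametrize("ppv,odds", [(0.5, 1.0), (1.0, 0.0), (0.2, 4.0)])
    def test_closed_form(self, ppv, odds):
        assert evaluate.misdiagnosis_odds(ppv) == pytest.approx(odds)

    def test_zero_ppv_is_infinite(self):
        assert np.isinf(evaluate.misdiagnosis_odds(0.0))


class TestDownsamplePrevalence:
    def test_case_count_arithmetic(self):
        # 1943 cases / 3215 controls at K = 0.10 -> floor(3215*0.1/0.9) = 357
        labels = np.concatenate([np.ones(1943), -np.ones(3215)]).astype(int)
        idx = evaluate.downsample_prevalence(labels, 0.10, seed=0)
        assert (labels[idx] == 1).sum() == 357
        assert (labels[idx] == -1).sum() == 3215

    def test_identity_at_observed_fraction(self):
        labels = np.concatenate([np.ones(100), -np.ones(100)]).astype(int)
        idx = evaluate.downsample_prevalence(labels, 0.5, seed=1)
        assert idx.size == 200

    def test_different_seeds_same_counts_different_subsets(self):
        labels = np.concatenate([np.ones(500), -np.ones(500)]).astype(int)
        i1 = evaluate.downsample_prevalence(labels, 0.2, seed=1)
        i2 = evaluate.downsample_prevalence(labels, 0.2, seed=2)
        assert i1.size == i2.size
        assert not np.array_equal(i1, i2)

    def test_unreachable_prevalence_rejected(self):
        labels = np.concatenate([np.ones(10), -np.ones(90)]).astype(int)
        with pytest.raises(ValueError, match="exceeds"):
            evaluate.downsample_prevalence(labels, 0.5)


class TestPrevalenceEvaluation:
    @pytest.fixture(scope="class")
    def scored(self):
        rng = np.random.default_rng(8)
        n = 4000
        labels = np.where(rng.random(n) < 0.4, 1, -1)
        scores = rng.normal(size=n) + 1.6 * (labels == 1)
        return scores, labels

    def test_perfect_separator_has_unit_ppv(self):
        labels = np.concatenate([np.ones(200), -np.ones(300)]).astype(int)
        scores = np.concatenate([np.ones(200), np.zeros(300)])
        res = evaluate.prevalence_evaluation(
            scores, labels, (0.1,), replicates=5, seed=0,
            grid=np.array([0.5]),
        )
        assert res[0.1].ppv[0] == pytest.approx(1.0)

    def test_sens_spec_invariant_across_prevalence(self, scored):
        scores, labels = scored
        res = evaluate.prevalence_evaluation(
            scores, labels, (0.05, 0.2), replicates=20, seed=3
        )
        mid = slice(30, 70)  # central cutoffs where both classes are split
        assert np.allclose(
            res[0.05].sensitivity[mid], res[0.2].sensitivity[mid], atol=0.03
        )
        assert np.allclose(
            res[0.05].specificity[mid], res[0.2].specificity[mid], atol=0.03
        )

    def test_replicate_mean_ppv_matches_formula(self, scored):
        scores, labels = scored
        res = evaluate.prevalence_evaluation(
            scores, labels, (0.1,), replicates=30, seed=5
        )
        pe = res[0.1]
        mid = slice(30, 70)
        expected = [
            evaluate.ppv_npv(s, p, 0.1)[0]
            for s, p in zip(pe.sensitivity[mid], pe.specificity[mid])
        ]
        assert np.allclose(pe.ppv[mid], expected, atol=0.03)

    def test_npv_floor_when_nobody_positive(self, scored):
        scores, labels = scored
        grid = np.array([scores.max() + 1.0])  # nobody called positive
        res = evaluate.prevalence_evaluation(
            scores, labels, (0.1,), replicates=5, seed=2, grid=grid
        )
        n_controls = (labels == -1).sum()
        n_cases = int(np.floor(n_controls * 0.1 / 0.9))
        realized = n_cases / (n_cases + n_controls)
        assert res[0.1].npv[0] == pytest.approx(1.0 - realized, abs=1e-12)


class TestScreeningTable:
    def test_random_scores_ppv_near_prevalence(self):
        rng = np.random.default_rng(4)
        n = 6000
        labels = np.where(rng.random(n) < 0.4, 1, -1)
        scores = rng.normal(size=n)  # uninformative
        table = evaluate.screening_table(
            scores, labels, (0.1,), cutoffs=(0.1, 0.3), replicates=30, seed=0
        )
        realized = np.floor((labels == -1).sum() * 0.1 / 0.9)
        realized /= realized + (labels == -1).sum()
        for _, row in table.iterrows():
            assert row["ppv"] == pytest.approx(realized, abs=0.03)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(9)
        labels = np.where(rng.random(2000) < 0.4, 1, -1)
        scores = rng.normal(size=2000) + (labels == 1)
        t1 = evaluate.screening_table(scores, labels, (0.1,), replicates=5, seed=7)
        t2 = evaluate.screening_table(scores, labels, (0.1,), replicates=5, seed=7)
        assert t1.equals(t2)

    def test_perfect_classifier_table(self):
        labels = np.concatenate([np.ones(300), -np.ones(700)]).astype(int)
        scores = labels.astype(float)
        table = evaluate.screening_table(
            scores, labels, (0.2,), cutoffs=(0.2,), replicates=3, seed=0
        )
        row = table.iloc[0]
        assert row["ppv"] > 0.95 and row["npv"] > 0.95


class TestStratumRiskScore:
    def test_strata_identical_to_labels_perfect(self):
        labels = np.resize([1, -1], 200)
        strata = labels.copy()
        idx = np.arange(200)
        s = evaluate.stratum_risk_score(strata, labels, idx[:100], idx[100:])
        _, auc = evaluate.roc_auc(s, labels[idx[100:]])
        assert auc == 1.0

    def test_single_stratum_is_chance(self):
        labels = np.resize([1, -1], 100)
        strata = np.zeros(100, dtype=int)
        idx = np.arange(100)
        s = evaluate.stratum_risk_score(strata, labels, idx[:50], idx[50:])
        _, auc = evaluate.roc_auc(s, labels[idx[50:]])
        assert auc == 0.5

    def test_unseen_stratum_gets_pooled_odds_with_warning(self):
        labels = np.resize([1, -1], 100)
        strata = np.zeros(100, dtype=int)
        strata[75] = 9  # appears only in the test split
        idx = np.arange(100)
        with pytest.warns(UserWarning, match="unseen"):
            s = evaluate.stratum_risk_score(strata, labels, idx[:50], idx[50:])
        assert np.isfinite(s).all()
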