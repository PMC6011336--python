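"""LDA fitting, panel evaluation, adaptive search, voting, ROC."""

import numpy as np
import pandas as pd
import pytest

from epimethyl.datamodel import CpGSite, Group, MethylationMatrix, Subject, ValidationError
from epimethyl.ensemble import (
    CpGSetModel,
    LDAModel,
    ReplicateEval,
    compute_metrics,
    evaluate_model,
    fit_lda,
    models_from_json,
    models_to_json,
    passes_gates,
    roc_from_votes,
    search_models,
    theoretical_roc,
    vote_classify,
)
from epimethyl.simulate import SimulationConfig, generate_cohort


def _matrix(score_rows, groups, chrom="chr1"):
    sites = [CpGSite(chrom, 10 * (i + 1)) for i in range(len(score_rows))]
    subjects = [Subject(f"s{j}", g) for j, g in enumerate(groups)]
    return MethylationMatrix(sites, subjects, np.asarray(score_rows, dtype=float))


# --------------------------------------------------------------- fit_lda
class TestFitLDA:
    def test_one_site_midpoint_maps_to_center(self):
        x = np.array([[10.0], [12.0], [30.0], [32.0]])
        y = np.array([False, False, True, True])
        lda = fit_lda(x, y, ridge_lambda=0.0)
        assert lda.score(np.array([[21.0]]))[0] == pytest.approx(5.0)
        assert lda.score(np.array([[11.0]]))[0] == pytest.approx(4.0)
        assert lda.score(np.array([[31.0]]))[0] == pytest.approx(6.0)

    def test_class_means_map_to_four_and_six(self, rng):
        x = rng.normal(50, 5, size=(16, 10))
        x[8:, :3] += 15
        y = np.repeat([False, True], 8)
        lda = fit_lda(x, y)
        scores = lda.score(x)
        assert scores[:8].mean() == pytest.approx(4.0, abs=1e-9)
        assert scores[8:].mean() == pytest.approx(6.0, abs=1e-9)

    def test_one_class_training_rejected(self, rng):
        with pytest.raises(ValidationError):
            fit_lda(rng.normal(size=(4, 2)), np.array([True] * 4))

    def test_zero_within_class_scatter_handled(self):
        x = np.array([[10.0, 1.0], [10.0, 1.0], [30.0, 1.0], [30.0, 1.0]])
        y = np.array([False, False, True, True])
        lda = fit_lda(x, y)
        assert not lda.degenerate
        assert (lda.score(x)[2:] > 5).all()

    def test_matches_bayes_rule_on_equal_covariance_toy(self, rng):
        """LDA predictions equal the Bayes rule that compares the two
        fitted equal-covariance Gaussian densities directly."""
        from scipy.stats import multivariate_normal

        mu0, mu1 = np.array([40.0, 60.0]), np.array([55.0, 70.0])
        cov = np.array([[30.0, 8.0], [8.0, 20.0]])
        x0 = rng.multivariate_normal(mu0, cov, size=60)
        x1 = rng.multivariate_normal(mu1, cov, size=60)
        x = np.vstack([x0, x1])
        y = np.repeat([False, True], 60)
        lda = fit_lda(x, y, ridge_lambda=0.0)

        m0, m1 = x0.mean(axis=0), x1.mean(axis=0)
        pooled = (
            (x0 - m0).T @ (x0 - m0) + (x1 - m1).T @ (x1 - m1)
        ) / (len(x) - 2)
        test = rng.multivariate_normal((mu0 + mu1) / 2, 4 * cov, size=200)
        bayes = multivariate_normal(m1, pooled).logpdf(test) > multivariate_normal(
            m0, pooled
        ).logpdf(test)
        np.testing.assert_array_equal(lda.predict_cp(test), bayes)

    def test_label_swap_mirrors_scores_about_center(self, rng):
        x = rng.normal(50, 5, size=(16, 6))
        x[8:, 0] += 12
        y = np.repeat([False, True], 8)
        test = rng.normal(50, 8, size=(9, 6))
        s = fit_lda(x, y).score(test)
        s_swapped = fit_lda(x, ~y).score(test)
        np.testing.assert_allclose(s + s_swapped, 10.0, atol=1e-9)


# ----------------------------------------------------------- evaluation
class TestEvaluateModel:
    def test_perfect_separation_scores_good(self):
        cfg = SimulationConfig(
            n_sites=60, n_differential=20, effect_size=40, subject_noise_sd=1, seed=0
        )
        c = generate_cohort(cfg)
        panel = tuple(list(c.truth)[:15])
        model = evaluate_model(panel, c.matrix, np.random.default_rng(0))
        assert model.sensitivity == 1.0 and model.specificity == 1.0
        assert model.is_good

    def test_permuted_labels_never_good(self, rng):
        cfg = SimulationConfig(
            n_sites=60, n_differential=20, effect_size=40, subject_noise_sd=1, seed=0
        )
        c = generate_cohort(cfg)
        perm = rng.permutation(c.matrix.n_subjects)
        shuffled = MethylationMatrix(
            c.matrix.sites,
            [
                Subject(s.subject_id, c.matrix.subjects[p].group)
                for s, p in zip(c.matrix.subjects, perm)
            ],
            c.matrix.scores,
        )
        panel = tuple(list(c.truth)[:15])
        for seed in range(5):
            model = evaluate_model(panel, shuffled, np.random.default_rng(seed))
            assert not model.is_good

    def test_missing_site_rejected(self, small_cohort):
        with pytest.raises(ValidationError, match="absent"):
            evaluate_model(("chrX:1",), small_cohort.matrix, np.random.default_rng(0))

    def test_gates_are_strict_inequalities(self):
        assert not passes_gates(0.98, 0.95)
        assert not passes_gates(0.99, 0.90)
        assert passes_gates(0.981, 0.901)

    def test_replicates_record_train_splits_and_confusions(self, small_cohort):
        panel = tuple(list(small_cohort.truth)[:16])
        model = evaluate_model(panel, small_cohort.matrix, np.random.default_rng(1))
        assert len(model.replicates) == 20
        pooled = np.array([[r.tp, r.fp, r.tn, r.fn] for r in model.replicates]).sum(axis=0)
        tp, fp, tn, fn = pooled
        assert model.sensitivity == pytest.approx(tp / (tp + fn))
        assert model.specificity == pytest.approx(tn / (tn + fp))
        for r in model.replicates:
            assert len(r.train_subject_ids) == 16
            assert r.tp + r.fp + r.tn + r.fn == 16  # validation = remaining 8+8


# --------------------------------------------------------------- search
class TestSearch:
    def test_deterministic_given_seed(self, small_cohort):
        pool = small_cohort.matrix.site_ids[:60]
        a, _ = search_models(pool, small_cohort.matrix, budget=30, seed=9, max_good=5)
        b, _ = search_models(pool, small_cohort.matrix, budget=30, seed=9, max_good=5)
        assert [m.site_ids for m in a] == [m.site_ids for m in b]
        assert [
            [r.train_subject_ids for r in m.replicates] for m in a
        ] == [[r.train_subject_ids for r in m.replicates] for m in b]

    def test_no_good_models_returns_empty_list(self, null_cohort):
        pool = null_cohort.matrix.site_ids[:50]
        good, state = search_models(pool, null_cohort.matrix, budget=20, seed=0)
        assert good == [] and state.n_good == 0 and state.evaluations == 20

    def test_bad_budget_rejected(self, small_cohort):
        with pytest.raises(ValidationError):
            search_models(small_cohort.matrix.site_ids[:50], small_cohort.matrix,
                          budget=0, seed=0)

    def test_panel_sizes_within_range(self, small_cohort):
        pool = small_cohort.matrix.site_ids[:60]
        good, _ = search_models(pool, small_cohort.matrix, budget=40, seed=2,
                                panel_range=(15, 40), max_good=10)
        for m in good:
            assert 15 <= len(m.site_ids) <= 40
            assert len(set(m.site_ids)) == len(m.site_ids)

    def test_good_models_pass_gate_replay(self, small_cohort):
        """Re-derive pooled rates from the stored replicate confusions:
        no retained model may sit at or below the gates."""
        pool = small_cohort.matrix.site_ids[:60]
        good, _ = search_models(pool, small_cohort.matrix, budget=40, seed=2, max_good=10)
        assert good
        for m in good:
            tp = sum(r.tp for r in m.replicates)
            fn = sum(r.fn for r in m.replicates)
            tn = sum(r.tn for r in m.replicates)
            fp = sum(r.fp for r in m.replicates)
            assert tp / (tp + fn) > 0.98
            assert tn / (tn + fp) > 0.90


# --------------------------------------------------------------- voting
def _fixed_vote_model(n_up, n_down, n_abstain=0):
    """A model whose replicate LDAs deterministically vote up/down on a
    single-site matrix with score 60."""
    reps = []
    for kind in ["up"] * n_up + ["down"] * n_down + ["abstain"] * n_abstain:
        if kind == "abstain":
            lda = LDAModel(("chr1:10",), np.array([1.0]), 0.0, 0.0, degenerate=True)
        elif kind == "up":
            lda = LDAModel(("chr1:10",), np.array([1.0]), 40.0, 60.0)  # 60 -> 6
        else:
            lda = LDAModel(("chr1:10",), np.array([-1.0]), -60.0, -40.0)  # 60 -> 4
        reps.append(ReplicateEval(("t",) * 16, 0, 0, 0, 0, lda))
    return CpGSetModel(("chr1:10",), reps, 1.0, 1.0, True)


def _blinded_single_site(n_subjects=3):
    return _matrix([[60.0] * n_subjects], [Group.UNKNOWN] * n_subjects)


class TestVoteClassify:
    def test_majority_rule_twelve_of_twenty_votes_cp(self):
        votes = vote_classify([_fixed_vote_model(12, 8)], _blinded_single_site())
        assert (votes["predicted"] == "CP").all()
        assert (votes["votes_total"] == 20).all()
        np.testing.assert_allclose(votes["vote_fraction"], 0.6)

    def test_all_scores_at_center_flagged_undefined(self):
        votes = vote_classify([_fixed_vote_model(0, 0, 20)], _blinded_single_site())
        assert (votes["abstentions"] == 20).all()
        assert votes["tie_flag"].all()
        assert (votes["predicted"] == "control").all()  # conservative default

    def test_votes_total_always_replicates_times_models(self):
        models = [_fixed_vote_model(12, 8), _fixed_vote_model(3, 12, 5)]
        votes = vote_classify(models, _blinded_single_site())
        assert (votes["votes_total"] == 40).all()
        assert (votes["votes_cp"] + votes["votes_control"] + votes["abstentions"] == 40).all()

    def test_tie_vote_classified_control_with_flag(self):
        votes = vote_classify([_fixed_vote_model(10, 10)], _blinded_single_site())
        assert votes["tie_flag"].all()
        assert (votes["predicted"] == "control").all()

    def test_empty_model_list_rejected(self):
        with pytest.raises(ValidationError):
            vote_classify([], _blinded_single_site())

    def test_replay_and_refit_agree_on_training_cohort(self, small_cohort):
        panel = tuple(list(small_cohort.truth)[:16])
        model = evaluate_model(panel, small_cohort.matrix, np.random.default_rng(3))
        blinded = small_cohort.matrix
        a = vote_classify([model], blinded, mode="replay")
        b = vote_classify([model], blinded, mode="refit", training_matrix=small_cohort.matrix)
        pd.testing.assert_frame_equal(a, b)

    def test_model_store_roundtrip_preserves_votes(self, small_cohort, tmp_path):
        panel = tuple(list(small_cohort.truth)[:16])
        model = evaluate_model(panel, small_cohort.matrix, np.random.default_rng(3))
        path = tmp_path / "models.json"
        models_to_json([model], path)
        back = models_from_json(path)
        a = vote_classify([model], small_cohort.matrix)
        b = vote_classify(back, small_cohort.matrix)
        pd.testing.assert_frame_equal(a, b)


# -------------------------------------------------------------- metrics
class TestMetrics:
    def test_blinded_cohort_worked_example(self):
        pred = ["CP"] * 9 + ["control"] * 2
        truth = ["CP"] * 6 + ["control"] * 3 + ["control"] * 2
        cm = compute_metrics(np.array(pred), np.array(truth))
        assert (cm.tp, cm.fp, cm.tn, cm.fn) == (6, 3, 2, 0)
        assert cm.as_percent() == {
            "sensitivity": 100,
            "specificity": 40,
            "accuracy": 73,
            "ppv": 67,
            "npv": 100,
        }

    def test_all_correct_gives_perfect_rates(self):
        pred = truth = np.array(["CP", "CP", "control"])
        cm = compute_metrics(pred, truth)
        assert cm.accuracy == 1.0 and cm.sensitivity == 1.0 and cm.specificity == 1.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            compute_metrics(np.array([]), np.array([]))

    def test_label_swap_exchanges_sensitivity_and_specificity(self, rng):
        pred = np.where(rng.random(30) < 0.5, "CP", "control")
        truth = np.where(rng.random(30) < 0.5, "CP", "control")
        cm = compute_metrics(pred, truth)
        sw = compute_metrics(pred, truth, positive="control")
        assert cm.sensitivity == pytest.approx(sw.specificity)
        assert cm.specificity == pytest.approx(sw.sensitivity)


# ------------------------------------------------------------------ ROC
class TestROC:
    def test_perfect_separation_gives_auc_one(self):
        frac = np.array([0.9, 0.8, 0.7, 0.2, 0.1])
        truth = np.array(["CP", "CP", "CP", "control", "control"])
        roc = roc_from_votes(frac, truth)
        assert roc.auc == 1.0
        assert roc.fpr[0] == 0.0 and roc.tpr[-1] == 1.0
        assert (np.diff(roc.fpr) >= 0).all() and (np.diff(roc.tpr) >= 0).all()

    def test_auc_equals_mann_whitney_statistic(self, rng):
        from scipy.stats import mannwhitneyu

        for _ in range(10):
            n1, n0 = int(rng.integers(5, 30)), int(rng.integers(5, 30))
            # discrete fractions force ties across groups
            f1 = rng.integers(0, 10, n1) / 10
            f0 = rng.integers(0, 10, n0) / 10
            frac = np.concatenate([f1, f0])
            truth = np.array(["CP"] * n1 + ["control"] * n0)
            roc = roc_from_votes(frac, truth)
            u = mannwhitneyu(f1, f0).statistic
            assert roc.auc == pytest.approx(u / (n1 * n0), abs=1e-12)

    def test_single_class_truth_rejected(self):
        with pytest.raises(ValidationError):
            roc_from_votes(np.array([0.1, 0.9]), np.array(["CP", "CP"]))

    def test_theoretical_envelope_saturates_on_separating_models(self, small_cohort):
        panel = tuple(list(small_cohort.truth)[:16])
        model = evaluate_model(panel, small_cohort.matrix, np.random.default_rng(5))
        roc = theoretical_roc([model], small_cohort.matrix, n_bootstrap=20, seed=0)
        assert roc.auc == pytest.approx(1.0)

    def test_theoretical_roc_requires_bootstrap(self, small_cohort):
        panel = tuple(list(small_cohort.truth)[:16])
        model = evaluate_model(panel, small_cohort.matrix, np.random.default_rng(5))
        with pytest.raises(ValidationError):
            theoretical_roc([model], small_cohort.matrix, n_bootstrap=0)
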