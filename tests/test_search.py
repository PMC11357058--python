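"""Metrics, splits, learning curves and the penalised search."""

import math

import numpy as np
import pytest
from sklearn.linear_model import LinearRegression

from dessol.search import (
    FAMILY_REGISTRY,
    GridSampler,
    LearningCurve,
    RandomSampler,
    TPESampler,
    compute_metrics,
    custom_loss,
    custom_loss_terms,
    learning_curve_analysis,
    rank_models,
    ranking_report,
    split_train_test,
    tune,
)

NOISE_FLOOR = lambda s: s * math.sqrt(2.0 / math.pi)


def naive_metrics(y_true, y_pred):
    """Independent re-implementation used as the metric oracle."""
    e = [p - t for t, p in zip(y_true, y_pred)]
    n = len(e)
    mae = sum(abs(v) for v in e) / n
    rmsd = math.sqrt(sum(v * v for v in e) / n)
    mape = 100.0 * sum(abs(v / t) for v, t in zip(e, y_true)) / n
    sst = sum((t - sum(y_true) / n) ** 2 for t in y_true)
    r2 = 1.0 - sum(v * v for v in e) / sst if sst else None
    return mae, rmsd, mape, r2


class TestComputeMetrics:
    def test_perfect_prediction(self):
        m = compute_metrics([-2.0, -3.0, -4.0], [-2.0, -3.0, -4.0])
        assert (m.mae, m.rmsd, m.mape_percent) == (0.0, 0.0, 0.0)
        assert m.r2 == 1.0

    def test_hand_arithmetic(self):
        m = compute_metrics([-2.0, -4.0], [-2.1, -3.9])
        assert m.mae == pytest.approx(0.1, abs=1e-12)
        assert m.rmsd == pytest.approx(0.1, abs=1e-12)
        assert m.mape_percent == pytest.approx(3.75, abs=1e-12)

    def test_constant_predictor_r2_zero(self):
        y = np.array([-1.0, -2.0, -3.0])
        m = compute_metrics(y, np.full(3, y.mean()))
        assert m.r2 == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_truth_r2_missing(self):
        m = compute_metrics([-2.0, -2.0], [-2.1, -1.9])
        assert m.r2 is None

    def test_matches_naive_oracle_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(2, 40))
            yt = rng.normal(-3, 1, n)
            yp = yt + rng.normal(0, 0.2, n)
            m = compute_metrics(yt, yp)
            mae, rmsd, mape, r2 = naive_metrics(yt, yp)
            assert m.mae == pytest.approx(mae, abs=1e-12)
            assert m.rmsd == pytest.approx(rmsd, abs=1e-12)
            assert m.mape_percent == pytest.approx(mape, abs=1e-10)
            assert m.r2 == pytest.approx(r2, abs=1e-12)


class TestSplit:
    def test_two_thirds_of_corpus(self, corpus):
        # positional ids: record_ids of deliberate duplicate
        # measurements coincide by design
        ids = list(range(len(corpus)))
        tags = [r.class_tag for r in corpus]
        train, test = split_train_test(ids, tags, 2.0 / 3.0, seed=0)
        assert len(train) + len(test) == 344
        # per-stratum nearest rounding of 2/3: 69 + 30 + 131
        assert len(train) in (229, 230)
        assert set(train).isdisjoint(test)

    def test_every_class_in_both_partitions(self, corpus):
        tags = {r.record_id: r.class_tag for r in corpus}
        train, test = split_train_test(
            list(tags), list(tags.values()), 2.0 / 3.0, seed=1
        )
        assert {tags[i] for i in train} == {"neat", "binary", "DES"}
        assert {tags[i] for i in test} == {"neat", "binary", "DES"}

    def test_same_seed_identical_partition(self, corpus):
        ids = [r.record_id for r in corpus]
        tags = [r.class_tag for r in corpus]
        a = split_train_test(ids, tags, seed=7)
        b = split_train_test(ids, tags, seed=7)
        assert a == b

    def test_singleton_class_goes_to_training(self, caplog):
        train, test = split_train_test(
            ["a", "b", "c"], ["neat", "neat", "DES"], 0.5, seed=0
        )
        assert "c" in train

    def test_tiny_stratum_never_empties_test(self):
        train, test = split_train_test(
            ["a", "b"], ["neat", "neat"], 0.9, seed=0
        )
        assert len(train) == 1 and len(test) == 1


class TestLearningCurve:
    def test_noise_free_linear_target_reaches_zero(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(120, 4))
        y = X @ np.array([1.0, -2.0, 0.5, 3.0])
        c = learning_curve_analysis(LinearRegression(), X, y,
                                    fractions=(0.5, 1.0), k_folds=10, seed=0)
        assert max(c.cv_mae) < 1e-10

    def test_cv_error_approaches_analytic_noise_floor(self):
        # mean |N(0, s)| = s * sqrt(2/pi)
        rng = np.random.default_rng(2)
        X = rng.normal(size=(400, 5))
        y = X @ rng.normal(size=5) + rng.normal(0, 0.1, 400)
        c = learning_curve_analysis(LinearRegression(), X, y,
                                    fractions=(0.5, 1.0), k_folds=10, seed=0)
        assert c.cv_mae[-1] == pytest.approx(NOISE_FLOOR(0.1), rel=0.10)

    def test_train_error_below_cv_error_for_interpolating_learner(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(200, 8))
        y = X @ rng.normal(size=8) + rng.normal(0, 0.2, 200)
        c = learning_curve_analysis(LinearRegression(), X, y,
                                    fractions=(0.5, 1.0), k_folds=10, seed=0)
        assert all(t <= v for t, v in zip(c.train_mae, c.cv_mae))

    def test_too_small_fraction_names_the_fraction(self):
        X = np.zeros((30, 2))
        y = np.zeros(30)
        with pytest.raises(ValueError, match="0.1"):
            learning_curve_analysis(LinearRegression(), X, y,
                                    fractions=(0.1,), k_folds=10)

    def test_curve_invariants(self):
        with pytest.raises(ValueError, match="increasing"):
            LearningCurve((0.5, 0.5), (0.1, 0.1), (0.1, 0.1))


class TestCustomLoss:
    def test_perfect_model_zero_loss(self):
        c = LearningCurve((0.5, 1.0), (0.0, 0.0), (0.0, 0.0))
        assert custom_loss(c) == 0.0

    def test_flat_curve_no_penalty(self):
        c = LearningCurve((0.5, 1.0), (0.2, 0.2), (0.2, 0.2))
        assert custom_loss(c) == pytest.approx(0.2)

    def test_hand_arithmetic(self):
        # cv(1.0)=0.2, train(1.0)=0.05, cv(0.5)=0.25
        c = LearningCurve((0.5, 1.0), (0.1, 0.05), (0.25, 0.2))
        assert custom_loss(c) == pytest.approx(0.2 + 0.15 + 0.0)
        terms = custom_loss_terms(c)
        assert terms["gap_penalty"] == pytest.approx(0.15)
        assert terms["slope_penalty"] == 0.0

    def test_loss_never_below_cv_accuracy_term(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            tr = rng.uniform(0, 0.5, 2)
            cv = rng.uniform(0, 0.5, 2)
            c = LearningCurve((0.5, 1.0), tuple(tr), tuple(cv))
            assert custom_loss(c) >= cv[-1] - 1e-15


def _linear_problem(n=150, p=5, sigma=0.1, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    y = X @ rng.normal(size=p) + rng.normal(0, sigma, n)
    return X, y


class TestTune:
    def test_single_trial_returned(self):
        X, y = _linear_problem()
        r = tune("ridge", X, y, n_trials=1, seed=0)
        assert r.n_trials == 1 and len(r.trial_losses) == 1
        assert r.score == r.trial_losses[0]

    def test_determinism_same_seed(self):
        X, y = _linear_problem()
        a = tune("ridge", X, y, n_trials=5, seed=3)
        b = tune("ridge", X, y, n_trials=5, seed=3)
        assert a.trial_losses == b.trial_losses
        assert a.best_params == b.best_params

    def test_ridge_reaches_noise_floor(self):
        X, y = _linear_problem(n=400, sigma=0.1)
        r = tune("ridge", X, y, n_trials=15, seed=0)
        assert r.score <= 1.10 * NOISE_FLOOR(0.1)

    def test_exhaustive_grid_samplers_agree(self):
        from dessol.search import RegressorSpec, _scaled
        from sklearn.linear_model import Ridge

        spec = RegressorSpec(
            "ridge-grid",
            {"alpha": ("choice", (0.001, 0.1, 10.0))},
            lambda p: _scaled(Ridge(**p)),
        )
        X, y = _linear_problem()
        a = tune(spec, X, y, n_trials=3, sampler=GridSampler(), seed=0)
        b = tune(spec, X, y, n_trials=3, sampler=GridSampler(), seed=0)
        assert a.best_params == b.best_params

    def test_failed_trials_scored_infinite(self):
        from dessol.search import RegressorSpec

        calls = {"n": 0}

        def broken_builder(p):
            raise RuntimeError("boom")

        spec = RegressorSpec("broken", {"a": ("uniform", 0, 1)},
                             broken_builder)
        X, y = _linear_problem(n=60)
        with pytest.raises(RuntimeError, match="every trial"):
            tune(spec, X, y, n_trials=3, seed=0)

    def test_tpe_sampler_improves_or_matches_random_on_average(self):
        # sanity: TPE-style proposals stay inside the space and run
        X, y = _linear_problem(n=100)
        r = tune("ridge", X, y, n_trials=12,
                 sampler=TPESampler(n_startup=4), seed=1)
        lo, hi = FAMILY_REGISTRY["ridge"].space["alpha"][1:3]
        assert lo <= r.best_params["alpha"] <= hi


class TestRanking:
    def test_sorted_by_independently_recomputed_scores(self):
        X, y = _linear_problem(n=120)
        results = [
            tune("ridge", X, y, n_trials=3, seed=s) for s in (0, 1, 2)
        ]
        ranked = rank_models(results)
        scores = [custom_loss(r.lca) for r in ranked]
        assert scores == sorted(scores)

    def test_singleton(self):
        X, y = _linear_problem(n=80)
        r = tune("ridge", X, y, n_trials=1, seed=0)
        assert rank_models([r]) == [r]

    def test_report_contains_rmsd_mape_pairs(self):
        X, y = _linear_problem(n=80)
        r = tune("ridge", X, y, n_trials=2, seed=0)
        rep = ranking_report([r])
        assert "RMSD" in rep and "MAPE%" in rep and "ridge" in rep


def test_registry_contains_the_five_mandatory_families():
    for fam in ("svr", "nu-svr", "hist-gradient-boosting",
                "gradient-boosting", "mlp"):
        assert fam in FAMILY_REGISTRY
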