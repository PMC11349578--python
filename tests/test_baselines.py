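"""Tests for the five comparison models."""

import math

import numpy as np
import pytest

from conceptboot.baselines import (
    GaussianProcessModel,
    GPConfig,
    LinearRegressionModel,
    MultinomialModel,
    RationalRules,
    RRConfig,
    SimilarityConfig,
    SimilarityModel,
    gp_predict,
    linreg_predict,
    rr_derivation_probability,
    rr_eval,
    rr_predict,
    rr_sample_posterior,
    similarity_predict,
    similarity_score,
)
from conceptboot.baselines import _split_to_bins
from conceptboot.curricula import N_RESPONSES, Trial


def tasks_from(*feats):
    return [Trial(*f) for f in feats]


class TestRationalRules:
    def test_derivation_probability_symmetry(self):
        # same production multiset -> exactly equal prior probability
        gt = ("sub", ("mult", "stripe", "segment"), "spot")
        alt = ("mult", "stripe", ("sub", "segment", "spot"))
        assert rr_derivation_probability(gt) == rr_derivation_probability(alt)

    def test_derivation_probability_values(self):
        # S->op (1/3); features cost 1/2*1/2*1/3, constants 1/2*1/2*1/4
        assert rr_derivation_probability(("add", "stripe", 0)) == pytest.approx(
            (1 / 3) * (1 / 12) * (1 / 16)
        )

    def test_sampling_matches_analytic_prior_within_3_se(self):
        from conceptboot.baselines import (
            _DepthExceeded,
            _rr_sample_S,
            rr_acceptance_probability,
        )

        rng = np.random.default_rng(3)
        counts = {}
        n = 0
        while n < 30000:
            try:
                expr = _rr_sample_S(rng, 1, 40)
            except _DepthExceeded:
                continue  # depth-cap rejection conditions the prior
            n += 1
            counts[expr] = counts.get(expr, 0) + 1
        p_accept = rr_acceptance_probability(40)
        for expr in (("add", "stripe", 0), ("mult", "segment", "spot")):
            p = rr_derivation_probability(expr) / p_accept
            c = counts.get(expr, 0)
            se = math.sqrt(p * (1 - p) / n)
            assert abs(c / n - p) <= 3 * se + 1e-9

    def test_acceptance_probability_matches_sampling(self):
        from conceptboot.baselines import (
            _DepthExceeded,
            _rr_sample_S,
            rr_acceptance_probability,
        )

        rng = np.random.default_rng(5)
        n, ok = 20000, 0
        for _ in range(n):
            try:
                _rr_sample_S(rng, 1, 40)
                ok += 1
            except _DepthExceeded:
                pass
        p = rr_acceptance_probability(40)
        se = math.sqrt(p * (1 - p) / n)
        assert abs(ok / n - p) <= 3 * se

    def test_posterior_survivors_match_rule(self):
        # R' = R + 1 with well-varied features: survivors reproduce the rule
        # on the whole learning feature range
        trials = [
            Trial(1, 2, 3, result=4),
            Trial(2, 1, 1, result=2),
            Trial(3, 3, 2, result=3),
            Trial(0, 3, 1, result=2),
            Trial(2, 0, 3, result=4),
        ]
        rng = np.random.default_rng(1)
        survivors, weights = rr_sample_posterior(trials, RRConfig(n_samples=20000), rng)
        assert len(survivors) > 0
        for expr in survivors:
            for s in range(4):
                for p in range(4):
                    for r in range(4):
                        assert rr_eval(expr, s, p, r) == r + 1, expr

    def test_contradictory_trials_empty_posterior_uniform_fallback(self):
        trials = [Trial(1, 1, 1, result=2), Trial(1, 1, 1, result=3)]
        rng = np.random.default_rng(2)
        survivors, weights = rr_sample_posterior(trials, RRConfig(n_samples=2000), rng)
        assert survivors == []
        preds = rr_predict(survivors, weights, tasks_from((1, 1, 1)))
        assert np.allclose(preds, 1.0 / N_RESPONSES)

    def test_estimator_order_insensitive(self):
        # RR sees the union of the evidence: construct and deconstruct orders
        # give identical posteriors (the mechanism behind missing order effects)
        trials = [(2, 0, 2, 4), (3, 0, 1, 3), (1, 0, 3, 3),
                  (2, 3, 3, 3), (3, 1, 2, 5), (1, 2, 2, 0)]
        X = np.array([t[:3] for t in trials]); y = np.array([t[3] for t in trials])
        rr1 = RationalRules(n_samples=5000, random_state=9).fit(X, y)
        Xr, yr = X[::-1], y[::-1]
        rr2 = RationalRules(n_samples=5000, random_state=9).fit(Xr, yr)
        Xt = np.array([[2, 2, 3], [0, 0, 3]])
        assert np.allclose(rr1.predict_proba(Xt), rr2.predict_proba(Xt))


class TestSimilarity:
    def test_identical_pair_scores_one(self):
        t = Trial(2, 1, 3, result=5)
        g = Trial(2, 1, 3)
        assert similarity_score(t, g, SimilarityConfig()) == 1.0

    def test_worked_example(self):
        # differences (1, 0, 1) with unit weights -> exp(-2)
        t = Trial(2, 1, 3, result=5)
        g = Trial(1, 1, 2)
        assert similarity_score(t, g, SimilarityConfig(1, 1, 1)) == pytest.approx(
            math.exp(-2)
        )

    def test_shared_result_gives_point_mass(self):
        trials = [Trial(1, 0, 1, result=4), Trial(3, 2, 2, result=4)]
        preds = similarity_predict(trials, tasks_from((0, 0, 3)), SimilarityConfig(2, 1, 3))
        assert preds[0, 4] == pytest.approx(1.0)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimilarityConfig(0, 0, 0)
        with pytest.raises(ValueError):
            SimilarityConfig(-1, 1, 1)

    def test_estimator_distribution(self):
        X = np.array([[2, 0, 2], [3, 0, 1]]); y = np.array([4, 3])
        preds = SimilarityModel().fit(X, y).predict_proba(np.array([[2, 0, 2]]))
        assert np.allclose(preds.sum(axis=1), 1.0)
        assert preds[0].argmax() == 4


class TestLinearRegression:
    def test_exact_linear_rule_interpolates(self):
        # R' = R + 2 with stripe fixed at 1: absorbed as a=2, c=1 (no intercept)
        trials = [Trial(1, 0, 1, result=3), Trial(1, 0, 2, result=4), Trial(1, 0, 3, result=5)]
        preds = linreg_predict(trials, tasks_from((1, 0, 4)))
        assert preds[0, 6] == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize(
        "yhat, expect",
        [
            (4.5, {4: 0.5, 5: 0.5}),
            (4.0, {4: 1.0}),
            (-0.3, {0: 1.0}),
            (16.7, {16: 1.0}),
            (2.25, {2: 0.75, 3: 0.25}),
        ],
    )
    def test_nearest_integer_split(self, yhat, expect):
        dist = _split_to_bins(yhat, "proximity")
        for k, v in expect.items():
            assert dist[k] == pytest.approx(v)
        assert dist.sum() == pytest.approx(1.0)

    def test_half_split_variant(self):
        dist = _split_to_bins(4.2, "half")
        assert dist[4] == pytest.approx(0.5) and dist[5] == pytest.approx(0.5)

    def test_degenerate_design_flagged(self):
        X = np.array([[1, 0, 1], [1, 0, 1], [1, 0, 1]]); y = np.array([2, 2, 2])
        model = LinearRegressionModel().fit(X, y)
        assert model.degenerate_
        assert np.allclose(model.predict_proba(np.array([[1, 0, 1]])).sum(axis=1), 1.0)


class TestMultinomial:
    def test_single_class_point_mass(self):
        X = np.array([[1, 0, 1], [2, 0, 2]]); y = np.array([4, 4])
        preds = MultinomialModel().fit(X, y).predict_proba(np.array([[3, 0, 3]]))
        assert preds[0, 4] == pytest.approx(1.0)

    def test_distribution_normalizes(self):
        X = np.array([[2, 0, 2], [3, 0, 1], [1, 0, 3], [2, 3, 3], [3, 1, 2], [1, 2, 2]])
        y = np.array([4, 3, 3, 3, 5, 0])
        preds = MultinomialModel().fit(X, y).predict_proba(np.array([[2, 2, 2], [0, 0, 1]]))
        assert np.allclose(preds.sum(axis=1), 1.0)
        assert np.all(preds >= 0)

    def test_strong_regularization_tracks_class_frequencies(self):
        # separable data + tiny C: probabilities stay finite, ordered by frequency
        X = np.array([[0, 0, 1], [0, 0, 2], [1, 0, 1], [1, 0, 2], [2, 0, 1], [3, 0, 2]])
        y = np.array([2, 2, 2, 2, 5, 5])
        preds = MultinomialModel(C=1e-4).fit(X, y).predict_proba(np.array([[1, 0, 1]]))
        assert np.isfinite(preds).all()
        assert preds[0, 2] > preds[0, 5] > 0


class TestGaussianProcess:
    def test_interpolation_mode_at_training_point(self):
        trials = [Trial(1, 0, 2, result=4), Trial(3, 0, 1, result=7)]
        preds = gp_predict(trials, tasks_from((1, 0, 2)), GPConfig(noise=1e-8))
        assert preds[0].argmax() == 4

    def test_bins_sum_to_one(self):
        trials = [Trial(2, 1, 3, result=3), Trial(1, 2, 2, result=0)]
        preds = gp_predict(trials, tasks_from((0, 0, 4), (4, 4, 4)))
        assert np.allclose(preds.sum(axis=1), 1.0)

    def test_predictive_matches_independent_gp_oracle(self):
        # independent dense-algebra GP + Gaussian binning reproduces gp_predict
        from scipy.stats import norm

        trials = [Trial(0, 0, 1, result=4), Trial(1, 2, 3, result=7)]
        task = (2, 1, 2)
        cfg = GPConfig(bandwidth=1.3, noise=1e-5)
        preds = gp_predict(trials, tasks_from(task), cfg)

        def kern(u, v):
            return sum(
                math.exp(-abs(a - b) / (2 * cfg.bandwidth)) for a, b in zip(u, v)
            )

        X = [t.features() for t in trials]
        y = np.array([t.result for t in trials], dtype=float)
        K = np.array([[kern(u, v) for v in X] for u in X]) + cfg.noise * np.eye(2)
        ks = np.array([kern(task, v) for v in X])
        mu = ks @ np.linalg.solve(K, y)
        var = 3.0 + cfg.noise - ks @ np.linalg.solve(K, ks)
        edges = np.arange(0.5, 16.5)
        cdf = norm.cdf(edges, loc=mu, scale=math.sqrt(var))
        expected = np.diff(np.concatenate(([0.0], cdf, [1.0])))
        assert np.allclose(preds[0], expected / expected.sum(), atol=1e-10)

    def test_gaussian_midpoint_splits_adjacent_bins_equally(self):
        # when the predictive mean sits on a half-integer, the two adjacent
        # bins receive identical mass (symmetric Gaussian integrals)
        trials = [Trial(0, 0, 2, result=9)]
        task = (0, 0, 2)
        # single training point, near-zero noise: mu = y * k**/prior == 9 * 3/3
        preds = gp_predict(trials, tasks_from(task), GPConfig(noise=1e-9))
        assert preds[0].argmax() == 9
        assert preds[0, 8] == pytest.approx(preds[0, 10], rel=1e-6)

    def test_product_kernel_variant(self):
        trials = [Trial(1, 0, 2, result=4)]
        preds = gp_predict(trials, tasks_from((1, 0, 2)), GPConfig(combination="product", noise=1e-8))
        assert preds[0].argmax() == 4

    def test_estimator_roundtrip(self):
        X = np.array([[2, 0, 2], [3, 0, 1]]); y = np.array([4, 3])
        preds = GaussianProcessModel().fit(X, y).predict_proba(np.array([[2, 0, 2]]))
        assert np.allclose(preds.sum(axis=1), 1.0)


class TestEveryBaselineOnEveryCurriculum:
    @pytest.mark.parametrize("model_name", ["rr", "similarity", "linreg", "multinom", "gp"])
    def test_valid_distributions_everywhere(self, model_name, all_curricula):
        from conceptboot.cli import predictions_for_curriculum

        overrides = {"n_samples": 2000} if model_name == "rr" else {}
        for name, cur in all_curricula.items():
            dists = predictions_for_curriculum(model_name, cur, seed=0, overrides=overrides)
            assert dists.shape == (2, 8, N_RESPONSES)
            assert np.all(dists >= 0)
            assert np.allclose(dists.sum(axis=-1), 1.0)
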