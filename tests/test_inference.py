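"""Tests for frames, Gibbs steps, learners and posterior predictions."""

import math

import numpy as np
import pytest

from conceptboot.adaptor_grammar import ConceptLibrary
from conceptboot.cl_core import (
    OBJ,
    chunk_programme,
    ground_truth_programme,
    programme_to_string,
    subprogrammes,
    well_typed,
)
from conceptboot.curricula import Trial, build_curriculum
from conceptboot.inference import (
    AdaptorGrammarLearner,
    AdaptorGrammarReprocessor,
    Frame,
    GibbsConfig,
    agr_predict,
    enumerate_frames,
    gibbs_step,
    likelihood,
    posterior_predictive,
    run_learner,
    sample_depth,
    unfold_frame,
)


class TestLikelihood:
    def test_ground_truth_explains_construct_phase(self, construct_curriculum):
        gt = ground_truth_programme()
        assert likelihood(gt, construct_curriculum.trials_through(1)) == 1

    def test_mismatch_scores_zero(self):
        chunk = chunk_programme()
        assert likelihood(chunk, [Trial(2, 1, 3, result=5)]) == 0

    def test_vacuous_on_empty_trials(self):
        assert likelihood(chunk_programme(), []) == 1

    def test_missing_result_is_an_error(self):
        with pytest.raises(ValueError):
            likelihood(chunk_programme(), [Trial(1, 1, 1)])


class TestDepthPrior:
    def test_zero_decay_is_uniform(self, rng):
        cfg = GibbsConfig(depth_decay=0.0)
        assert np.allclose(cfg.depth_probabilities(), [0.5, 0.5])

    def test_large_decay_prefers_depth_one(self, rng):
        cfg = GibbsConfig(depth_decay=50.0)
        draws = {sample_depth(cfg, rng) for _ in range(50)}
        assert draws == {1}

    def test_default_decay_closed_form(self):
        cfg = GibbsConfig(depth_decay=6.0)
        expected = math.exp(-6.0) / (math.exp(-6.0) + math.exp(-12.0))
        assert cfg.depth_probabilities()[0] == pytest.approx(expected)
        assert cfg.depth_probabilities()[0] == pytest.approx(1 / (1 + math.exp(-6.0)))


class TestFrames:
    def test_sixteen_equal_weight_frames_at_depth_one(self):
        frames = enumerate_frames(2, 1)
        assert len(frames) == 16
        assert all(w == pytest.approx(1 / 16) for _, w in frames)

    def test_depth_two_strictly_contains_depth_one(self):
        f1 = {f.key() for f, _ in enumerate_frames(2, 1)}
        f2 = {f.key() for f, _ in enumerate_frames(2, 2)}
        assert f1 < f2

    def test_frame_weights_normalize(self):
        assert sum(w for _, w in enumerate_frames(2, 2)) == pytest.approx(1.0)

    def test_unfoldings_type_check(self):
        lib = ConceptLibrary()
        lib.cache([chunk_programme()])
        for frame, _ in enumerate_frames(2, 1):
            for prog in unfold_frame(frame, lib):
                assert well_typed(prog, (OBJ, OBJ)), programme_to_string(prog)

    def test_cached_chunk_enables_ground_truth_unfolding(self):
        lib = ConceptLibrary()
        lib.cache([chunk_programme()])
        gt = programme_to_string(ground_truth_programme())
        hits = [
            prog
            for frame, _ in enumerate_frames(2, 1)
            for prog in unfold_frame(frame, lib)
            if programme_to_string(prog) == gt
        ]
        assert hits  # one depth-1 node over the cached chunk


class TestGibbs:
    def test_phase_one_caches_multiplicative_chunk(self, construct_curriculum, rng):
        cfg = GibbsConfig()
        hits = 0
        for _ in range(30):
            lib, found = gibbs_step(
                ConceptLibrary(), construct_curriculum.phases[0], cfg, rng
            )
            if not found:
                continue
            for e in lib.entries():
                if e.context == (OBJ, OBJ):
                    vals = [
                        likelihood(e.programme, construct_curriculum.phases[0])
                    ]
                    if all(vals):
                        hits += 1
                        break
        assert hits > 0

    def test_contradictory_trials_find_nothing(self, rng):
        trials = [Trial(1, 1, 1, result=2), Trial(1, 1, 1, result=3)]
        lib = ConceptLibrary()
        out, found = gibbs_step(lib, trials, GibbsConfig(), rng)
        assert not found
        assert out is lib  # untouched

    def test_n_cache_bounds_root_growth(self, construct_curriculum, rng):
        cfg = GibbsConfig()
        for _ in range(10):
            before = ConceptLibrary()
            after, found = gibbs_step(before, construct_curriculum.phases[0], cfg, rng)
            if not found:
                continue
            grown = [
                e.programme
                for e in after.entries()
                if after.count_of(e.programme, e.context)
                > before.count_of(e.programme, e.context)
            ]
            keys = {programme_to_string(p) for p in grown}
            roots = [
                p
                for p in grown
                if not any(
                    programme_to_string(p) in
                    {programme_to_string(s) for s in subprogrammes(q)}
                    for q in grown
                    if programme_to_string(q) != programme_to_string(p)
                )
            ]
            assert len(roots) <= cfg.n_cache
            assert keys  # something was cached

    def test_learner_stages_and_reproducibility(self, construct_curriculum):
        cfg = GibbsConfig(chain_length=2)
        a = run_learner(construct_curriculum, cfg, np.random.default_rng(7))
        b = run_learner(construct_curriculum, cfg, np.random.default_rng(7))
        assert len(a) == construct_curriculum.n_phases == 2
        assert [lib.state_key() for lib in a] == [lib.state_key() for lib in b]


class TestPredictions:
    def test_posterior_predictive_shape_and_normalization(self, construct_curriculum):
        cfg = GibbsConfig(n_learners=20, n_predictive_draws=300, seed=5)
        preds = posterior_predictive(construct_curriculum, cfg)
        assert preds.shape == (2, 8, 17)
        assert np.all(preds >= 0)
        assert np.allclose(preds.sum(axis=-1), 1.0)

    def test_degenerate_pool_is_point_mass(self, construct_curriculum, rng):
        from conceptboot.inference import draw_predictions
        from conceptboot.adaptor_grammar import GenerationBudget

        # library whose only task-typed entry is the ground truth itself
        import json

        gt = ground_truth_programme()
        payload = {
            "alpha0": 1e-9,
            "discount": 1e-9,
            "seed": None,
            "entries": [
                {
                    "programme": programme_to_string(gt),
                    "context": ["obj", "obj"],
                    "count": 200,
                }
            ],
        }
        lib = ConceptLibrary.from_json(json.dumps(payload))
        truths = construct_curriculum.truth_responses()
        preds = draw_predictions(
            [lib], construct_curriculum.generalization_tasks, 400, rng,
            GenerationBudget(2),
        )
        # overwhelming mass on the ground-truth answer for every task
        for i, t in enumerate(truths):
            assert preds[i, t] > 0.8

    def test_zero_feature_agent_concentrates_at_zero(self, rng):
        from conceptboot.inference import draw_predictions
        from conceptboot.adaptor_grammar import GenerationBudget

        lib = ConceptLibrary(alpha0=1e-9, discount=1e-9)
        for _ in range(200):
            lib.cache([chunk_programme()])
        task = Trial(0, 0, 3)
        preds = draw_predictions([lib], [task], 400, rng, GenerationBudget(2))
        assert preds[0, 0] > 0.8  # 0 * 3 = 0

    def test_agr_mixture(self):
        fwd = np.zeros((1, 17)); fwd[0, 4] = 1.0
        bwd = np.zeros((1, 17)); bwd[0, 6] = 1.0
        assert np.allclose(agr_predict(fwd, bwd, 1.0), fwd)
        assert np.allclose(agr_predict(fwd, bwd, 0.0), bwd)
        half = agr_predict(fwd, bwd, 0.5)
        assert half[0, 4] == pytest.approx(0.5) and half[0, 6] == pytest.approx(0.5)
        with pytest.raises(ValueError):
            agr_predict(fwd, bwd, 1.5)


class TestEstimators:
    def _xy(self, curriculum):
        trials = curriculum.trials_through(1)
        X = np.array([t.features() for t in trials])
        y = np.array([t.result for t in trials])
        phases = [np.arange(0, 3), np.arange(3, 6)]
        Xt = np.array([t.features() for t in curriculum.generalization_tasks])
        return X, y, phases, Xt

    def test_ag_estimator_fit_predict(self, construct_curriculum):
        X, y, phases, Xt = self._xy(construct_curriculum)
        ag = AdaptorGrammarLearner(n_learners=20, n_predictive_draws=300, random_state=0)
        probs = ag.fit(X, y, phases=phases).predict_proba(Xt)
        assert probs.shape == (8, 17)
        assert np.allclose(probs.sum(axis=1), 1.0)
        assert ag.n_stages_ == 2
        early = ag.predict_proba(Xt, stage=0)
        assert early.shape == (8, 17)

    def test_ag_estimator_is_reproducible_and_clonable(self, construct_curriculum):
        from sklearn.base import clone

        X, y, phases, Xt = self._xy(construct_curriculum)
        ag = AdaptorGrammarLearner(n_learners=10, n_predictive_draws=200, random_state=3)
        p1 = ag.fit(X, y, phases=phases).predict_proba(Xt)
        p2 = clone(ag).fit(X, y, phases=phases).predict_proba(Xt)
        assert np.array_equal(p1, p2)

    def test_agr_estimator_runs_both_directions(self, construct_curriculum):
        X, y, phases, Xt = self._xy(construct_curriculum)
        agr = AdaptorGrammarReprocessor(
            mix_weight=0.5, n_learners=10, n_predictive_draws=200, random_state=1
        )
        probs = agr.fit(X, y, phases=phases).predict_proba(Xt)
        assert np.allclose(probs.sum(axis=1), 1.0)
        # phase orders differ between the two passes
        fwd0 = agr.forward_.phase_trials_[0]
        bwd0 = agr.backward_.phase_trials_[0]
        assert fwd0 != bwd0
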