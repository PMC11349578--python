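"""Resource-bounded Gibbs inference over concept libraries.

Each Gibbs iteration models one bounded episode of hypothesis search:

1. draw a search depth ``d`` with prior ``P(d) ∝ exp(-b d)`` over
   ``{1, .., max_frame_depth}`` (larger ``b`` = stronger preference for
   shallow search);
2. enumerate the *frames* up to depth ``d`` — router skeletons with typed
   placeholders for heads and argument slots — weighted by their generation
   probability under the grammar (uniform router draws at every node),
   renormalized over the enumerated set;
3. sample frames without replacement by weight; *unfold* each sampled frame
   against the current library, filling every placeholder with each
   type-matching base term or cached library entry, producing the candidate
   set M;
4. score candidates with the deterministic 0/1 likelihood; on the first frame
   with a non-empty consistent subset M*, sample ``min(n_cache, |M*|)``
   programmes uniformly from M* and cache them (with all their subparts),
   then stop.  If every frame is exhausted the library is returned unchanged
   with a nothing-found flag.

A learner processes a curriculum in stages: ``h`` Gibbs steps on Phase I,
then ``h`` steps on Phases I+II together, continuing from the updated
library.  Population-level predictions pool many independent learners and
draw programmes from their libraries via the generative grammar; evaluating
the draws on a generalization task and clipping to the 0-16 response scale
yields a 17-bin posterior-predictive distribution.

The AG estimator follows the phase order as given; the AGR (reprocessing)
variant mixes forward (I then I+II) and backward (II then II+I) predictions
with a weight ``mix_weight``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .adaptor_grammar import (
    ConceptLibrary,
    GenerationBudget,
    GenerationError,
    _leaf_ok,
    _head_inputs,
    generate_programme,
)
from .base import ResponsePredictorMixin, trials_from_arrays, validate_features
from .cl_core import (
    INT,
    OBJ,
    PRIMITIVES,
    TYPE_VAR,
    Leaf,
    Node,
    Programme,
    SemType,
    all_routers,
    count_routers,
    evaluate_pair,
    programme_to_string,
    route_variables,
)
from .curricula import N_RESPONSES, Curriculum, Trial, clip_response

__all__ = [
    "GibbsConfig",
    "Frame",
    "likelihood",
    "sample_depth",
    "enumerate_frames",
    "unfold_frame",
    "gibbs_step",
    "run_learner",
    "population_libraries",
    "draw_predictions",
    "posterior_predictive",
    "agr_predict",
    "AdaptorGrammarLearner",
    "AdaptorGrammarReprocessor",
]

_TOP_TYPE = SemType((OBJ, OBJ, INT))


@dataclass(frozen=True)
class GibbsConfig:
    """Resource parameters of the bounded learner.

    depth_decay
        ``b`` in the search-depth prior ``P(d) ∝ exp(-b d)``; default 6.
    chain_length
        ``h``, Gibbs steps per curriculum stage; default 2.
    n_cache
        favoured concepts cached per successful step; default 3.
    max_frame_depth
        deepest enumerable frame; default 2.
    n_learners / n_predictive_draws
        population size and generative draws for posterior predictions
        (full-scale defaults 1,000 and 10,000).
    """

    depth_decay: float = 6.0
    chain_length: int = 2
    n_cache: int = 3
    max_frame_depth: int = 2
    n_learners: int = 1000
    n_predictive_draws: int = 10000
    alpha0: float = 1.0
    discount: float = 0.5
    consistency_filter: bool = False
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.depth_decay < 0:
            raise ValueError("depth_decay must be >= 0")
        for name in ("chain_length", "n_cache", "max_frame_depth", "n_learners",
                     "n_predictive_draws"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    def depth_probabilities(self) -> np.ndarray:
        d = np.arange(1, self.max_frame_depth + 1, dtype=float)
        w = np.exp(-self.depth_decay * d)
        return w / w.sum()


def sample_depth(config: GibbsConfig, rng: np.random.Generator) -> int:
    """Draw a search depth from P(d) ∝ exp(-b d) over {1..max_frame_depth}."""
    return int(rng.choice(np.arange(1, config.max_frame_depth + 1),
                          p=config.depth_probabilities()))


def likelihood(programme: Programme, trials: Sequence[Trial]) -> int:
    """Deterministic likelihood: 1 iff the programme reproduces every observed
    result exactly, else 0.  Vacuously 1 on an empty trial list."""
    for t in trials:
        if t.result is None:
            raise ValueError(f"trial {t} has no observed result")
        try:
            if evaluate_pair(programme, t.agent, t.recipient) != t.result:
                return 0
        except Exception:
            return 0
    return 1


# ---------------------------------------------------------------------------
# Frames
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Frame:
    """A router skeleton with implicit typed placeholders.

    ``left``/``right`` hold nested sub-frames in the first/last argument
    position of the (placeholder) head; ``None`` means that position is a
    plain placeholder slot filled from the library at unfolding time.
    """

    router: str
    left: Optional["Frame"] = None
    right: Optional["Frame"] = None

    @property
    def depth(self) -> int:
        sub = [f.depth for f in (self.left, self.right) if f is not None]
        return 1 + (max(sub) if sub else 0)

    def key(self) -> tuple:
        return (
            self.router,
            self.left.key() if self.left else None,
            self.right.key() if self.right else None,
        )


def _routed_counts(router: str) -> tuple[int, int]:
    nl = sum(1 for c in router if c in "CS")
    nr = sum(1 for c in router if c in "BS")
    return nl, nr


def enumerate_frames(n_variables: int, depth: int) -> list[tuple[Frame, float]]:
    """All frames up to ``depth`` with weights renormalized over the set.

    A frame's raw weight is the product over its nodes of the uniform router
    probability ``1/4**n`` for the ``n`` variables entering that node.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")

    def rec(n: int, d: int) -> list[tuple[Frame, float]]:
        out: list[tuple[Frame, float]] = []
        for r in all_routers(n):
            base = 1.0 / count_routers(n)
            out.append((Frame(r), base))
            if d >= 2:
                nl, nr = _routed_counts(r)
                lsubs = rec(nl, d - 1)
                rsubs = rec(nr, d - 1)
                for lf, lw in lsubs:
                    out.append((Frame(r, left=lf), base * lw))
                for rf, rw in rsubs:
                    out.append((Frame(r, right=rf), base * rw))
                for lf, lw in lsubs:
                    for rf, rw in rsubs:
                        out.append((Frame(r, left=lf, right=rf), base * lw * rw))
        return out

    frames = rec(n_variables, depth)
    total = sum(w for _, w in frames)
    return [(f, w / total) for f, w in frames]


def _node_heads(out: str):
    return [
        PRIMITIVES[name]
        for name in sorted(PRIMITIVES)
        if PRIMITIVES[name].arity >= 1
        and PRIMITIVES[name].signature.output in (out, TYPE_VAR)
    ]


def _slot_candidates(
    library: ConceptLibrary, context: tuple[str, ...], out: str
) -> list[Programme]:
    """Fillings for a placeholder slot: exactly-typed base terms and cached
    library entries of the required type."""
    cands: dict[str, Programme] = {}
    for name in sorted(PRIMITIVES):
        z = PRIMITIVES[name]
        if _leaf_ok(z, context, out):
            leaf = Leaf(z)
            cands[programme_to_string(leaf)] = leaf
    for e in library.matching(SemType(tuple(context) + (out,))):
        cands.setdefault(programme_to_string(e.programme), e.programme)
    return [cands[k] for k in sorted(cands)]


def unfold_frame(
    frame: Frame,
    library: ConceptLibrary,
    context: tuple[str, ...] = (OBJ, OBJ),
    out: str = INT,
) -> list[Programme]:
    """All well-typed programmes obtained by filling the frame's placeholders."""
    if len(frame.router) != len(context):
        return []
    left_ctx, right_ctx = route_variables(frame.router, context)
    left_ctx, right_ctx = tuple(left_ctx), tuple(right_ctx)
    results: dict[str, Programme] = {}
    for z in _node_heads(out):
        ins = _head_inputs(z, out)
        if z.arity == 1:
            if left_ctx or frame.left is not None:
                continue
            if frame.right is not None:
                args = unfold_frame(frame.right, library, right_ctx, ins[0])
            else:
                args = _slot_candidates(library, right_ctx, ins[0])
            for a in args:
                p = Node(frame.router, z, (a,))
                results[programme_to_string(p)] = p
        else:
            if frame.left is not None:
                lefts = unfold_frame(frame.left, library, left_ctx, ins[0])
            else:
                lefts = _slot_candidates(library, left_ctx, ins[0])
            if not lefts:
                continue
            if frame.right is not None:
                rights = unfold_frame(frame.right, library, right_ctx, ins[1])
            else:
                rights = _slot_candidates(library, right_ctx, ins[1])
            for a1 in lefts:
                for a2 in rights:
                    p = Node(frame.router, z, (a1, a2))
                    results[programme_to_string(p)] = p
    return [results[k] for k in sorted(results)]


# Memo of consistent unfoldings keyed by (frame, library membership, trials).
_CONSISTENT_CACHE: dict[tuple, tuple[Programme, ...]] = {}
_CACHE_LIMIT = 200_000


def _trials_key(trials: Sequence[Trial]) -> tuple:
    return tuple((t.stripes, t.spots, t.segments, t.result) for t in trials)


def _consistent_unfoldings(
    frame: Frame, library: ConceptLibrary, trials: Sequence[Trial]
) -> tuple[Programme, ...]:
    key = (frame.key(), library.membership_key(), _trials_key(trials))
    hit = _CONSISTENT_CACHE.get(key)
    if hit is not None:
        return hit
    consistent = tuple(
        p for p in unfold_frame(frame, library) if likelihood(p, trials)
    )
    if len(_CONSISTENT_CACHE) > _CACHE_LIMIT:
        _CONSISTENT_CACHE.clear()
    _CONSISTENT_CACHE[key] = consistent
    return consistent


def gibbs_step(
    library: ConceptLibrary,
    trials: Sequence[Trial],
    config: GibbsConfig,
    rng: np.random.Generator,
) -> tuple[ConceptLibrary, bool]:
    """One search-check-sample iteration; returns (library, found_flag).

    On success the returned library is an updated copy; on exhaustion the
    original library is returned unchanged with ``found_flag=False``.
    """
    depth = sample_depth(config, rng)
    frames = enumerate_frames(2, depth)
    weights = np.array([w for _, w in frames], dtype=float)
    order = list(range(len(frames)))
    while order:
        w = weights[order]
        idx = order[int(rng.choice(len(order), p=w / w.sum()))]
        order.remove(idx)
        consistent = _consistent_unfoldings(frames[idx][0], library, trials)
        if consistent:
            n_pick = min(config.n_cache, len(consistent))
            picks = rng.choice(len(consistent), size=n_pick, replace=False)
            new_lib = library.copy()
            new_lib.cache([consistent[int(i)] for i in picks])
            return new_lib, True
    return library, False


def run_learner(
    curriculum: Curriculum,
    config: GibbsConfig,
    rng: np.random.Generator,
    library: Optional[ConceptLibrary] = None,
) -> list[ConceptLibrary]:
    """Run one bounded learner through the curriculum's phases.

    Stage ``k`` runs ``chain_length`` Gibbs steps on the cumulative trials of
    phases 0..k, continuing from the previous stage's library; returns the
    per-stage library snapshots.
    """
    lib = library.copy() if library is not None else ConceptLibrary(
        config.alpha0, config.discount
    )
    snapshots: list[ConceptLibrary] = []
    for k in range(curriculum.n_phases):
        trials = curriculum.trials_through(k)
        for _ in range(config.chain_length):
            lib, _found = gibbs_step(lib, trials, config, rng)
        snapshots.append(lib)
    return snapshots


def population_libraries(
    curriculum: Curriculum,
    config: GibbsConfig,
    rng: np.random.Generator,
    n_learners: Optional[int] = None,
) -> list[list[ConceptLibrary]]:
    """Per-stage library pools from independent simulated learners.

    Returns ``pools[stage][learner]``.
    """
    n = config.n_learners if n_learners is None else n_learners
    pools: list[list[ConceptLibrary]] = [[] for _ in range(curriculum.n_phases)]
    for _ in range(n):
        snaps = run_learner(curriculum, config, rng)
        for k, lib in enumerate(snaps):
            pools[k].append(lib)
    return pools


def draw_predictions(
    libraries: Sequence[ConceptLibrary],
    tasks: Sequence[Trial],
    n_draws: int,
    rng: np.random.Generator,
    budget: Optional[GenerationBudget] = None,
    consistent_with: Optional[Sequence[Trial]] = None,
) -> np.ndarray:
    """Tally generative draws from pooled libraries into 17-bin distributions.

    Each draw picks a library uniformly, generates one programme of the task
    type via the grammar and evaluates it on every task, clipping results to
    the response scale.  Failed generation attempts are dropped and the
    distribution renormalized; ``consistent_with`` optionally filters draws
    by data consistency (off by default, matching the generative predictive).
    """
    budget = budget or GenerationBudget(max_depth=2)
    tally = np.zeros((len(tasks), N_RESPONSES), dtype=float)
    n_ok = 0
    for _ in range(n_draws):
        lib = libraries[int(rng.integers(len(libraries)))]
        try:
            prog = generate_programme(lib, _TOP_TYPE, budget, rng)
        except GenerationError:
            continue
        if consistent_with is not None and not likelihood(prog, consistent_with):
            continue
        n_ok += 1
        for j, task in enumerate(tasks):
            try:
                value = clip_response(evaluate_pair(prog, task.agent, task.recipient))
            except Exception:
                continue
            tally[j, value] += 1.0
    if n_ok == 0:
        return np.full((len(tasks), N_RESPONSES), 1.0 / N_RESPONSES)
    sums = tally.sum(axis=1, keepdims=True)
    sums[sums == 0] = 1.0
    return tally / sums


def posterior_predictive(
    curriculum: Curriculum,
    config: GibbsConfig,
    tasks: Optional[Sequence[Trial]] = None,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Population posterior-predictive distributions per phase and task.

    Returns an array of shape (n_phases, n_tasks, 17), each row a normalized
    distribution over the 0-16 response scale.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    tasks = curriculum.generalization_tasks if tasks is None else tasks
    pools = population_libraries(curriculum, config, rng)
    out = np.zeros((curriculum.n_phases, len(tasks), N_RESPONSES))
    budget = GenerationBudget(max_depth=config.max_frame_depth)
    for k, pool in enumerate(pools):
        consistent = curriculum.trials_through(k) if config.consistency_filter else None
        out[k] = draw_predictions(
            pool, tasks, config.n_predictive_draws, rng, budget, consistent
        )
    return out


def agr_predict(
    pred_forward: np.ndarray, pred_backward: np.ndarray, theta: float
) -> np.ndarray:
    """Convex mixture of forward and backward predictions, renormalized."""
    if not (0.0 <= theta <= 1.0):
        raise ValueError("theta must lie in [0, 1]")
    fwd = np.asarray(pred_forward, dtype=float)
    bwd = np.asarray(pred_backward, dtype=float)
    if fwd.shape != bwd.shape:
        raise ValueError("forward/backward predictions must share a shape")
    mix = theta * fwd + (1.0 - theta) * bwd
    return mix / mix.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------

def _phased_trials(X: np.ndarray, y: np.ndarray, phases) -> list[list[Trial]]:
    trials = trials_from_arrays(X, y)
    if phases is None:
        return [trials]
    out = []
    for idx in phases:
        out.append([trials[int(i)] for i in idx])
    return out


class _PhasedCurriculum:
    """Minimal curriculum-like view over raw (X, y) phases for the estimators."""

    def __init__(self, phases: list[list[Trial]]):
        self.phases = phases
        self.n_phases = len(phases)

    def trials_through(self, k: int) -> tuple[Trial, ...]:
        out: list[Trial] = []
        for p in self.phases[: k + 1]:
            out.extend(p)
        return tuple(out)


class AdaptorGrammarLearner(ResponsePredictorMixin, BaseEstimator):
    """Bootstrap concept learner (adaptor grammar over causal programmes).

    Fits a population of resource-bounded Gibbs learners to phased causal
    observations and predicts 17-bin response distributions for novel
    (stripe, spot, segment) feature triples.

    Parameters mirror :class:`GibbsConfig`; ``n_learners`` and
    ``n_predictive_draws`` default to desk-scale values here so the estimator
    is cheap to use interactively — pass larger values for full-scale runs.
    """

    def __init__(
        self,
        alpha0: float = 1.0,
        discount: float = 0.5,
        depth_decay: float = 6.0,
        chain_length: int = 2,
        n_cache: int = 3,
        max_frame_depth: int = 2,
        n_learners: int = 100,
        n_predictive_draws: int = 1000,
        consistency_filter: bool = False,
        random_state: Optional[int] = None,
    ):
        self.alpha0 = alpha0
        self.discount = discount
        self.depth_decay = depth_decay
        self.chain_length = chain_length
        self.n_cache = n_cache
        self.max_frame_depth = max_frame_depth
        self.n_learners = n_learners
        self.n_predictive_draws = n_predictive_draws
        self.consistency_filter = consistency_filter
        self.random_state = random_state

    def _config(self) -> GibbsConfig:
        return GibbsConfig(
            depth_decay=self.depth_decay,
            chain_length=self.chain_length,
            n_cache=self.n_cache,
            max_frame_depth=self.max_frame_depth,
            n_learners=self.n_learners,
            n_predictive_draws=self.n_predictive_draws,
            alpha0=self.alpha0,
            discount=self.discount,
            consistency_filter=self.consistency_filter,
            seed=self.random_state,
        )

    def fit(self, X, y, phases=None):
        """Fit to learning trials.

        X : array (n_trials, 3) of (stripes, spots, segments); y : observed
        result segments.  ``phases`` optionally lists index arrays defining
        the curriculum stages (processed cumulatively, in order).
        """
        X, y = validate_features(X, y)
        phase_trials = _phased_trials(X, y, phases)
        curriculum = _PhasedCurriculum(phase_trials)
        config = self._config()
        rng = np.random.default_rng(self.random_state)
        pools: list[list[ConceptLibrary]] = [[] for _ in range(curriculum.n_phases)]
        for _ in range(self.n_learners):
            lib = ConceptLibrary(self.alpha0, self.discount)
            for k in range(curriculum.n_phases):
                trials = curriculum.trials_through(k)
                for _ in range(self.chain_length):
                    lib, _f = gibbs_step(lib, trials, config, rng)
                pools[k].append(lib)
        self.libraries_ = pools
        self.phase_trials_ = phase_trials
        self.n_stages_ = curriculum.n_phases
        self._rng_after_fit = rng
        return self

    def predict_proba(self, X, stage: int = -1):
        """17-bin response distributions for feature triples, from the pooled
        libraries of the given stage (default: final stage)."""
        X, _ = validate_features(X, None)
        tasks = [Trial(int(r[0]), int(r[1]), int(r[2])) for r in X]
        pool = self.libraries_[stage]
        rng = np.random.default_rng(
            None if self.random_state is None else self.random_state + 1
        )
        consistent = None
        if self.consistency_filter:
            stage_idx = stage % self.n_stages_
            consistent = _PhasedCurriculum(self.phase_trials_).trials_through(stage_idx)
        return draw_predictions(
            pool,
            tasks,
            self.n_predictive_draws,
            rng,
            GenerationBudget(self.max_frame_depth),
            consistent,
        )


class AdaptorGrammarReprocessor(ResponsePredictorMixin, BaseEstimator):
    """AG with reprocessing: mixes forward and phase-reversed predictions.

    ``mix_weight`` is the weight on the forward (as-presented) pass; the
    backward pass reprocesses the phases in reverse order, modelling learners
    who revisit earlier evidence.
    """

    def __init__(
        self,
        mix_weight: float = 0.5,
        alpha0: float = 1.0,
        discount: float = 0.5,
        depth_decay: float = 6.0,
        chain_length: int = 2,
        n_cache: int = 3,
        max_frame_depth: int = 2,
        n_learners: int = 100,
        n_predictive_draws: int = 1000,
        consistency_filter: bool = False,
        random_state: Optional[int] = None,
    ):
        self.mix_weight = mix_weight
        self.alpha0 = alpha0
        self.discount = discount
        self.depth_decay = depth_decay
        self.chain_length = chain_length
        self.n_cache = n_cache
        self.max_frame_depth = max_frame_depth
        self.n_learners = n_learners
        self.n_predictive_draws = n_predictive_draws
        self.consistency_filter = consistency_filter
        self.random_state = random_state

    def _sub_params(self, offset: int) -> dict:
        seed = None if self.random_state is None else self.random_state + offset
        return dict(
            alpha0=self.alpha0,
            discount=self.discount,
            depth_decay=self.depth_decay,
            chain_length=self.chain_length,
            n_cache=self.n_cache,
            max_frame_depth=self.max_frame_depth,
            n_learners=self.n_learners,
            n_predictive_draws=self.n_predictive_draws,
            consistency_filter=self.consistency_filter,
            random_state=seed,
        )

    def fit(self, X, y, phases=None):
        if not (0.0 <= self.mix_weight <= 1.0):
            raise ValueError("mix_weight must lie in [0, 1]")
        X, y = validate_features(X, y)
        if phases is None:
            phases = [np.arange(len(y))]
        self.forward_ = AdaptorGrammarLearner(**self._sub_params(0)).fit(
            X, y, phases=phases
        )
        self.backward_ = AdaptorGrammarLearner(**self._sub_params(1000003)).fit(
            X, y, phases=list(reversed(list(phases)))
        )
        self.n_stages_ = self.forward_.n_stages_
        return self

    def predict_proba(self, X, stage: int = -1):
        fwd = self.forward_.predict_proba(X, stage=stage)
        bwd = self.backward_.predict_proba(X, stage=stage)
        return agr_predict(fwd, bwd, self.mix_weight)
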