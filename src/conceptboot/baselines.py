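"""Comparison models: rational rules, similarity, regressions and GP.

All five models consume (stripes, spots, segments) feature triples with
observed result segments and emit 17-bin distributions over the 0-16
response scale, so they plug into the same evaluation harness as the
adaptor-grammar learners.

The rational-rules model is a Bayesian-symbolic baseline without caching: a
probabilistic context-free grammar over the same primitive inventory,

    S -> add(A, A) | sub(A, A) | mult(A, A)
    A -> S | B
    B -> C | D
    C -> stripe | spot | segment
    D -> 0 | 1 | 2 | 3

with uniform production probabilities per non-terminal and a hard derivation
depth cap (overlong derivations are rejected so the prior stays
well-defined).  Sampled concepts are filtered by the deterministic 0/1
likelihood; surviving frequencies approximate the posterior.  Because this
grammar is context-free, the model sees only the union of the evidence and
cannot show curriculum-order effects.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import linalg as sla
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LinearRegression, LogisticRegression

from .base import ResponsePredictorMixin, trials_from_arrays, validate_features
from .curricula import N_RESPONSES, Trial, clip_response

__all__ = [
    "RRConfig",
    "SimilarityConfig",
    "GPConfig",
    "RationalRules",
    "SimilarityModel",
    "LinearRegressionModel",
    "MultinomialModel",
    "GaussianProcessModel",
    "rr_sample_posterior",
    "rr_predict",
    "rr_derivation_probability",
    "similarity_predict",
    "linreg_predict",
    "multinom_predict",
    "gp_predict",
]


# ---------------------------------------------------------------------------
# Rational rules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RRConfig:
    max_depth: int = 40
    n_samples: int = 100_000
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.max_depth < 1 or self.n_samples < 1:
            raise ValueError("max_depth and n_samples must be positive")


_OPS = ("add", "sub", "mult")
_FEATURES = ("stripe", "spot", "segment")
_CONSTS = (0, 1, 2, 3)


class _DepthExceeded(Exception):
    pass


def _rr_sample_A(rng: np.random.Generator, depth: int, max_depth: int):
    if depth > max_depth:
        raise _DepthExceeded
    if rng.random() < 0.5:  # A -> S
        return _rr_sample_S(rng, depth, max_depth)
    # A -> B; B -> C | D
    if rng.random() < 0.5:
        return _FEATURES[int(rng.integers(3))]
    return _CONSTS[int(rng.integers(4))]


def _rr_sample_S(rng: np.random.Generator, depth: int, max_depth: int):
    if depth > max_depth:
        raise _DepthExceeded
    op = _OPS[int(rng.integers(3))]
    return (op, _rr_sample_A(rng, depth + 1, max_depth), _rr_sample_A(rng, depth + 1, max_depth))


def rr_eval(expr, stripes: int, spots: int, segments: int) -> int:
    """Evaluate a rational-rules expression on one feature triple."""
    if isinstance(expr, tuple):
        op, a, b = expr
        va = rr_eval(a, stripes, spots, segments)
        vb = rr_eval(b, stripes, spots, segments)
        if op == "add":
            return va + vb
        if op == "sub":
            return va - vb
        return va * vb
    if expr == "stripe":
        return stripes
    if expr == "spot":
        return spots
    if expr == "segment":
        return segments
    return int(expr)


def rr_derivation_probability(expr, root: bool = True) -> float:
    """Exact prior probability of one derivation under the uniform-production
    grammar.  Two derivations using the same multiset of productions have
    exactly equal probability, whatever their nesting."""
    if isinstance(expr, tuple):
        op, a, b = expr
        p = 1.0 / 3.0  # S -> op(A, A)
        if not root:
            p *= 0.5  # A -> S
        return p * rr_derivation_probability(a, root=False) * rr_derivation_probability(
            b, root=False
        )
    if root:
        raise ValueError("the start symbol derives an operation")
    if expr in _FEATURES:
        return 0.5 * 0.5 * (1.0 / 3.0)  # A -> B, B -> C, C -> feature
    return 0.5 * 0.5 * 0.25  # A -> B, B -> D, D -> constant


def rr_acceptance_probability(max_depth: int = 40) -> float:
    """Exact probability that a grammar draw respects the depth cap.

    Rejecting overlong derivations conditions the prior on the cap, so
    sampled frequencies equal ``rr_derivation_probability(expr) / P(accept)``.
    """
    from functools import lru_cache

    @lru_cache(None)
    def a_fit(d: int) -> float:
        if d > max_depth:
            return 0.0
        return 0.5 + 0.5 * s_fit(d)

    @lru_cache(None)
    def s_fit(d: int) -> float:
        if d > max_depth:
            return 0.0
        return a_fit(d + 1) ** 2

    return s_fit(1)


def rr_sample_posterior(
    trials: Sequence[Trial], config: RRConfig, rng: np.random.Generator
) -> tuple[list[tuple], np.ndarray]:
    """Sample n derivations, keep those with deterministic likelihood 1.

    Returns (distinct surviving expressions, frequency weights); both empty
    when nothing survives (flagged empty posterior).
    """
    counts: dict[tuple, int] = {}
    exprs: dict[tuple, object] = {}
    accepted = 0
    while accepted < config.n_samples:
        try:
            expr = _rr_sample_S(rng, 1, config.max_depth)
        except _DepthExceeded:
            continue  # rejected overlong derivation
        accepted += 1
        ok = True
        for t in trials:
            if t.result is None:
                raise ValueError("rational rules requires observed results")
            if rr_eval(expr, t.stripes, t.spots, t.segments) != t.result:
                ok = False
                break
        if ok:
            key = expr
            counts[key] = counts.get(key, 0) + 1
            exprs[key] = expr
    keys = sorted(counts, key=repr)
    weights = np.array([counts[k] for k in keys], dtype=float)
    if weights.size:
        weights /= weights.sum()
    return [exprs[k] for k in keys], weights


def rr_predict(
    posterior: Sequence, weights: np.ndarray, tasks: Sequence[Trial]
) -> np.ndarray:
    """Weight-tally survivor evaluations into 17-bin distributions; an empty
    posterior falls back to the uniform distribution (documented)."""
    out = np.zeros((len(tasks), N_RESPONSES))
    if len(posterior) == 0:
        out[:] = 1.0 / N_RESPONSES
        return out
    for expr, w in zip(posterior, weights):
        for j, t in enumerate(tasks):
            out[j, clip_response(rr_eval(expr, t.stripes, t.spots, t.segments))] += w
    return out / out.sum(axis=1, keepdims=True)


class RationalRules(ResponsePredictorMixin, BaseEstimator):
    """PCFG concept learner with uniform productions and no caching."""

    def __init__(
        self,
        max_depth: int = 40,
        n_samples: int = 100_000,
        random_state: Optional[int] = None,
    ):
        self.max_depth = max_depth
        self.n_samples = n_samples
        self.random_state = random_state

    def fit(self, X, y):
        X, y = validate_features(X, y)
        trials = trials_from_arrays(X, y)
        rng = np.random.default_rng(self.random_state)
        cfg = RRConfig(self.max_depth, self.n_samples, self.random_state)
        self.posterior_, self.weights_ = rr_sample_posterior(trials, cfg, rng)
        self.empty_posterior_ = len(self.posterior_) == 0
        return self

    def predict_proba(self, X):
        X, _ = validate_features(X)
        tasks = [Trial(int(r[0]), int(r[1]), int(r[2])) for r in X]
        return rr_predict(self.posterior_, self.weights_, tasks)


# ---------------------------------------------------------------------------
# Similarity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimilarityConfig:
    a: float = 1.0
    b: float = 1.0
    c: float = 1.0

    def __post_init__(self) -> None:
        if self.a < 0 or self.b < 0 or self.c < 0:
            raise ValueError("similarity weights must be non-negative")
        if self.a == self.b == self.c == 0:
            raise ValueError("similarity weights cannot all be zero")


def similarity_score(learning: Trial, task: Trial, config: SimilarityConfig) -> float:
    """sigma = exp(-Delta) with Delta the weighted absolute feature distance;
    equals 1 exactly when agent and recipient features coincide."""
    delta = (
        config.a * abs(learning.stripes - task.stripes)
        + config.b * abs(learning.spots - task.spots)
        + config.c * abs(learning.segments - task.segments)
    )
    return math.exp(-delta)


def similarity_predict(
    trials: Sequence[Trial], tasks: Sequence[Trial], config: SimilarityConfig
) -> np.ndarray:
    if not trials:
        raise ValueError("similarity model needs at least one learning trial")
    out = np.zeros((len(tasks), N_RESPONSES))
    for j, task in enumerate(tasks):
        for t in trials:
            out[j, clip_response(t.result)] += similarity_score(t, task, config)
    return out / out.sum(axis=1, keepdims=True)


class SimilarityModel(ResponsePredictorMixin, BaseEstimator):
    """Exemplar model: each learning trial votes for its own observed result
    with weight exp(-weighted feature distance)."""

    def __init__(self, a: float = 1.0, b: float = 1.0, c: float = 1.0):
        self.a = a
        self.b = b
        self.c = c

    def fit(self, X, y):
        X, y = validate_features(X, y)
        self.trials_ = trials_from_arrays(X, y)
        self.config_ = SimilarityConfig(self.a, self.b, self.c)
        return self

    def predict_proba(self, X):
        X, _ = validate_features(X)
        tasks = [Trial(int(r[0]), int(r[1]), int(r[2])) for r in X]
        return similarity_predict(self.trials_, tasks, self.config_)


# ---------------------------------------------------------------------------
# Linear regression
# ---------------------------------------------------------------------------

def _split_to_bins(yhat: float, split: str) -> np.ndarray:
    """Spread a continuous prediction over its two nearest integers."""
    dist = np.zeros(N_RESPONSES)
    lo = math.floor(yhat)
    hi = math.ceil(yhat)
    if lo == hi:
        dist[clip_response(lo)] = 1.0
        return dist
    frac = yhat - lo
    w_hi = 0.5 if split == "half" else frac
    dist[clip_response(lo)] += 1.0 - w_hi
    dist[clip_response(hi)] += w_hi
    return dist


def linreg_predict(
    trials: Sequence[Trial], tasks: Sequence[Trial], split: str = "proximity"
) -> np.ndarray:
    X = np.array([t.features() for t in trials], dtype=float)
    y = np.array([t.result for t in trials], dtype=float)
    model = LinearRegression(fit_intercept=False).fit(X, y)
    Xt = np.array([t.features() for t in tasks], dtype=float)
    yhat = model.predict(Xt)
    return np.vstack([_split_to_bins(float(v), split) for v in yhat])


class LinearRegressionModel(ResponsePredictorMixin, BaseEstimator):
    """R' ~ a*stripe + b*spot + c*R, least squares (minimum-norm when the
    design is degenerate); the continuous prediction is spread over its two
    nearest integers, proximity-weighted by default (``split="half"`` for an
    even split)."""

    def __init__(self, split: str = "proximity"):
        self.split = split

    def fit(self, X, y):
        X, y = validate_features(X, y)
        self.model_ = LinearRegression(fit_intercept=False).fit(
            X.astype(float), y.astype(float)
        )
        self.degenerate_ = np.linalg.matrix_rank(X.astype(float)) < X.shape[1]
        return self

    def predict_proba(self, X):
        X, _ = validate_features(X)
        yhat = self.model_.predict(X.astype(float))
        return np.vstack([_split_to_bins(float(v), self.split) for v in yhat])


# ---------------------------------------------------------------------------
# Multinomial logistic regression
# ---------------------------------------------------------------------------

def multinom_predict(
    trials: Sequence[Trial], tasks: Sequence[Trial], C: float = 1.0
) -> np.ndarray:
    X = np.array([t.features() for t in trials], dtype=float)
    y = np.array([clip_response(t.result) for t in trials], dtype=int)
    model = MultinomialModel(C=C)
    model.fit(X, y)
    Xt = np.array([t.features() for t in tasks], dtype=float)
    return model.predict_proba(Xt)


class MultinomialModel(ResponsePredictorMixin, BaseEstimator):
    """L2-regularized multinomial logistic regression over observed result
    classes; unseen classes receive zero mass (the evaluation layer adds
    trembling-hand noise).  Falls back to class frequencies if the solver
    fails to converge (flagged via ``converged_``)."""

    def __init__(self, C: float = 1.0, max_iter: int = 2000):
        self.C = C
        self.max_iter = max_iter

    def fit(self, X, y):
        X, y = validate_features(X, y)
        self.classes_seen_ = np.unique(y)
        self.converged_ = True
        self.class_freq_ = np.bincount(y, minlength=N_RESPONSES).astype(float)
        self.class_freq_ /= self.class_freq_.sum()
        if len(self.classes_seen_) < 2:
            self.model_ = None
            return self
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            try:
                self.model_ = LogisticRegression(
                    C=self.C, max_iter=self.max_iter
                ).fit(X.astype(float), y)
            except ConvergenceWarning:
                self.model_ = None
                self.converged_ = False
        return self

    def predict_proba(self, X):
        X, _ = validate_features(X)
        out = np.zeros((len(X), N_RESPONSES))
        if self.model_ is None:
            if len(self.classes_seen_) == 1:
                out[:, int(self.classes_seen_[0])] = 1.0
            else:
                out[:] = self.class_freq_[None, :]
            return out
        proba = self.model_.predict_proba(X.astype(float))
        for j, cls in enumerate(self.model_.classes_):
            out[:, int(cls)] = proba[:, j]
        return out / out.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# Gaussian process regression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GPConfig:
    bandwidth: float = 1.0  # sigma^2 in exp(-|x_f - x_f'| / (2 sigma^2))
    combination: str = "sum"  # or "product"
    noise: float = 1e-6

    def __post_init__(self) -> None:
        if self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")
        if self.combination not in ("sum", "product"):
            raise ValueError("combination must be 'sum' or 'product'")


def _gp_kernel(A: np.ndarray, B: np.ndarray, config: GPConfig) -> np.ndarray:
    # one exponential kernel per feature on the absolute difference
    per_feature = np.exp(
        -np.abs(A[:, None, :] - B[None, :, :]) / (2.0 * config.bandwidth)
    )
    if config.combination == "sum":
        return per_feature.sum(axis=2)
    return per_feature.prod(axis=2)


def gp_predict(
    trials: Sequence[Trial], tasks: Sequence[Trial], config: GPConfig = GPConfig()
) -> np.ndarray:
    X = np.array([t.features() for t in trials], dtype=float)
    y = np.array([t.result for t in trials], dtype=float)
    Xt = np.array([t.features() for t in tasks], dtype=float)
    K = _gp_kernel(X, X, config)
    jitter = config.noise
    for _ in range(8):
        try:
            cho = sla.cho_factor(K + jitter * np.eye(len(X)), lower=True)
            break
        except np.linalg.LinAlgError:
            jitter *= 10.0  # conditioning failure: escalate jitter
    else:  # pragma: no cover - pathological conditioning
        raise np.linalg.LinAlgError("GP kernel matrix could not be factorized")
    alpha = sla.cho_solve(cho, y)
    Ks = _gp_kernel(Xt, X, config)
    mu = Ks @ alpha
    prior_var = 3.0 if config.combination == "sum" else 1.0
    v = sla.cho_solve(cho, Ks.T)
    var = prior_var + config.noise - np.einsum("ij,ji->i", Ks, v)
    var = np.maximum(var, 1e-12)
    sd = np.sqrt(var)
    # Bin the Gaussian over the response scale; end bins absorb the tails.
    edges = np.arange(0.5, N_RESPONSES - 0.5)  # 0.5 .. 15.5
    out = np.zeros((len(tasks), N_RESPONSES))
    for j in range(len(tasks)):
        cdf = stats.norm.cdf(edges, loc=mu[j], scale=sd[j])
        probs = np.diff(np.concatenate(([0.0], cdf, [1.0])))
        out[j] = probs
    return out / out.sum(axis=1, keepdims=True)


class GaussianProcessModel(ResponsePredictorMixin, BaseEstimator):
    """GP regression on 3-D feature inputs with one exponential kernel per
    feature (summed by default, ``combination="product"`` available); the
    predictive Gaussian is binned over the 17 response values."""

    def __init__(
        self, bandwidth: float = 1.0, combination: str = "sum", noise: float = 1e-6
    ):
        self.bandwidth = bandwidth
        self.combination = combination
        self.noise = noise

    def fit(self, X, y):
        X, y = validate_features(X, y)
        self.trials_ = trials_from_arrays(X, y)
        self.config_ = GPConfig(self.bandwidth, self.combination, self.noise)
        return self

    def predict_proba(self, X):
        X, _ = validate_features(X)
        tasks = [Trial(int(r[0]), int(r[1]), int(r[2])) for r in X]
        return gp_predict(self.trials_, tasks, self.config_)
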