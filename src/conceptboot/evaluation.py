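"""Model scoring against response tables.

Predictions are smoothed with trembling-hand noise before scoring,

    P_h(y) = (P(y) + h) / (1 + 17 h),        0 < h < 1/17,

which keeps the shape of the raw prediction while removing zero-likelihood
responses.  The total fit of a model to a response table is the natural-log
likelihood

    LL = sum_c sum_i sum_y ln(P_h_ci(y)) * n_ciy,

compared against the eyes-closed baseline ``LL_random = n_participants *
n_tasks * ln(1/17)``.  ``cross_validate`` holds out one curriculum at a
time, fits ``h`` (and the AGR mixing weight, when given forward/backward
prediction pairs) by maximum likelihood on the remaining curricula, and sums
the held-out log-likelihoods.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np
from scipy import optimize

from .curricula import N_RESPONSES, ResponseTable
from .inference import agr_predict

__all__ = [
    "NoiseSetting",
    "FitResult",
    "tremble",
    "total_log_likelihood",
    "random_baseline_ll",
    "cross_validate",
]

_H_MAX = 1.0 / N_RESPONSES


@dataclass(frozen=True)
class NoiseSetting:
    noise_h: float

    def __post_init__(self) -> None:
        if not (0.0 < self.noise_h < _H_MAX):
            raise ValueError(f"noise_h must lie in (0, {_H_MAX:.6f})")


def tremble(P: np.ndarray, noise_h: float) -> np.ndarray:
    """Trembling-hand smoothing; strictly positive, sums to 1, keeps shape."""
    NoiseSetting(noise_h)
    P = np.asarray(P, dtype=float)
    return (P + noise_h) / (1.0 + N_RESPONSES * noise_h)


def total_log_likelihood(
    predictions: dict[str, np.ndarray],
    counts: dict[str, np.ndarray],
    noise_h: float,
) -> float:
    """Sum of ln(P_h(y)) * n_ciy over curricula, phases, tasks and responses."""
    ll = 0.0
    for curriculum, table in counts.items():
        table = np.asarray(table, dtype=float)
        if table.sum() == 0:
            continue
        if curriculum not in predictions:
            raise KeyError(f"missing predictions for curriculum {curriculum!r}")
        P = np.asarray(predictions[curriculum], dtype=float)
        if P.shape != table.shape:
            raise ValueError(
                f"prediction shape {P.shape} does not match counts {table.shape} "
                f"for curriculum {curriculum!r}"
            )
        nz = table.sum(axis=-1) > 0
        missing = np.argwhere(nz & ~np.isfinite(P.sum(axis=-1)))
        if missing.size:
            raise ValueError(f"non-finite prediction cells at {missing.tolist()}")
        ll += float(np.sum(np.log(tremble(P, noise_h)) * table))
    return ll


def random_baseline_ll(
    n_participants: int, n_tasks_per_participant: int, n_options: int = N_RESPONSES
) -> float:
    """Log-likelihood of uniform random responding."""
    if min(n_participants, n_tasks_per_participant, n_options) < 1:
        raise ValueError("all arguments must be positive")
    return n_participants * n_tasks_per_participant * math.log(1.0 / n_options)


@dataclass
class FitResult:
    folds: list[dict] = field(default_factory=list)
    total_ll: float = 0.0
    ll_random: float = 0.0

    @property
    def delta(self) -> float:
        """Improvement over the random baseline, LL_model - LL_random."""
        return self.total_ll - self.ll_random

    def to_json(self) -> str:
        return json.dumps(
            {
                "folds": self.folds,
                "total_ll": self.total_ll,
                "ll_random": self.ll_random,
                "delta": self.delta,
            },
            indent=2,
        )


_H_GRID = np.linspace(1e-6, _H_MAX - 1e-6, 64)


def _fit_noise(
    predictions: dict[str, np.ndarray], counts: dict[str, np.ndarray]
) -> float:
    def neg_ll(h: float) -> float:
        return -total_log_likelihood(predictions, counts, h)

    res = optimize.minimize_scalar(
        neg_ll, bounds=(1e-9, _H_MAX - 1e-9), method="bounded"
    )
    best_h = float(res.x) if res.success else None
    # grid fallback / refinement guard
    grid_best = min(_H_GRID, key=neg_ll)
    if best_h is None or neg_ll(best_h) > neg_ll(grid_best):
        best_h = float(grid_best)
    return best_h


def _fit_noise_and_theta(
    forward: dict[str, np.ndarray],
    backward: dict[str, np.ndarray],
    counts: dict[str, np.ndarray],
) -> tuple[float, float]:
    def mixed(theta: float) -> dict[str, np.ndarray]:
        return {c: agr_predict(forward[c], backward[c], theta) for c in forward}

    def neg_ll(params) -> float:
        h, theta = params
        return -total_log_likelihood(mixed(theta), counts, h)

    best = None
    for theta0 in (0.2, 0.5, 0.8):
        res = optimize.minimize(
            neg_ll,
            x0=np.array([0.02, theta0]),
            bounds=[(1e-9, _H_MAX - 1e-9), (0.0, 1.0)],
            method="L-BFGS-B",
        )
        if res.success and (best is None or res.fun < best.fun):
            best = res
    # grid fallback
    thetas = np.linspace(0.0, 1.0, 21)
    grid = min(
        ((h, t) for h in _H_GRID[::4] for t in thetas), key=lambda p: neg_ll(p)
    )
    if best is None or neg_ll(grid) < best.fun:
        return float(grid[0]), float(grid[1])
    return float(best.x[0]), float(best.x[1])


PredictionSpec = Union[
    dict[str, np.ndarray], tuple[dict[str, np.ndarray], dict[str, np.ndarray]]
]


def cross_validate(predictions: PredictionSpec, counts: dict[str, np.ndarray]) -> FitResult:
    """Leave-one-curriculum-out evaluation with per-fold ML parameter fitting.

    ``predictions`` is either ``{curriculum: (phases, tasks, 17) array}``, in
    which case only the trembling-hand ``h`` is fitted, or a
    ``(forward, backward)`` pair of such dicts for the reprocessing model, in
    which case the mixing weight is fitted jointly with ``h``.
    ``counts`` holds the matching response-count arrays per curriculum.
    """
    agr_mode = isinstance(predictions, tuple)
    curricula = sorted(counts)
    if len(curricula) < 2:
        raise ValueError("cross-validation needs at least two curricula")
    result = FitResult()
    total_responses = 0.0
    responses_per_subject = None
    for held_out in curricula:
        train = {c: counts[c] for c in curricula if c != held_out}
        test = {held_out: counts[held_out]}
        if agr_mode:
            fwd, bwd = predictions
            h, theta = _fit_noise_and_theta(
                {c: fwd[c] for c in train}, {c: bwd[c] for c in train}, train
            )
            test_pred = {held_out: agr_predict(fwd[held_out], bwd[held_out], theta)}
            fold = {"test_curriculum": held_out, "noise_h": h, "mix_weight": theta}
        else:
            h = _fit_noise({c: predictions[c] for c in train}, train)
            test_pred = {held_out: predictions[held_out]}
            fold = {"test_curriculum": held_out, "noise_h": h}
        ll_test = total_log_likelihood(test_pred, test, h)
        fold["ll_test"] = ll_test
        result.folds.append(fold)
        result.total_ll += ll_test
        total_responses += float(np.asarray(counts[held_out]).sum())
    result.ll_random = total_responses * math.log(1.0 / N_RESPONSES)
    return result
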