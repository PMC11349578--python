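"""Curricula, generalization tasks and synthetic participants.

A learning *trial* is one observed causal interaction: an agent (stripes,
spots), a recipient (segments) and the observed result-segment count.  A
*curriculum* is a named, phased ordering of such trials over the same
ground-truth rule, ``R' = stripe(A) * R - spot(A)``:

construct
    Phase I exercises only the multiplicative feature (spots fixed at 0),
    Phase II varies both features.
deconstruct
    the phase reversal of construct.
combine
    Phase I as construct; Phase II holds the multiplicative feature at 1,
    leaving the compositional form of the two sub-concepts ambiguous.
flip
    combine with its phases swapped.

Counterbalanced variants exchange the stripe and spot roles (ground truth
``spot(A) * R - stripe(A)``).  Feature values in learning trials lie in 0-3;
generalization tasks are novel out-of-distribution pairs, answered on a
17-option response scale (0-16 segments).

Trial feature values are pinned here: the constraints they satisfy are the
phase structure above plus the requirement that the Phase-I triple of
construct admits the multiplicative chunk — and not an additive or constant
rule — as its shallow explanation.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .cl_core import (
    CausalObject,
    Programme,
    alternative_programme,
    chunk_programme,
    evaluate_pair,
    ground_truth_programme,
    parse_programme,
    programme_to_string,
)

__all__ = [
    "N_RESPONSES",
    "RESPONSE_VALUES",
    "Trial",
    "Curriculum",
    "ResponseTable",
    "CURRICULUM_NAMES",
    "build_curriculum",
    "clip_response",
    "default_candidate_tasks",
    "default_hypothesis_set",
    "select_generalization_trials",
    "simulate_participants",
    "accuracy",
]

#: The generalization response scale: 0-16 segments, 17 options.
N_RESPONSES = 17
RESPONSE_VALUES = tuple(range(N_RESPONSES))

CURRICULUM_NAMES = ("construct", "deconstruct", "combine", "flip")


def clip_response(value: int) -> int:
    """Clip an evaluated result onto the bounded response scale (0-16)."""
    return max(0, min(N_RESPONSES - 1, int(value)))


@dataclass(frozen=True)
class Trial:
    """One causal observation; ``result`` is None for generalization tasks."""

    stripes: int
    spots: int
    segments: int
    result: Optional[int] = None

    def __post_init__(self) -> None:
        for name in ("stripes", "spots", "segments"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def agent(self) -> CausalObject:
        return CausalObject(role="agent", stripes=self.stripes, spots=self.spots)

    @property
    def recipient(self) -> CausalObject:
        return CausalObject(role="recipient", segments=self.segments)

    @property
    def is_learning(self) -> bool:
        return self.result is not None

    def features(self) -> tuple[int, int, int]:
        return (self.stripes, self.spots, self.segments)


def _apply_rule(prog: Programme, stripes: int, spots: int, segments: int) -> int:
    agent = CausalObject(role="agent", stripes=stripes, spots=spots)
    recipient = CausalObject(role="recipient", segments=segments)
    return evaluate_pair(prog, agent, recipient)


# Feature triples (stripes, spots, segments) for the base (non-counterbalanced)
# phases; results are derived from the ground truth at build time.
_PHASE_MULT_ONLY = ((2, 0, 2), (3, 0, 1), (1, 0, 3))
_PHASE_BOTH = ((2, 3, 3), (3, 1, 2), (1, 2, 2))
_PHASE_FIXED_ONE = ((1, 1, 2), (1, 2, 3), (1, 3, 3))


@dataclass(frozen=True)
class Curriculum:
    name: str
    phases: tuple[tuple[Trial, ...], ...]
    ground_truth: Programme
    generalization_tasks: tuple[Trial, ...]
    counterbalanced: bool = False

    def __post_init__(self) -> None:
        for phase in self.phases:
            for t in phase:
                if not t.is_learning:
                    raise ValueError("learning phases must carry observed results")
                expected = _apply_rule(self.ground_truth, *t.features())
                if expected != t.result:
                    raise ValueError(
                        f"trial {t} inconsistent with ground truth ({expected})"
                    )
        for t in self.generalization_tasks:
            if t.is_learning:
                raise ValueError("generalization tasks must not carry results")

    @property
    def n_phases(self) -> int:
        return len(self.phases)

    def trials_through(self, phase_index: int) -> tuple[Trial, ...]:
        """Cumulative learning trials visible at the end of a phase (0-based)."""
        out: list[Trial] = []
        for p in self.phases[: phase_index + 1]:
            out.extend(p)
        return tuple(out)

    def truth_responses(self) -> np.ndarray:
        """Clipped ground-truth answer for each generalization task."""
        return np.array(
            [
                clip_response(_apply_rule(self.ground_truth, *t.features()))
                for t in self.generalization_tasks
            ],
            dtype=int,
        )

    # -- serialization ------------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "name": self.name,
                "counterbalanced": self.counterbalanced,
                "ground_truth": programme_to_string(self.ground_truth),
                "phases": [
                    [
                        {
                            "stripes": t.stripes,
                            "spots": t.spots,
                            "segments": t.segments,
                            "result": t.result,
                        }
                        for t in phase
                    ]
                    for phase in self.phases
                ],
                "generalization_tasks": [
                    {"stripes": t.stripes, "spots": t.spots, "segments": t.segments}
                    for t in self.generalization_tasks
                ],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "Curriculum":
        data = json.loads(text)
        return cls(
            name=data["name"],
            counterbalanced=bool(data.get("counterbalanced", False)),
            ground_truth=parse_programme(data["ground_truth"]),
            phases=tuple(
                tuple(Trial(**t) for t in phase) for phase in data["phases"]
            ),
            generalization_tasks=tuple(
                Trial(**t) for t in data["generalization_tasks"]
            ),
        )


def _swap(triples: Iterable[tuple[int, int, int]]) -> tuple[tuple[int, int, int], ...]:
    return tuple((p, s, r) for (s, p, r) in triples)


def build_curriculum(name: str, counterbalanced: bool = False) -> Curriculum:
    """Construct one of the four built-in curricula (plus counterbalance)."""
    if name not in CURRICULUM_NAMES:
        raise ValueError(f"unknown curriculum {name!r}; choose from {CURRICULUM_NAMES}")
    truth = ground_truth_programme(counterbalanced)
    mult_only, both, fixed_one = _PHASE_MULT_ONLY, _PHASE_BOTH, _PHASE_FIXED_ONE
    if counterbalanced:
        mult_only, both, fixed_one = _swap(mult_only), _swap(both), _swap(fixed_one)
    phase_map = {
        "construct": (mult_only, both),
        "deconstruct": (both, mult_only),
        "combine": (mult_only, fixed_one),
        "flip": (fixed_one, mult_only),
    }
    phases = tuple(
        tuple(
            Trial(s, p, r, result=_apply_rule(truth, s, p, r))
            for (s, p, r) in phase
        )
        for phase in phase_map[name]
    )
    tasks = default_generalization_tasks(counterbalanced)
    return Curriculum(
        name=name,
        phases=phases,
        ground_truth=truth,
        generalization_tasks=tasks,
        counterbalanced=counterbalanced,
    )


# ---------------------------------------------------------------------------
# Generalization-task selection
# ---------------------------------------------------------------------------

def _shallow_rule(op: str, x: str, y: str) -> Programme:
    """One-node rule ``op(x, y)`` with the router induced by the argument needs."""
    leaves = {
        "stripe": ("getStripe", "A"),
        "spot": ("getSpot", "A"),
        "segment": ("getSegment", "R"),
        "0": ("0", None),
        "1": ("1", None),
        "2": ("2", None),
        "3": ("3", None),
    }
    lx, needx = leaves[x]
    ly, needy = leaves[y]

    def letter(var: str) -> str:
        left = needx == var
        right = needy == var
        if left and right:
            return "S"
        if left:
            return "C"
        if right:
            return "B"
        return "I"

    router = letter("A") + letter("R")
    return parse_programme(f"({router} {op} {lx} {ly})")


def default_hypothesis_set(counterbalanced: bool = False) -> list[tuple[Programme, float]]:
    """A uniform-weight hypothesis set of rules a shallow learner favours.

    Used (with the candidate grid) to reconstruct the greedy entropy-minimizing
    choice of generalization tasks: every one-node rule ``op(x, y)`` over the
    primitive features/constants, plus the key two-level composites (ground
    truth, its data-consistent alternative, and relatives).
    """
    progs = [
        _shallow_rule(op, x, y)
        for op in ("add", "sub", "mult")
        for x in ("stripe", "spot", "segment", "0", "1", "2", "3")
        for y in ("stripe", "spot", "segment", "0", "1", "2", "3")
    ]
    progs += [
        ground_truth_programme(counterbalanced),
        alternative_programme(counterbalanced),
        chunk_programme(counterbalanced),
        ground_truth_programme(not counterbalanced),
        alternative_programme(not counterbalanced),
        chunk_programme(not counterbalanced),
        parse_programme("(BC sub getSegment getSpot)"),  # R - spot
        parse_programme("(BC sub getSegment getStripe)"),  # R - stripe
        parse_programme("(CB add getStripe getSegment)"),  # stripe + R
        parse_programme("(CB add getSpot getSegment)"),  # spot + R
        parse_programme("(IB I getSegment)"),  # R unchanged
        parse_programme("(SC add (CB mult getStripe getSegment) getSpot)"),  # s*R + p
        parse_programme("(CC sub (CB mult getStripe getSegment) 1)"),  # s*R - 1
        parse_programme("(CB mult (S sub getStripe getSpot) getSegment)"),  # (s-p)*R
        parse_programme("(BC sub (B mult 2 getSegment) getSpot)"),  # 2R - p
        parse_programme("(SB add getStripe (BC add getSegment getSpot))"),  # s+p+R
    ]
    dedup: dict[str, Programme] = {}
    for p in progs:
        dedup.setdefault(programme_to_string(p), p)
    unique = [dedup[k] for k in sorted(dedup)]
    w = 1.0 / len(unique)
    return [(p, w) for p in unique]


def default_candidate_tasks() -> list[Trial]:
    """Candidate pool for task selection: agent features 0-4, recipient 1-4,
    excluding feature triples used in any learning phase."""
    used = set(_PHASE_MULT_ONLY) | set(_PHASE_BOTH) | set(_PHASE_FIXED_ONE)
    used |= {(p, s, r) for (s, p, r) in used}
    out = []
    for s, p, r in itertools.product(range(5), range(5), range(1, 5)):
        if (s, p, r) not in used:
            out.append(Trial(s, p, r))
    return out


def _entropy(weights: Sequence[float]) -> float:
    total = sum(weights)
    if total <= 0:
        return 0.0
    h = 0.0
    for w in weights:
        if w > 0:
            q = w / total
            h -= q * math.log(q)
    return h


def select_generalization_trials(
    hypotheses: Sequence[tuple[Programme, float]],
    candidates: Sequence[Trial],
    k: int = 8,
) -> list[Trial]:
    """Greedy expected-residual-entropy minimization over candidate tasks.

    At each step, add the candidate whose induced refinement of the hypothesis
    partition (hypotheses grouped by their joint predicted responses on the
    chosen tasks) minimizes the expected residual Shannon entropy of the
    hypothesis distribution.  Ties break lexicographically on
    (stripes, spots, segments), so the selection is deterministic.
    """
    if len(candidates) < k:
        raise ValueError(f"need at least k={k} candidates, got {len(candidates)}")
    if len(hypotheses) < 2:
        raise ValueError("need at least two hypotheses")
    cands = sorted(candidates, key=lambda t: t.features())
    responses = {
        t.features(): tuple(
            clip_response(_apply_rule(p, *t.features())) for p, _ in hypotheses
        )
        for t in cands
    }
    weights = [w for _, w in hypotheses]
    chosen: list[Trial] = []
    signature: list[tuple[int, ...]] = [() for _ in hypotheses]

    def expected_residual(extra: Optional[Trial]) -> float:
        cells: dict[tuple, list[float]] = {}
        for i, w in enumerate(weights):
            sig = signature[i]
            if extra is not None:
                sig = sig + (responses[extra.features()][i],)
            cells.setdefault(sig, []).append(w)
        total = sum(weights)
        return sum(
            (sum(ws) / total) * _entropy(ws) for ws in cells.values()
        )

    remaining = list(cands)
    for _ in range(k):
        best = min(remaining, key=lambda t: (expected_residual(t), t.features()))
        chosen.append(best)
        remaining.remove(best)
        for i in range(len(hypotheses)):
            signature[i] = signature[i] + (responses[best.features()][i],)
    return chosen


def default_generalization_tasks(counterbalanced: bool = False) -> tuple[Trial, ...]:
    """The pinned 8-task battery used by every built-in curriculum."""
    tasks = select_generalization_trials(
        default_hypothesis_set(counterbalanced), default_candidate_tasks(), k=8
    )
    return tuple(tasks)


# ---------------------------------------------------------------------------
# Synthetic participants and accuracy
# ---------------------------------------------------------------------------

class ResponseTable:
    """Counts of participants choosing each response per curriculum/phase/task.

    Backed by a tidy DataFrame with columns ``curriculum``, ``phase``,
    ``task_id``, ``response``, ``count`` (the ``n_ciy`` data of the
    log-likelihood).  ``phase`` and ``task_id`` are 0-based.
    """

    COLUMNS = ("curriculum", "phase", "task_id", "response", "count")

    def __init__(self, frame: pd.DataFrame) -> None:
        missing = set(self.COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"response table missing columns {sorted(missing)}")
        self.frame = frame.loc[:, list(self.COLUMNS)].reset_index(drop=True)

    def curricula(self) -> list[str]:
        return sorted(self.frame["curriculum"].unique())

    def counts(self, curriculum: str, n_phases: int, n_tasks: int) -> np.ndarray:
        """Counts array of shape (n_phases, n_tasks, 17) for one curriculum."""
        arr = np.zeros((n_phases, n_tasks, N_RESPONSES), dtype=float)
        sub = self.frame[self.frame["curriculum"] == curriculum]
        for _, row in sub.iterrows():
            arr[int(row["phase"]), int(row["task_id"]), int(row["response"])] += row["count"]
        return arr

    def n_participants(self, curriculum: str) -> int:
        sub = self.frame[
            (self.frame["curriculum"] == curriculum)
            & (self.frame["phase"] == self.frame["phase"].min())
            & (self.frame["task_id"] == self.frame["task_id"].min())
        ]
        return int(sub["count"].sum())

    def total_responses(self) -> int:
        return int(self.frame["count"].sum())

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ResponseTable":
        return cls(pd.read_csv(path))


def simulate_participants(
    predictions: dict[str, np.ndarray],
    n_participants: int,
    rng: np.random.Generator,
) -> ResponseTable:
    """Draw synthetic participants from model prediction distributions.

    ``predictions`` maps curriculum name to an array of shape
    (n_phases, n_tasks, 17); each (phase, task) cell gets ``n_participants``
    independent categorical draws.  This generator stands in for behavioural
    response tables and emits the same schema.
    """
    rows = []
    for curriculum in sorted(predictions):
        dists = np.asarray(predictions[curriculum], dtype=float)
        n_phases, n_tasks, n_opts = dists.shape
        if n_opts != N_RESPONSES:
            raise ValueError("predictions must have 17 response bins")
        for phase in range(n_phases):
            for task in range(n_tasks):
                p = dists[phase, task]
                p = p / p.sum()
                counts = rng.multinomial(n_participants, p)
                for response, count in enumerate(counts):
                    if count > 0:
                        rows.append(
                            {
                                "curriculum": curriculum,
                                "phase": phase,
                                "task_id": task,
                                "response": response,
                                "count": int(count),
                            }
                        )
    return ResponseTable(pd.DataFrame(rows, columns=list(ResponseTable.COLUMNS)))


def accuracy(predictions_or_responses, truths: Sequence[int]) -> float:
    """Match-to-ground-truth fraction.

    For an integer response array (n_tasks,) or (n_subjects, n_tasks): the
    fraction of responses equal to the clipped ground-truth answer.  For a
    distribution array (n_tasks, 17): the mean probability mass on the
    ground-truth answer.
    """
    truths = np.asarray(truths, dtype=int)
    arr = np.asarray(predictions_or_responses)
    if arr.ndim == 2 and arr.shape[1] == N_RESPONSES and arr.shape[0] == len(truths):
        return float(np.mean([arr[i, truths[i]] for i in range(len(truths))]))
    if arr.ndim == 1:
        return float(np.mean(arr == truths))
    if arr.ndim == 2:
        return float(np.mean(arr == truths[None, :]))
    raise ValueError("unrecognized input shape for accuracy")
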