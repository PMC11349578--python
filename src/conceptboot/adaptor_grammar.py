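"""Dynamic concept library and Pitman-Yor construct-or-fetch generation.

The generative model maintains a *concept library*: a multiset of cached
programmes (with occurrence counts) on top of the fixed primitive inventory.
Generation of a programme of a required type either **constructs** a new tree
from primitives, with probability

    lambda_1 = (alpha_0 + N * d) / (alpha_0 + |C|),

or **fetches** a cached programme of the required type, where a cached
programme ``z`` is fetched with conditional probability proportional to
``M_z - d`` (``N`` distinct cached programmes, ``|C|`` total cached tokens,
concentration ``alpha_0 > 0``, discount ``0 < d < 1``).  The more often a
programme has been cached, the more it behaves like a primitive: its internal
generation cost is overridden by its usage frequency, which is what lets a
learner bootstrap complex concepts from previously cached fragments.

Construction follows the typed recursion of the grammar: sample a head term
from a flat prior over terms whose output matches the target type, sample a
router uniformly from the ``4**n`` options for the ``n`` variables in scope,
and recurse on each argument slot under the induced type constraints.  A
fetched programme costs one unit regardless of its internal size.

``generation_probability`` is the exact analytic mirror of
``generate_programme`` and serves as the sampling oracle in tests;
``generation_failure_probability`` gives the exact mass of the (reported,
non-silent) failure outcome of a single generation attempt.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

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
    parse_programme,
    programme_to_string,
    route_variables,
    subprogrammes_with_context,
)

__all__ = [
    "GenerationBudget",
    "GenerationError",
    "ConceptLibrary",
    "lambda_construct",
    "fetch_distribution",
    "generate_programme",
    "generation_probability",
    "generation_failure_probability",
    "cache",
]

#: Deterministic term order used for flat priors.
_TERMS = [PRIMITIVES[name] for name in sorted(PRIMITIVES)]


class GenerationError(Exception):
    """A single generation attempt failed (reported, never silent)."""


@dataclass(frozen=True)
class GenerationBudget:
    """Recursion bound for construction: a node costs one level of depth."""

    max_depth: int = 2

    def __post_init__(self) -> None:
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")


@dataclass
class _Entry:
    programme: Programme
    context: tuple[str, ...]
    output: str
    count: int


class ConceptLibrary:
    """Multiset of cached programmes plus the always-available primitives.

    Entries are keyed by (canonical programme string, context types); each
    carries an occurrence count ``M_z >= 1``.  ``n_distinct`` is ``N`` and
    ``size`` is ``|C|`` in the Pitman-Yor weights.
    """

    def __init__(self, alpha0: float = 1.0, discount: float = 0.5) -> None:
        if alpha0 <= 0:
            raise ValueError("alpha0 must be > 0")
        if not (0.0 < discount < 1.0):
            raise ValueError("discount must be in (0, 1)")
        self.alpha0 = float(alpha0)
        self.discount = float(discount)
        self._entries: dict[tuple[str, tuple[str, ...]], _Entry] = {}

    # -- bookkeeping --------------------------------------------------------
    @property
    def n_distinct(self) -> int:
        return len(self._entries)

    @property
    def size(self) -> int:
        return sum(e.count for e in self._entries.values())

    def entries(self) -> list[_Entry]:
        return [self._entries[k] for k in sorted(self._entries)]

    def count_of(self, programme: Programme, context: tuple[str, ...] = (OBJ, OBJ)) -> int:
        e = self._entries.get((programme_to_string(programme), tuple(context)))
        return 0 if e is None else e.count

    def matching(self, required_type: SemType) -> list[_Entry]:
        ctx, out = required_type.inputs, required_type.output
        keys = sorted(
            k
            for k, e in self._entries.items()
            if e.context == ctx and e.output == out
        )
        return [self._entries[k] for k in keys]

    def membership_key(self) -> tuple:
        """Hashable key identifying the *set* of cached entries (counts ignored)."""
        return tuple(sorted(self._entries))

    def state_key(self) -> tuple:
        """Hashable key identifying entries together with their counts."""
        return tuple(sorted((k, e.count) for k, e in self._entries.items()))

    def copy(self) -> "ConceptLibrary":
        new = ConceptLibrary(self.alpha0, self.discount)
        new._entries = {
            k: _Entry(e.programme, e.context, e.output, e.count)
            for k, e in self._entries.items()
        }
        return new

    # -- caching ------------------------------------------------------------
    def cache(
        self,
        programmes: Iterable[Programme],
        context: tuple[str, ...] = (OBJ, OBJ),
    ) -> "ConceptLibrary":
        """Cache programmes together with all their subparts (counts increment)."""
        from .cl_core import infer_type

        for prog in programmes:
            for sub, ctx in subprogrammes_with_context(prog, tuple(context)):
                out = infer_type(sub, ctx)
                key = (programme_to_string(sub), ctx)
                entry = self._entries.get(key)
                if entry is None:
                    self._entries[key] = _Entry(sub, ctx, out, 1)
                else:
                    entry.count += 1
        return self

    # -- Pitman-Yor weights -------------------------------------------------
    def lambda_construct(self) -> float:
        return (self.alpha0 + self.n_distinct * self.discount) / (self.alpha0 + self.size)

    def fetch_weights(self, required_type: SemType) -> tuple[list[_Entry], np.ndarray]:
        support = self.matching(required_type)
        if not support:
            raise GenerationError(
                f"no cached programme of type {required_type}; caller must construct"
            )
        w = np.array([e.count - self.discount for e in support], dtype=float)
        return support, w / w.sum()

    # -- serialization ------------------------------------------------------
    def to_json(self, seed: Optional[int] = None) -> str:
        payload = {
            "alpha0": self.alpha0,
            "discount": self.discount,
            "seed": seed,
            "entries": [
                {
                    "programme": programme_to_string(e.programme),
                    "context": list(e.context),
                    "count": e.count,
                }
                for e in self.entries()
            ],
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ConceptLibrary":
        from .cl_core import infer_type

        payload = json.loads(text)
        lib = cls(alpha0=payload["alpha0"], discount=payload["discount"])
        for item in payload["entries"]:
            prog = parse_programme(item["programme"])
            ctx = tuple(item["context"])
            count = int(item["count"])
            if count < 1:
                raise ValueError("library counts must be >= 1")
            out = infer_type(prog, ctx)  # validates typing
            lib._entries[(item["programme"], ctx)] = _Entry(prog, ctx, out, count)
        return lib


# ---------------------------------------------------------------------------
# Module-level operation wrappers
# ---------------------------------------------------------------------------

def lambda_construct(library: ConceptLibrary) -> float:
    """Probability of the construct branch, (alpha0 + N d) / (alpha0 + |C|)."""
    return library.lambda_construct()


def fetch_distribution(
    library: ConceptLibrary, required_type: SemType
) -> list[tuple[Programme, float]]:
    """Conditional fetch distribution over cached programmes of the required type."""
    support, probs = library.fetch_weights(required_type)
    return [(e.programme, float(p)) for e, p in zip(support, probs)]


def cache(
    library: ConceptLibrary,
    programmes: Iterable[Programme],
    context: tuple[str, ...] = (OBJ, OBJ),
) -> ConceptLibrary:
    """Cache programmes (and their subparts) into the library, in place."""
    return library.cache(programmes, context)


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _leaf_ok(term, context: tuple[str, ...], out: str) -> bool:
    """Can ``term`` alone complete the target in this context?

    Arity-0 constants ignore the variable context; function terms must be
    fully applied by exactly the context variables.
    """
    if term.arity == 0:
        return term.signature.output == out
    if len(context) != term.arity:
        return False
    if term.signature.output == TYPE_VAR:  # identity: context type is the output
        return all(t == TYPE_VAR for t in term.signature.inputs) and context == (out,)
    return term.signature.inputs == context and term.signature.output == out


def _eligible_heads(context: tuple[str, ...], out: str, depth: int):
    """Flat-prior support for the head draw at this recursion point."""
    if depth <= 0:
        return [z for z in _TERMS if _leaf_ok(z, context, out)]
    return [z for z in _TERMS if z.signature.output in (out, TYPE_VAR)]


def _head_inputs(term, out: str) -> tuple[str, ...]:
    return tuple(out if t == TYPE_VAR else t for t in term.signature.inputs)


def generate_programme(
    library: ConceptLibrary,
    target_type: SemType,
    budget: GenerationBudget = GenerationBudget(),
    rng: Optional[np.random.Generator] = None,
) -> Programme:
    """Draw one programme of ``target_type`` by construct-or-fetch recursion.

    ``target_type`` encodes both the variable context (its inputs) and the
    required output.  Raises :class:`GenerationError` when the single attempt
    cannot be completed (unsatisfiable type at the depth limit with an empty
    cache); callers decide whether to retry or drop.
    """
    rng = np.random.default_rng() if rng is None else rng
    return _generate(library, target_type.inputs, target_type.output, budget.max_depth, rng)


def _generate(
    library: ConceptLibrary,
    context: tuple[str, ...],
    out: str,
    depth: int,
    rng: np.random.Generator,
) -> Programme:
    req = SemType(tuple(context) + (out,))
    support = library.matching(req)
    p_construct = 1.0 if not support else library.lambda_construct()
    if support and rng.random() > p_construct:
        entries, probs = library.fetch_weights(req)
        idx = rng.choice(len(entries), p=probs)
        return entries[idx].programme

    heads = _eligible_heads(context, out, depth)
    if not heads:
        if support:  # construction impossible here: fall back to fetch
            entries, probs = library.fetch_weights(req)
            idx = rng.choice(len(entries), p=probs)
            return entries[idx].programme
        raise GenerationError(
            f"unsatisfiable type {req} at depth limit with empty cache"
        )
    z = heads[int(rng.integers(len(heads)))]
    if _leaf_ok(z, context, out):
        return Leaf(z)
    # needs a node: only reachable when depth >= 1
    router = all_routers(len(context))[int(rng.integers(count_routers(len(context))))]
    left, right = route_variables(router, context)
    ins = _head_inputs(z, out)
    if z.arity == 1:
        if left:
            raise GenerationError(
                f"router {router!r} routes variables to the missing left branch of {z.name}"
            )
        arg = _generate(library, tuple(right), ins[0], depth - 1, rng)
        return Node(router, z, (arg,))
    a1 = _generate(library, tuple(left), ins[0], depth - 1, rng)
    a2 = _generate(library, tuple(right), ins[1], depth - 1, rng)
    return Node(router, z, (a1, a2))


def generation_probability(
    library: ConceptLibrary,
    programme: Programme,
    target_type: SemType = SemType((OBJ, OBJ, INT)),
    budget: GenerationBudget = GenerationBudget(),
) -> float:
    """Exact probability that a single ``generate_programme`` attempt emits
    ``programme``; 0 for programmes unrepresentable within the budget."""
    return _probability(
        library, programme, target_type.inputs, target_type.output, budget.max_depth
    )


def _probability(
    library: ConceptLibrary,
    prog: Programme,
    context: tuple[str, ...],
    out: str,
    depth: int,
) -> float:
    req = SemType(tuple(context) + (out,))
    support = library.matching(req)
    p_construct = 1.0 if not support else library.lambda_construct()
    p = 0.0
    if support:
        key = programme_to_string(prog)
        weights = np.array([e.count - library.discount for e in support], dtype=float)
        weights /= weights.sum()
        for e, w in zip(support, weights):
            if programme_to_string(e.programme) == key:
                p += (1.0 - p_construct) * float(w)
                break

    heads = _eligible_heads(context, out, depth)
    if not heads:
        if support:  # construct branch falls back to fetch
            key = programme_to_string(prog)
            weights = np.array([e.count - library.discount for e in support], dtype=float)
            weights /= weights.sum()
            for e, w in zip(support, weights):
                if programme_to_string(e.programme) == key:
                    p += p_construct * float(w)
                    break
        return p
    p_head = p_construct / len(heads)

    if isinstance(prog, Leaf):
        if prog.term in heads and _leaf_ok(prog.term, context, out):
            p += p_head
        return p
    if not isinstance(prog, Node):
        return p
    z = prog.head
    if z not in heads or _leaf_ok(z, context, out) or depth < 1:
        return p
    if len(prog.router) != len(context):
        return p
    left, right = route_variables(prog.router, context)
    ins = _head_inputs(z, out)
    p_node = p_head / count_routers(len(context))
    if z.arity == 1:
        if left:
            return p
        p_node *= _probability(library, prog.args[0], tuple(right), ins[0], depth - 1)
    else:
        p_node *= _probability(library, prog.args[0], tuple(left), ins[0], depth - 1)
        if p_node > 0.0:
            p_node *= _probability(library, prog.args[1], tuple(right), ins[1], depth - 1)
    return p + p_node


def generation_failure_probability(
    library: ConceptLibrary,
    target_type: SemType = SemType((OBJ, OBJ, INT)),
    budget: GenerationBudget = GenerationBudget(),
) -> float:
    """Exact probability that a single generation attempt fails."""
    memo: dict[tuple, float] = {}

    def pf(context: tuple[str, ...], out: str, depth: int) -> float:
        key = (context, out, depth)
        if key in memo:
            return memo[key]
        req = SemType(tuple(context) + (out,))
        support = library.matching(req)
        p_construct = 1.0 if not support else library.lambda_construct()
        heads = _eligible_heads(context, out, depth)
        if not heads:
            # construct branch falls back to fetch when possible, else hard failure
            memo[key] = 0.0 if support else p_construct
            return memo[key]
        total = 0.0
        for z in heads:
            if _leaf_ok(z, context, out):
                continue
            ins = _head_inputs(z, out)
            fail_z = 0.0
            n_routers = count_routers(len(context))
            for router in all_routers(len(context)):
                left, right = route_variables(router, context)
                if z.arity == 1:
                    if left:
                        fail_r = 1.0
                    else:
                        fail_r = pf(tuple(right), ins[0], depth - 1)
                else:
                    f1 = pf(tuple(left), ins[0], depth - 1)
                    f2 = pf(tuple(right), ins[1], depth - 1)
                    fail_r = 1.0 - (1.0 - f1) * (1.0 - f2)
                fail_z += fail_r / n_routers
            total += fail_z / len(heads)
        memo[key] = p_construct * total
        return memo[key]

    return pf(target_type.inputs, target_type.output, budget.max_depth)
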