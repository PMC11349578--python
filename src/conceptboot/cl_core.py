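"""Typed combinatory-logic DSL for causal programmes.

Causal concepts are expressed as variable-free programme trees. A programme
denotes a function from an (agent, recipient) pair of objects to an integer
number of result segments. Agents carry ``stripes`` and ``spots`` features,
recipients carry ``segments``; all features are non-negative integers.

A programme is either a *leaf* (a primitive term fully applied to the
variables routed to it) or a *node* ``[router, head, arg_1 .. arg_k]``: the
head is a primitive function term of arity ``k`` and each argument slot is
itself a programme. The router carries one letter per variable entering the
node and directs where that variable flows:

``C``
    to the first ("left") argument subtree only,
``B``
    to the last ("right") argument subtree only,
``S``
    to every argument subtree,
``I``
    to none (the variable is dropped at this node).

For a unary head there is a single argument subtree, conventionally the
"right" side, so ``[B, f, g](x)`` evaluates as ``f(g(x))`` and a unary node
with variables routed left is ill-typed. For ``n`` variables there are
``4**n`` routers.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from itertools import product as _iter_product
from typing import Callable, Iterable, Optional, Union

OBJ = "obj"
INT = "int"
TYPE_VAR = "a"  # polymorphic placeholder used by the identity term
_BASE_TYPES = (OBJ, INT, TYPE_VAR)

ROUTER_ALPHABET = "BCSI"

__all__ = [
    "OBJ",
    "INT",
    "SemType",
    "Term",
    "CausalObject",
    "Programme",
    "Leaf",
    "Node",
    "PRIMITIVES",
    "EvaluationError",
    "ProgrammeTypeError",
    "route_variables",
    "count_routers",
    "all_routers",
    "evaluate",
    "evaluate_pair",
    "infer_type",
    "well_typed",
    "subprogrammes",
    "subprogrammes_with_context",
    "programme_to_string",
    "parse_programme",
    "programme_to_dict",
    "programme_from_dict",
    "ground_truth_programme",
    "alternative_programme",
    "chunk_programme",
]


class EvaluationError(Exception):
    """A programme could not be evaluated on the supplied variables."""


class ProgrammeTypeError(Exception):
    """A programme tree violates the typing rules."""


@dataclass(frozen=True)
class SemType:
    """A function type over base types; the last component is the output."""

    components: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("a type needs at least one component")
        for c in self.components:
            if c not in _BASE_TYPES:
                raise ValueError(f"unknown base type {c!r}")

    @property
    def arity(self) -> int:
        return len(self.components) - 1

    @property
    def inputs(self) -> tuple[str, ...]:
        return self.components[:-1]

    @property
    def output(self) -> str:
        return self.components[-1]

    def __str__(self) -> str:
        return " -> ".join(self.components)

    @classmethod
    def parse(cls, text: str) -> "SemType":
        parts = tuple(p.strip() for p in re.split(r"->|→", text))
        return cls(parts)


@dataclass(frozen=True)
class CausalObject:
    """An agent (stripes/spots) or recipient (segments) stimulus object."""

    role: str = "agent"
    stripes: int = 0
    spots: int = 0
    segments: int = 0

    def __post_init__(self) -> None:
        if self.role not in ("agent", "recipient"):
            raise ValueError(f"unknown role {self.role!r}")
        for name in ("stripes", "spots", "segments"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")


def _need_obj(x, term: str) -> CausalObject:
    if not isinstance(x, CausalObject):
        raise EvaluationError(f"{term} expects an object, got {x!r}")
    return x


def _need_int(x, term: str) -> int:
    if isinstance(x, bool) or not isinstance(x, int):
        raise EvaluationError(f"{term} expects an integer, got {x!r}")
    return x


@dataclass(frozen=True)
class Term:
    """A primitive term: a name, a type signature and a pure denotation."""

    name: str
    signature: SemType
    fn: Callable = field(compare=False, repr=False)

    @property
    def arity(self) -> int:
        return self.signature.arity

    def __str__(self) -> str:
        return self.name


def _make_primitives() -> dict[str, Term]:
    t_feature = SemType((OBJ, INT))
    t_binop = SemType((INT, INT, INT))
    prims = [
        Term("getStripe", t_feature, lambda o: _need_obj(o, "getStripe").stripes),
        Term("getSpot", t_feature, lambda o: _need_obj(o, "getSpot").spots),
        Term("getSegment", t_feature, lambda o: _need_obj(o, "getSegment").segments),
        Term(
            "setSegment",
            SemType((OBJ, INT, OBJ)),
            lambda o, n: replace(_need_obj(o, "setSegment"), segments=max(int(n), 0)),
        ),
        Term("add", t_binop, lambda x, y: _need_int(x, "add") + _need_int(y, "add")),
        Term("sub", t_binop, lambda x, y: _need_int(x, "sub") - _need_int(y, "sub")),
        Term("mult", t_binop, lambda x, y: _need_int(x, "mult") * _need_int(y, "mult")),
        Term("I", SemType((TYPE_VAR, TYPE_VAR)), lambda x: x),
    ]
    for k in range(4):
        prims.append(Term(str(k), SemType((INT,)), (lambda v: (lambda: v))(k)))
    return {p.name: p for p in prims}


#: The full primitive inventory of the DSL.
PRIMITIVES: dict[str, Term] = _make_primitives()


# ---------------------------------------------------------------------------
# Routers
# ---------------------------------------------------------------------------

def route_variables(router: str, variables: Iterable) -> tuple[list, list]:
    """Split ``variables`` into (left-bound, right-bound) lists per the router.

    Per position: ``B`` right only, ``C`` left only, ``S`` both, ``I`` neither.
    Order is preserved within each side.
    """
    variables = list(variables)
    if len(router) != len(variables):
        raise ValueError(
            f"router {router!r} has length {len(router)}, "
            f"but {len(variables)} variables were supplied"
        )
    left: list = []
    right: list = []
    for ch, v in zip(router, variables):
        if ch == "B":
            right.append(v)
        elif ch == "C":
            left.append(v)
        elif ch == "S":
            left.append(v)
            right.append(v)
        elif ch == "I":
            pass
        else:
            raise ValueError(f"unknown router letter {ch!r}")
    return left, right


def count_routers(n_variables: int) -> int:
    """Number of distinct routers for ``n_variables`` entering a node: 4**n."""
    if n_variables < 0:
        raise ValueError("n_variables must be non-negative")
    return 4 ** n_variables


def all_routers(n_variables: int) -> list[str]:
    """All ``4**n`` router strings for ``n`` variables, in lexicographic order."""
    if n_variables < 0:
        raise ValueError("n_variables must be non-negative")
    return ["".join(p) for p in _iter_product(sorted(ROUTER_ALPHABET), repeat=n_variables)]


# ---------------------------------------------------------------------------
# Programme trees
# ---------------------------------------------------------------------------

class Programme:
    """Base class for programme trees (see :class:`Leaf` and :class:`Node`)."""

    @property
    def depth(self) -> int:  # pragma: no cover - overridden
        raise NotImplementedError

    def __str__(self) -> str:
        return programme_to_string(self)


@dataclass(frozen=True)
class Leaf(Programme):
    term: Term

    @property
    def depth(self) -> int:
        return 0


@dataclass(frozen=True)
class Node(Programme):
    router: str
    head: Term
    args: tuple[Programme, ...]

    def __post_init__(self) -> None:
        if self.head.arity < 1:
            raise ProgrammeTypeError(f"node head {self.head.name} must be a function term")
        if len(self.args) != self.head.arity:
            raise ProgrammeTypeError(
                f"head {self.head.name} has arity {self.head.arity}, "
                f"got {len(self.args)} argument subtrees"
            )
        for ch in self.router:
            if ch not in ROUTER_ALPHABET:
                raise ProgrammeTypeError(f"unknown router letter {ch!r}")

    @property
    def depth(self) -> int:
        return 1 + max(a.depth for a in self.args)


def _head_io(head: Term, out: str) -> tuple[tuple[str, ...], str]:
    """Input/output types of a head with the type variable bound to ``out``."""
    ins = tuple(out if t == TYPE_VAR else t for t in head.signature.inputs)
    o = out if head.signature.output == TYPE_VAR else head.signature.output
    return ins, o


def evaluate(programme: Programme, variables: tuple) -> Union[int, CausalObject]:
    """Evaluate a programme on a tuple of variables (objects or integers).

    Leaves of arity zero (integer constants) ignore the variables; every other
    leaf consumes exactly the variables routed to it. A node routes its
    variables to its argument subtrees and applies its head to their values.
    """
    if isinstance(programme, Leaf):
        term = programme.term
        if term.arity == 0:
            return term.fn()
        if len(variables) != term.arity:
            raise EvaluationError(
                f"leaf {term.name} expects {term.arity} variable(s), got {len(variables)}"
            )
        return term.fn(*variables)
    if not isinstance(programme, Node):
        raise EvaluationError(f"not a programme: {programme!r}")
    left, right = route_variables(programme.router, variables)
    head = programme.head
    try:
        if head.arity == 1:
            if left:
                raise EvaluationError(
                    f"unary node {head.name} received left-routed variables "
                    f"(router {programme.router!r})"
                )
            return head.fn(evaluate(programme.args[0], tuple(right)))
        v1 = evaluate(programme.args[0], tuple(left))
        v2 = evaluate(programme.args[1], tuple(right))
        return head.fn(v1, v2)
    except EvaluationError as err:
        raise EvaluationError(f"at node ({programme}): {err}") from None


def evaluate_pair(programme: Programme, agent: CausalObject, recipient: CausalObject) -> int:
    """Evaluate a two-variable integer-valued programme on an (agent, recipient) pair."""
    value = evaluate(programme, (agent, recipient))
    if isinstance(value, bool) or not isinstance(value, int):
        raise EvaluationError(f"programme produced a non-integer result: {value!r}")
    return value


def infer_type(programme: Programme, context: tuple[str, ...]) -> str:
    """Output base type of ``programme`` in a variable-type ``context``.

    Raises :class:`ProgrammeTypeError` on any violation.
    """
    if isinstance(programme, Leaf):
        term = programme.term
        if term.arity == 0:
            return term.signature.output
        if len(context) != term.arity:
            raise ProgrammeTypeError(
                f"leaf {term.name} expects {term.arity} variable(s), context has {len(context)}"
            )
        if term.signature.inputs == tuple(context):
            return term.signature.output
        if all(t == TYPE_VAR for t in term.signature.inputs):  # polymorphic identity
            if len(set(context)) == 1:
                return context[0]
        raise ProgrammeTypeError(f"leaf {term.name} does not accept context {context}")
    if not isinstance(programme, Node):
        raise ProgrammeTypeError(f"not a programme: {programme!r}")
    if len(programme.router) != len(context):
        raise ProgrammeTypeError(
            f"router {programme.router!r} does not match context of size {len(context)}"
        )
    left, right = route_variables(programme.router, context)
    head = programme.head
    if head.arity == 1:
        if left:
            raise ProgrammeTypeError(
                f"unary node {head.name} received left-routed variables"
            )
        argt = infer_type(programme.args[0], tuple(right))
        if head.signature.inputs[0] == TYPE_VAR:
            return argt
        if argt != head.signature.inputs[0]:
            raise ProgrammeTypeError(
                f"{head.name} expects {head.signature.inputs[0]}, argument has {argt}"
            )
        return head.signature.output
    t1 = infer_type(programme.args[0], tuple(left))
    t2 = infer_type(programme.args[1], tuple(right))
    ins, out = _head_io(head, head.signature.output)
    if (t1, t2) != ins:
        raise ProgrammeTypeError(
            f"{head.name} expects {ins}, arguments have {(t1, t2)}"
        )
    return out


def well_typed(programme: Programme, context: tuple[str, ...] = (OBJ, OBJ)) -> bool:
    try:
        infer_type(programme, context)
        return True
    except ProgrammeTypeError:
        return False


def subprogrammes(programme: Programme) -> list[Programme]:
    """All complete subtrees (the programme itself, nodes and leaf arguments),
    de-duplicated by structural equality, in pre-order."""
    seen: dict[str, Programme] = {}

    def visit(p: Programme) -> None:
        key = programme_to_string(p)
        if key not in seen:
            seen[key] = p
        if isinstance(p, Node):
            for a in p.args:
                visit(a)

    visit(programme)
    return list(seen.values())


def subprogrammes_with_context(
    programme: Programme, context: tuple[str, ...]
) -> list[tuple[Programme, tuple[str, ...]]]:
    """Subtrees paired with the variable-type context in which each occurs."""
    seen: dict[tuple[str, tuple[str, ...]], tuple[Programme, tuple[str, ...]]] = {}

    def visit(p: Programme, ctx: tuple[str, ...]) -> None:
        key = (programme_to_string(p), ctx)
        if key not in seen:
            seen[key] = (p, ctx)
        if isinstance(p, Node):
            left, right = route_variables(p.router, ctx)
            if p.head.arity == 1:
                visit(p.args[0], tuple(right))
            else:
                visit(p.args[0], tuple(left))
                visit(p.args[1], tuple(right))

    visit(programme, context)
    return list(seen.values())


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

_EMPTY_ROUTER_MARK = "."


def programme_to_string(programme: Programme) -> str:
    """Canonical prefix notation, e.g. ``(SC sub (CB mult getStripe getSegment) getSpot)``.

    A node with no incoming variables prints its router as ``.``.
    """
    if isinstance(programme, Leaf):
        return programme.term.name
    router = programme.router or _EMPTY_ROUTER_MARK
    parts = [router, programme.head.name]
    parts.extend(programme_to_string(a) for a in programme.args)
    return "(" + " ".join(parts) + ")"


def parse_programme(text: str) -> Programme:
    """Parse canonical prefix notation back into a programme tree."""
    tokens = text.replace("(", " ( ").replace(")", " ) ").split()
    pos = 0

    def parse() -> Programme:
        nonlocal pos
        if pos >= len(tokens):
            raise ValueError("unexpected end of programme text")
        tok = tokens[pos]
        pos += 1
        if tok == "(":
            router = tokens[pos]
            pos += 1
            if router == _EMPTY_ROUTER_MARK:
                router = ""
            head_name = tokens[pos]
            pos += 1
            if head_name not in PRIMITIVES:
                raise ValueError(f"unknown term {head_name!r}")
            args = []
            while tokens[pos] != ")":
                args.append(parse())
            pos += 1
            return Node(router, PRIMITIVES[head_name], tuple(args))
        if tok == ")":
            raise ValueError("unbalanced parentheses")
        if tok not in PRIMITIVES:
            raise ValueError(f"unknown term {tok!r}")
        return Leaf(PRIMITIVES[tok])

    out = parse()
    if pos != len(tokens):
        raise ValueError("trailing tokens after programme")
    return out


def programme_to_dict(programme: Programme) -> dict:
    """JSON-friendly tree form; round-trips with :func:`programme_from_dict`."""
    if isinstance(programme, Leaf):
        return {"term": programme.term.name}
    return {
        "router": programme.router,
        "head": programme.head.name,
        "args": [programme_to_dict(a) for a in programme.args],
    }


def programme_from_dict(data: dict) -> Programme:
    if "term" in data:
        return Leaf(PRIMITIVES[data["term"]])
    return Node(
        data["router"],
        PRIMITIVES[data["head"]],
        tuple(programme_from_dict(a) for a in data["args"]),
    )


# ---------------------------------------------------------------------------
# Canonical concepts of the causal task
# ---------------------------------------------------------------------------

def ground_truth_programme(counterbalanced: bool = False) -> Programme:
    """stripe(A) x R - spot(A); counterbalanced swaps the stripe/spot roles."""
    if counterbalanced:
        return parse_programme("(SC sub (CB mult getSpot getSegment) getStripe)")
    return parse_programme("(SC sub (CB mult getStripe getSegment) getSpot)")


def alternative_programme(counterbalanced: bool = False) -> Programme:
    """stripe(A) x (R - spot(A)), the equally complex data-consistent alternative."""
    if counterbalanced:
        return parse_programme("(SB mult getSpot (BC sub getSegment getStripe))")
    return parse_programme("(SB mult getStripe (BC sub getSegment getSpot))")


def chunk_programme(counterbalanced: bool = False) -> Programme:
    """stripe(A) x R, the reusable sub-concept (the bootstrap 'chunk')."""
    if counterbalanced:
        return parse_programme("(CB mult getSpot getSegment)")
    return parse_programme("(CB mult getStripe getSegment)")
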