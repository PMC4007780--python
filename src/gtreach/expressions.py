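"""Expression algebras for guarded transitions.

Two small algebras make up a guard:

* :class:`CondExpr` — Boolean formulas over places (variables), combined
  with ``and`` / ``or`` / ``not`` plus the constants ``true`` / ``false``.
  A condition is evaluated against a total place assignment (a state).

* :class:`EventExpr` — signal-algebra expressions over named event atoms,
  combined with ``default`` (merge of occurrences: present when either
  operand is present) and ``when`` (selection: present when the left event
  is present *and* the right-hand condition holds on the current state).

Both are immutable trees.  ``And``/``Or`` are n-ary for convenience when
compiling reactions; parsing produces the same nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping


# ---------------------------------------------------------------------------
# Conditions


class CondExpr:
    """Base class for condition (state-formula) nodes."""

    __slots__ = ()

    def eval(self, state: Mapping[str, bool]) -> bool:
        raise NotImplementedError

    def places(self) -> set[str]:
        """All place names referenced by this formula."""
        return {n.name for n in self.walk() if isinstance(n, Var)}

    def walk(self) -> Iterator["CondExpr"]:
        raise NotImplementedError

    # Parenthesised text form, re-parseable by gtreach.io
    def unparse(self) -> str:
        raise NotImplementedError

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.unparse()


@dataclass(frozen=True, slots=True)
class Const(CondExpr):
    value: bool

    def eval(self, state: Mapping[str, bool]) -> bool:
        return self.value

    def walk(self):
        yield self

    def unparse(self) -> str:
        return "true" if self.value else "false"


TRUE = Const(True)
FALSE = Const(False)


@dataclass(frozen=True, slots=True)
class Var(CondExpr):
    name: str

    def eval(self, state: Mapping[str, bool]) -> bool:
        try:
            return state[self.name]
        except KeyError:
            raise KeyError(f"place {self.name!r} not in state") from None

    def walk(self):
        yield self

    def unparse(self) -> str:
        return self.name


@dataclass(frozen=True, slots=True)
class Not(CondExpr):
    child: CondExpr

    def eval(self, state: Mapping[str, bool]) -> bool:
        return not self.child.eval(state)

    def walk(self):
        yield self
        yield from self.child.walk()

    def unparse(self) -> str:
        return f"not {self.child.unparse()}" if isinstance(
            self.child, (Var, Const)
        ) else f"not ({self.child.unparse()})"


@dataclass(frozen=True, slots=True)
class And(CondExpr):
    children: tuple[CondExpr, ...]

    def __init__(self, *children: CondExpr):
        if len(children) == 1 and isinstance(children[0], (tuple, list)):
            children = tuple(children[0])
        object.__setattr__(self, "children", tuple(children))

    def eval(self, state: Mapping[str, bool]) -> bool:
        return all(c.eval(state) for c in self.children)

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()

    def unparse(self) -> str:
        return "(" + " and ".join(c.unparse() for c in self.children) + ")"


@dataclass(frozen=True, slots=True)
class Or(CondExpr):
    children: tuple[CondExpr, ...]

    def __init__(self, *children: CondExpr):
        if len(children) == 1 and isinstance(children[0], (tuple, list)):
            children = tuple(children[0])
        object.__setattr__(self, "children", tuple(children))

    def eval(self, state: Mapping[str, bool]) -> bool:
        return any(c.eval(state) for c in self.children)

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()

    def unparse(self) -> str:
        return "(" + " or ".join(c.unparse() for c in self.children) + ")"


def conjoin(terms: Iterable[CondExpr]) -> CondExpr:
    """AND a sequence of conditions, simplifying the empty and unit cases."""
    terms = [t for t in terms if t is not TRUE]
    if not terms:
        return TRUE
    if any(t is FALSE for t in terms):
        return FALSE
    if len(terms) == 1:
        return terms[0]
    return And(*terms)


def normalize_cond(expr: CondExpr) -> CondExpr:
    """Canonical form: flatten nested And/Or, sort and deduplicate children.

    Used when merging models so that syntactically shuffled but identical
    conditions compare equal.
    """
    if isinstance(expr, (Var, Const)):
        return expr
    if isinstance(expr, Not):
        return Not(normalize_cond(expr.child))
    cls = type(expr)
    flat: list[CondExpr] = []
    for c in expr.children:
        c = normalize_cond(c)
        if isinstance(c, cls):
            flat.extend(c.children)
        else:
            flat.append(c)
    uniq = sorted({c.unparse(): c for c in flat}.items())
    kids = tuple(c for _, c in uniq)
    if len(kids) == 1:
        return kids[0]
    return cls(*kids)


# ---------------------------------------------------------------------------
# Events


class EventExpr:
    """Base class for event-algebra nodes."""

    __slots__ = ()

    def present(self, active: frozenset | set, state: Mapping[str, bool]) -> bool:
        """Presence at one step given the present atoms and the state."""
        raise NotImplementedError

    def atoms(self) -> set[str]:
        raise NotImplementedError

    def condition_places(self) -> set[str]:
        """Places referenced by ``when`` conditions nested in this event."""
        raise NotImplementedError

    def unparse(self) -> str:
        raise NotImplementedError

    def __str__(self) -> str:  # pragma: no cover
        return self.unparse()


@dataclass(frozen=True, slots=True)
class EventAtom(EventExpr):
    name: str

    def __post_init__(self):
        if not self.name:
            raise ValueError("event atom name must be nonempty")

    def present(self, active, state) -> bool:
        return self.name in active

    def atoms(self) -> set[str]:
        return {self.name}

    def condition_places(self) -> set[str]:
        return set()

    def unparse(self) -> str:
        return self.name


@dataclass(frozen=True, slots=True)
class Default(EventExpr):
    """Merge: present when either operand is present."""

    left: EventExpr
    right: EventExpr

    def present(self, active, state) -> bool:
        return self.left.present(active, state) or self.right.present(active, state)

    def atoms(self) -> set[str]:
        return self.left.atoms() | self.right.atoms()

    def condition_places(self) -> set[str]:
        return self.left.condition_places() | self.right.condition_places()

    def unparse(self) -> str:
        return f"({self.left.unparse()} default {self.right.unparse()})"


@dataclass(frozen=True, slots=True)
class When(EventExpr):
    """Selection: present when the event is present and the condition holds."""

    event: EventExpr
    cond: CondExpr

    def present(self, active, state) -> bool:
        return self.event.present(active, state) and self.cond.eval(state)

    def atoms(self) -> set[str]:
        return self.event.atoms()

    def condition_places(self) -> set[str]:
        return self.cond.places()

    def unparse(self) -> str:
        return f"({self.event.unparse()} when {self.cond.unparse()})"


def merge_events(events: Iterable[EventExpr]) -> EventExpr:
    """Combine events with ``default``, deduplicating identical operands.

    The operands are ordered by their text form so the result is canonical.
    """
    uniq = sorted({e.unparse(): e for e in events}.items())
    exprs = [e for _, e in uniq]
    if not exprs:
        raise ValueError("cannot merge zero events")
    out = exprs[0]
    for e in exprs[1:]:
        out = Default(out, e)
    return out
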