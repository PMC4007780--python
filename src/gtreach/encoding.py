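"""Tseitin compilation of model dynamics into CNF, unrolled over a horizon.

Bounded model checking reduces "can this property become true within n
steps?" to propositional satisfiability: one Boolean variable per (place,
step) and per (event atom, step), frame-complete constraints tying step
k+1 to step k via the evolution rule

    A@{k+1}  <->  h_in@k  or  (not h_out@k  and  A@k)

with the transition events ``h when (A and C)`` expressed through Tseitin
auxiliary variables (linear size).  Step 0 forces every non-frontier place
False and leaves frontier variables free — the SAT search space is exactly
the allocation of initialization places and event timing.

Variable numbering is reproducible: place variables first (sorted by name,
then step), then event variables, then auxiliaries in creation order, so
DIMACS output is bit-stable for a fixed (model, horizon, options).

An optional optimization pass performs constant propagation (folding
``true``/``false`` and the known all-False non-frontier step-0 values is
left to the solver; here folding is structural) and common-subexpression
elimination (structural hashing of auxiliary definitions).  It never
changes satisfiability, only formula size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .expressions import (
    And,
    CondExpr,
    Const,
    Default,
    EventAtom,
    EventExpr,
    Not,
    Or,
    Var,
    When,
)
from .model import GuardedTransitionModel


class VarMap:
    """Bijection (kind, name, step) -> positive DIMACS variable index."""

    def __init__(self, model: GuardedTransitionModel, horizon: int):
        self.horizon = horizon
        self.place_names = sorted(model.place_set)
        self.event_names = sorted(model.events)
        self._fwd: dict[tuple[str, str, int], int] = {}
        self._rev: dict[int, tuple[str, str, int]] = {}
        nxt = 1
        for p in self.place_names:
            for k in range(horizon + 1):
                self._fwd[("place", p, k)] = nxt
                self._rev[nxt] = ("place", p, k)
                nxt += 1
        for e in self.event_names:
            for k in range(horizon):
                self._fwd[("event", e, k)] = nxt
                self._rev[nxt] = ("event", e, k)
                nxt += 1
        self._next = nxt

    def place(self, name: str, step: int) -> int:
        return self._fwd[("place", name, step)]

    def event(self, name: str, step: int) -> int:
        return self._fwd[("event", name, step)]

    def new_aux(self, label: str = "t") -> int:
        v = self._next
        self._next += 1
        key = ("aux", f"{label}_{v}", -1)
        self._fwd[key] = v
        self._rev[v] = key
        return v

    def decode(self, var: int) -> tuple[str, str, int]:
        return self._rev[var]

    @property
    def num_vars(self) -> int:
        return self._next - 1

    def to_json(self) -> str:
        entries = [
            {"kind": k, "name": n, "step": s, "var": v}
            for (k, n, s), v in sorted(self._fwd.items(), key=lambda kv: kv[1])
        ]
        return json.dumps({"horizon": self.horizon, "variables": entries}, indent=1)


class Encoder:
    """Clause emitter with Tseitin auxiliaries and optional simplification."""

    def __init__(self, varmap: VarMap, optimize: bool = True):
        self.varmap = varmap
        self.optimize = optimize
        self.clauses: list[list[int]] = []
        self._cache: dict[tuple, int] = {}

    # Literal domain: int DIMACS literal, or the Python bools for constants.

    def _const_lit(self, value: bool):
        if self.optimize:
            return value
        v = self.varmap.new_aux("const")
        self.clauses.append([v] if value else [-v])
        return v

    @staticmethod
    def _neg(lit):
        if lit is True:
            return False
        if lit is False:
            return True
        return -lit

    def _define_and(self, lits: list) -> int | bool:
        if self.optimize:
            if any(l is False for l in lits):
                return False
            lits = [l for l in lits if l is not True]
            lits = list(dict.fromkeys(lits))
            if not lits:
                return True
            if len(lits) == 1:
                return lits[0]
            key = ("and", tuple(sorted(lits)))
            if key in self._cache:
                return self._cache[key]
        v = self.varmap.new_aux("and")
        for l in lits:
            if l is True:
                continue
            if l is False:
                self.clauses.append([-v])
                break
            self.clauses.append([-v, l])
        else:
            self.clauses.append([v] + [self._neg(l) for l in lits if isinstance(l, int)])
        if self.optimize:
            self._cache[key] = v
        return v

    def _define_or(self, lits: list) -> int | bool:
        if self.optimize:
            if any(l is True for l in lits):
                return True
            lits = [l for l in lits if l is not False]
            lits = list(dict.fromkeys(lits))
            if not lits:
                return False
            if len(lits) == 1:
                return lits[0]
            key = ("or", tuple(sorted(lits)))
            if key in self._cache:
                return self._cache[key]
        v = self.varmap.new_aux("or")
        for l in lits:
            if l is False:
                continue
            if l is True:
                self.clauses.append([v])
                break
            self.clauses.append([v, -l])
        else:
            self.clauses.append([-v] + [l for l in lits if isinstance(l, int)])
        if self.optimize:
            self._cache[key] = v
        return v

    # -- expression compilation -----------------------------------------

    def cond_lit(self, expr: CondExpr, step: int):
        if isinstance(expr, Const):
            return self._const_lit(expr.value)
        if isinstance(expr, Var):
            return self.varmap.place(expr.name, step)
        if isinstance(expr, Not):
            return self._neg(self.cond_lit(expr.child, step))
        if isinstance(expr, And):
            return self._define_and([self.cond_lit(c, step) for c in expr.children])
        if isinstance(expr, Or):
            return self._define_or([self.cond_lit(c, step) for c in expr.children])
        raise TypeError(f"unknown condition node {type(expr).__name__}")

    def event_lit(self, expr: EventExpr, step: int):
        if isinstance(expr, EventAtom):
            return self.varmap.event(expr.name, step)
        if isinstance(expr, Default):
            return self._define_or(
                [self.event_lit(expr.left, step), self.event_lit(expr.right, step)]
            )
        if isinstance(expr, When):
            return self._define_and(
                [self.event_lit(expr.event, step), self.cond_lit(expr.cond, step)]
            )
        raise TypeError(f"unknown event node {type(expr).__name__}")

    def assert_equiv(self, var: int, rhs) -> None:
        """Add ``var <-> rhs`` where rhs is a literal or constant."""
        if rhs is True:
            self.clauses.append([var])
        elif rhs is False:
            self.clauses.append([-var])
        else:
            self.clauses.append([-var, rhs])
            self.clauses.append([var, -rhs])

    def assert_true(self, lit) -> None:
        if lit is True:
            return
        if lit is False:
            self.clauses.append([])  # unsatisfiable
        else:
            self.clauses.append([lit])


def tseitin(expr, varmap: VarMap, step: int, optimize: bool = True):
    """Compile one expression at one step.

    Returns ``(literal, clauses)`` where the literal is equisatisfiable
    with the expression (constants may come back as Python bools when
    optimization folds them away).  Works for both condition formulas and
    event-presence expressions.
    """
    enc = Encoder(varmap, optimize=optimize)
    if isinstance(expr, EventExpr):
        lit = enc.event_lit(expr, step)
    else:
        lit = enc.cond_lit(expr, step)
    return lit, enc.clauses


@dataclass
class UnrolledCNF:
    """CNF over steps 0..n with its variable map; decodes back to scenarios."""

    model: GuardedTransitionModel
    horizon: int
    varmap: VarMap
    encoder: Encoder
    strict: bool
    optimize: bool

    @property
    def clauses(self) -> list[list[int]]:
        return self.encoder.clauses

    @property
    def num_vars(self) -> int:
        return self.varmap.num_vars

    def decode_scenario(self, assignment: dict[int, bool]):
        from .model import Scenario

        frontier = self.model.frontier()
        f = {
            p
            for p in frontier
            if assignment.get(self.varmap.place(p, 0), False)
        }
        timing = []
        for k in range(self.horizon):
            timing.append(
                frozenset(
                    e
                    for e in self.varmap.event_names
                    if assignment.get(self.varmap.event(e, k), False)
                )
            )
        return Scenario(frozenset(f), tuple(timing))

    def add_property(self, prop: CondExpr, mode: str = "any-step") -> None:
        enc = self.encoder
        if mode == "final-step":
            enc.assert_true(enc.cond_lit(prop, self.horizon))
        elif mode == "any-step":
            lits = [enc.cond_lit(prop, k) for k in range(self.horizon + 1)]
            enc.assert_true(enc._define_or(lits))
        else:
            raise ValueError(f"unknown property mode {mode!r}")

    def activation_indicators(self) -> dict[str, int]:
        """One variable per place, constrained to 'ever True over 0..n'.

        Used to enumerate trajectories with pairwise-distinct activated
        sets via blocking clauses.
        """
        enc = self.encoder
        out: dict[str, int] = {}
        for p in self.varmap.place_names:
            lits = [self.varmap.place(p, k) for k in range(self.horizon + 1)]
            v = self.varmap.new_aux(f"act_{p}")
            for l in lits:
                enc.clauses.append([v, -l])
            enc.clauses.append([-v] + lits)
            out[p] = v
        return out

    def to_dimacs(self) -> str:
        lines = [f"p cnf {self.num_vars} {len(self.clauses)}"]
        lines += [" ".join(map(str, c)) + " 0" for c in self.clauses]
        return "\n".join(lines) + "\n"


def encode_dynamics(
    model: GuardedTransitionModel, enc: Encoder, step: int, strict: bool = True
) -> None:
    """Constraints linking step and step+1 (one application of the rule)."""
    vm = enc.varmap
    tr_lits = {}
    for i, tr in enumerate(model.transitions):
        h = enc.event_lit(tr.event, step)
        a = vm.place(tr.source, step)
        c = enc.cond_lit(tr.condition, step)
        tr_lits[i] = enc._define_and([h, a, c])
    for p in vm.place_names:
        h_in = enc._define_or(
            [tr_lits[i] for i, tr in enumerate(model.transitions) if tr.target == p]
        )
        h_out = enc._define_or(
            [tr_lits[i] for i, tr in enumerate(model.transitions) if tr.source == p]
        )
        keep = enc._define_and([Encoder._neg(h_out), vm.place(p, step)])
        rhs = enc._define_or([h_in, keep])
        enc.assert_equiv(vm.place(p, step + 1), rhs)
    if strict and vm.event_names:
        enc.clauses.append([vm.event(e, step) for e in vm.event_names])


def unroll(
    model: GuardedTransitionModel,
    horizon: int,
    strict: bool = True,
    optimize: bool = True,
) -> UnrolledCNF:
    """Full bounded encoding: free frontier at step 0, dynamics for 0..n-1."""
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    vm = VarMap(model, horizon)
    enc = Encoder(vm, optimize=optimize)
    frontier = model.frontier()
    for p in vm.place_names:
        if p not in frontier:
            enc.clauses.append([-vm.place(p, 0)])
    for k in range(horizon):
        encode_dynamics(model, enc, k, strict=strict)
    return UnrolledCNF(model, horizon, vm, enc, strict, optimize)
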