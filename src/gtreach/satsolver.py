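"""A small CDCL SAT solver.

Conflict-driven clause learning with two watched literals, first-UIP
conflict analysis, VSIDS-style variable activity and phase saving.  The
default saved phase is False, which biases found witnesses toward sparse
activations — convenient starting points for scenario shrinking.

Literals are nonzero integers in the DIMACS convention: variable ``v`` is
the positive literal ``v``, its negation ``-v``.  The solver is built for
the bounded-reachability formulas this package produces (hundreds to a few
thousand variables); it is a complete solver, just not an industrial one.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Sequence


class SolverError(RuntimeError):
    pass


class Solver:
    def __init__(self, num_vars: int = 0):
        self.nvars = num_vars
        self.clauses: list[list[int]] = []
        self._trivially_unsat = False

    def new_var(self) -> int:
        self.nvars += 1
        return self.nvars

    def add_clause(self, lits: Iterable[int]) -> None:
        clause = list(dict.fromkeys(lits))
        for l in clause:
            if l == 0:
                raise SolverError("literal 0 is not allowed")
            if abs(l) > self.nvars:
                self.nvars = abs(l)
        if any(-l in clause for l in clause):
            return  # tautology
        if not clause:
            self._trivially_unsat = True
        self.clauses.append(clause)

    # ------------------------------------------------------------------

    def solve(self) -> bool:
        """Decide satisfiability; on True, read values via :meth:`value`."""
        if self._trivially_unsat:
            return False
        n = self.nvars
        self._assign = [0] * (n + 1)  # 0 unassigned, +1 True, -1 False
        self._level = [0] * (n + 1)
        self._reason: list[list[int] | None] = [None] * (n + 1)
        self._trail: list[int] = []
        self._trail_lim: list[int] = []
        self._qhead = 0
        self._phase = [False] * (n + 1)
        self._activity = [0.0] * (n + 1)
        self._var_inc = 1.0
        self._watches: dict[int, list[list[int]]] = defaultdict(list)

        self._db: list[list[int]] = []
        for c in self.clauses:
            if len(c) == 1:
                if not self._enqueue(c[0], None):
                    return False
            else:
                self._db.append(c)
                self._watches[c[0]].append(c)
                self._watches[c[1]].append(c)

        while True:
            confl = self._propagate()
            if confl is not None:
                if not self._trail_lim:
                    return False
                learnt, bt_level = self._analyze(confl)
                self._backtrack(bt_level)
                if len(learnt) == 1:
                    if not self._enqueue(learnt[0], None):
                        return False
                else:
                    self._db.append(learnt)
                    self._watches[learnt[0]].append(learnt)
                    self._watches[learnt[1]].append(learnt)
                    self._enqueue(learnt[0], learnt)
                self._var_inc *= 1.05
                if self._var_inc > 1e100:
                    self._activity = [a / 1e100 for a in self._activity]
                    self._var_inc /= 1e100
            else:
                v = self._pick_branch_var()
                if v is None:
                    return True
                self._trail_lim.append(len(self._trail))
                self._enqueue(v if self._phase[v] else -v, None)

    def value(self, var: int) -> bool:
        return self._assign[var] > 0

    def model(self) -> dict[int, bool]:
        return {v: self._assign[v] > 0 for v in range(1, self.nvars + 1)}

    # -- internals ------------------------------------------------------

    def _enqueue(self, lit: int, reason: list[int] | None) -> bool:
        v = abs(lit)
        val = self._assign[v]
        if val != 0:
            return (val > 0) == (lit > 0)
        self._assign[v] = 1 if lit > 0 else -1
        self._level[v] = len(self._trail_lim)
        self._reason[v] = reason
        self._trail.append(lit)
        return True

    def _propagate(self) -> list[int] | None:
        while self._qhead < len(self._trail):
            lit = self._trail[self._qhead]
            self._qhead += 1
            false_lit = -lit
            watchers = self._watches[false_lit]
            i = 0
            while i < len(watchers):
                clause = watchers[i]
                # normalise: watched literals sit at positions 0 and 1
                if clause[0] == false_lit:
                    clause[0], clause[1] = clause[1], clause[0]
                first = clause[0]
                a0 = self._assign[abs(first)]
                if a0 != 0 and (a0 > 0) == (first > 0):
                    i += 1  # clause already satisfied
                    continue
                moved = False
                for k in range(2, len(clause)):
                    lk = clause[k]
                    ak = self._assign[abs(lk)]
                    if ak == 0 or (ak > 0) == (lk > 0):
                        clause[1], clause[k] = clause[k], clause[1]
                        self._watches[clause[1]].append(clause)
                        watchers[i] = watchers[-1]
                        watchers.pop()
                        moved = True
                        break
                if moved:
                    continue
                # unit or conflicting
                if a0 != 0:  # first is False -> conflict
                    self._qhead = len(self._trail)
                    return clause
                self._enqueue(first, clause)
                i += 1
        return None

    def _analyze(self, confl: list[int]) -> tuple[list[int], int]:
        learnt: list[int] = []
        seen = [False] * (self.nvars + 1)
        counter = 0
        p: int | None = None
        idx = len(self._trail) - 1
        cur_level = len(self._trail_lim)
        clause = confl
        while True:
            for q in clause:
                if p is not None and q == p:
                    continue
                v = abs(q)
                if not seen[v] and self._level[v] > 0:
                    seen[v] = True
                    self._activity[v] += self._var_inc
                    if self._level[v] == cur_level:
                        counter += 1
                    else:
                        learnt.append(q)
            while not seen[abs(self._trail[idx])]:
                idx -= 1
            p = self._trail[idx]
            idx -= 1
            v = abs(p)
            seen[v] = False
            counter -= 1
            if counter == 0:
                break
            clause = self._reason[v] or []
        learnt.insert(0, -p)
        if len(learnt) == 1:
            bt = 0
        else:
            # second-highest level among learnt literals
            levels = sorted((self._level[abs(l)] for l in learnt[1:]), reverse=True)
            bt = levels[0]
            # move a literal of that level into watch position 1
            for k in range(1, len(learnt)):
                if self._level[abs(learnt[k])] == bt:
                    learnt[1], learnt[k] = learnt[k], learnt[1]
                    break
        return learnt, bt

    def _backtrack(self, level: int) -> None:
        if len(self._trail_lim) <= level:
            return
        bound = self._trail_lim[level]
        for lit in self._trail[bound:]:
            v = abs(lit)
            self._phase[v] = lit > 0
            self._assign[v] = 0
            self._reason[v] = None
        del self._trail[bound:]
        del self._trail_lim[level:]
        self._qhead = len(self._trail)

    def _pick_branch_var(self) -> int | None:
        best = None
        best_act = -1.0
        for v in range(1, self.nvars + 1):
            if self._assign[v] == 0 and self._activity[v] > best_act:
                best = v
                best_act = self._activity[v]
        return best


def solve_clauses(clauses: Sequence[Sequence[int]], num_vars: int = 0):
    """One-shot convenience: returns a model dict or None if unsatisfiable."""
    s = Solver(num_vars)
    for c in clauses:
        s.add_clause(c)
    return s.model() if s.solve() else None
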