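"""Bounded reachability: SAT search, minimal scenarios, trajectory enumeration.

A query asks whether a Boolean property over places can become true within
``n`` steps (default 10, the representative solution depth for signaling
models of this kind).  The engine unrolls the dynamics to CNF, hands the
formula to the SAT solver, and decodes any satisfying assignment into a
scenario ``(F, T)``; every witness is re-simulated before being returned
(self-verification — an encoding bug can never masquerade as a result).

A witness scenario is *minimal* when removing any single frontier place
from F, or any single event occurrence from T, breaks reachability under
the same remaining timing.  Minimality checks and shrinking run the plain
simulator (deterministic, no SAT); deleting an occurrence may leave a step
empty, so these checks simulate leniently (an idle step changes nothing).

Distinct minimal scenarios are enumerated by blocking the exact step-0
frontier assignment of every scenario already seen; distinct trajectories
of one scenario are enumerated by blocking activated-sets through
indicator variables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .encoding import UnrolledCNF, unroll
from .expressions import CondExpr
from .model import GuardedTransitionModel, Scenario, Trajectory
from .satsolver import Solver, SolverError
from .simulator import holds_on, simulate


class SolverFailure(RuntimeError):
    """The SAT backend misbehaved (never reported as 'unreachable')."""


@dataclass(frozen=True)
class ReachabilityQuery:
    prop: CondExpr
    horizon: int = 10
    mode: str = "any-step"  # or "final-step"
    strict: bool = True

    def __post_init__(self):
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1")
        if self.mode not in ("any-step", "final-step"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class Witness:
    scenario: Scenario
    trajectory: Trajectory
    step: int  # first step at which the property held


def _satisfied(trajectory: Trajectory, query: ReachabilityQuery) -> int | None:
    if query.mode == "final-step":
        return (
            query.horizon
            if query.prop.eval(trajectory.states[query.horizon])
            else None
        )
    return holds_on(trajectory, query.prop)


def reaches(
    model: GuardedTransitionModel, scenario: Scenario, query: ReachabilityQuery
) -> int | None:
    """Simulate the scenario; return the satisfaction step, or None."""
    traj = simulate(model, scenario, strict=False)
    return _satisfied(traj, query)


def _solve(clauses, num_vars) -> dict[int, bool] | None:
    try:
        s = Solver(num_vars)
        for c in clauses:
            s.add_clause(c)
        return s.model() if s.solve() else None
    except (SolverError, RecursionError, MemoryError) as exc:  # pragma: no cover
        raise SolverFailure(f"SAT backend failed: {exc}") from exc


def _verify(model, cnf: UnrolledCNF, assignment, query) -> Witness:
    scenario = cnf.decode_scenario(assignment)
    traj = simulate(model, scenario, strict=False)
    step = _satisfied(traj, query)
    if step is None:
        raise SolverFailure(
            "SAT witness failed re-simulation: encoding and simulator disagree"
        )
    return Witness(scenario, traj, step)


def check(
    model: GuardedTransitionModel,
    query: ReachabilityQuery,
    optimize: bool = True,
) -> Witness | None:
    """Decide reachability; a Witness always re-simulates successfully."""
    cnf = unroll(model, query.horizon, strict=query.strict, optimize=optimize)
    cnf.add_property(query.prop, query.mode)
    assignment = _solve(cnf.clauses, cnf.num_vars)
    if assignment is None:
        return None
    return _verify(model, cnf, assignment, query)


# -- minimality ------------------------------------------------------------


def _deletions(scenario: Scenario):
    """All single-component deletions: first places (lexical), then event
    occurrences by (step, atom)."""
    for p in sorted(scenario.frontier):
        yield Scenario(scenario.frontier - {p}, scenario.timing)
    for i, stp in enumerate(scenario.timing):
        for h in sorted(stp):
            timing = list(scenario.timing)
            timing[i] = stp - {h}
            yield Scenario(scenario.frontier, tuple(timing))


def is_minimal(
    model: GuardedTransitionModel, scenario: Scenario, query: ReachabilityQuery
) -> bool:
    """Exact deletion-minimality: every single deletion breaks reachability."""
    if reaches(model, scenario, query) is None:
        raise ValueError("scenario is not a witness for the query")
    return all(reaches(model, s, query) is None for s in _deletions(scenario))


def shrink(
    model: GuardedTransitionModel, witness: Witness, query: ReachabilityQuery
) -> Witness:
    """Greedy destructive deletion to a fixpoint; output passes is_minimal.

    Deletion order is fixed (places lexically, then occurrences by
    (step, atom)) so the particular minimum found is reproducible.
    """
    frontier = set(witness.scenario.frontier)
    timing = [set(s) for s in witness.scenario.timing]
    changed = True
    while changed:
        changed = False
        for p in sorted(frontier):
            cand = Scenario.make(frontier - {p}, timing)
            if reaches(model, cand, query) is not None:
                frontier.discard(p)
                changed = True
        for i in range(len(timing)):
            for h in sorted(timing[i]):
                trial = [set(s) for s in timing]
                trial[i].discard(h)
                cand = Scenario.make(frontier, trial)
                if reaches(model, cand, query) is not None:
                    timing[i].discard(h)
                    changed = True
    scenario = Scenario.make(frontier, timing)
    traj = simulate(model, scenario, strict=False)
    return Witness(scenario, traj, _satisfied(traj, query))


# -- enumeration -----------------------------------------------------------


def _block_exact_frontier(cnf: UnrolledCNF, fset: frozenset[str]) -> list[int]:
    vm = cnf.varmap
    frontier = sorted(cnf.model.frontier())
    return [
        -vm.place(p, 0) if p in fset else vm.place(p, 0) for p in frontier
    ]


def enumerate_minimal(
    model: GuardedTransitionModel,
    query: ReachabilityQuery,
    limit: int = 100,
    optimize: bool = True,
) -> list[Witness]:
    """Minimal scenarios with pairwise-distinct frontier sets.

    Repeatedly: solve, shrink the witness to a minimal scenario, record its
    F-set if new, and block the exact step-0 assignments of both the
    decoded and the minimal F (each round excludes at least one fresh
    assignment, so the loop terminates at UNSAT or the limit).
    """
    if limit < 1:
        raise ValueError("limit must be >= 1")
    cnf = unroll(model, query.horizon, strict=query.strict, optimize=optimize)
    cnf.add_property(query.prop, query.mode)
    results: list[Witness] = []
    seen_f: set[frozenset[str]] = set()
    blocked: set[frozenset[str]] = set()
    while len(results) < limit:
        assignment = _solve(cnf.clauses, cnf.num_vars)
        if assignment is None:
            break
        witness = _verify(model, cnf, assignment, query)
        minimal = shrink(model, witness, query)
        fmin = minimal.scenario.frontier
        if fmin not in seen_f:
            seen_f.add(fmin)
            results.append(minimal)
        for f in (witness.scenario.frontier, fmin):
            if f not in blocked:
                blocked.add(f)
                cnf.encoder.clauses.append(_block_exact_frontier(cnf, f))
    return results


def enumerate_trajectories(
    model: GuardedTransitionModel,
    scenario: Scenario,
    query: ReachabilityQuery,
    limit: int = 100,
    optimize: bool = True,
) -> list[Trajectory]:
    """Trajectories reaching the property from a fixed F, one per distinct
    activated-set; the timing is left free and re-searched by SAT."""
    if reaches(model, scenario, query) is None:
        raise ValueError("scenario is not a witness for the query")
    cnf = unroll(model, query.horizon, strict=query.strict, optimize=optimize)
    cnf.add_property(query.prop, query.mode)
    vm = cnf.varmap
    for p in sorted(model.frontier()):
        lit = vm.place(p, 0)
        cnf.encoder.clauses.append([lit] if p in scenario.frontier else [-lit])
    act = cnf.activation_indicators()
    results: list[Trajectory] = []
    seen: set[frozenset[str]] = set()
    while len(results) < limit:
        assignment = _solve(cnf.clauses, cnf.num_vars)
        if assignment is None:
            break
        witness = _verify(model, cnf, assignment, query)
        activated = witness.trajectory.activated
        if activated not in seen:
            seen.add(activated)
            results.append(witness.trajectory)
        cnf.encoder.clauses.append(
            [-act[p] if p in activated else act[p] for p in vm.place_names]
        )
    return results


def gene_scenario_screen(
    model: GuardedTransitionModel,
    genes: list[str],
    horizon: int = 10,
    mode: str = "any-step",
    strict: bool = True,
    scenario_limit: int = 50,
    trajectory_limit: int = 50,
):
    """Batch reachability screen: per gene, all minimal scenarios (up to the
    limit), the frontier content of each, and the distinct trajectories.

    Missing places are reported in the record and the screen continues."""
    from .expressions import Var
    from .trajectory_analysis import GeneRegulationRecord

    records: dict[str, GeneRegulationRecord] = {}
    for gene in genes:
        if gene not in model.place_set:
            records[gene] = GeneRegulationRecord(
                gene=gene, scenarios=[], trajectories=[],
                error=f"place {gene!r} not in model",
            )
            continue
        query = ReachabilityQuery(Var(gene), horizon=horizon, mode=mode, strict=strict)
        witnesses = enumerate_minimal(model, query, limit=scenario_limit)
        trajectories: list[frozenset[str]] = []
        seen: set[frozenset[str]] = set()
        for w in witnesses:
            for traj in enumerate_trajectories(
                model, w.scenario, query, limit=trajectory_limit
            ):
                if traj.activated not in seen:
                    seen.add(traj.activated)
                    trajectories.append(traj.activated)
        records[gene] = GeneRegulationRecord(
            gene=gene,
            scenarios=[w.scenario for w in witnesses],
            trajectories=trajectories,
        )
    return records
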