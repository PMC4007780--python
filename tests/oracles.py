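"""Independent reference implementations used only as test oracles.

These deliberately share no code with the package's simulator or SAT
path: expressions are evaluated by a separate recursive walk over the
node classes, and the per-place update applies the written rule directly
(in-transition fired -> True; else out-transition fired -> False; else
unchanged).  The explicit-state oracle answers reachability by
breadth-first search over the full state space, and the exhaustive
minimal-scenario oracle enumerates every (F, T) pair on tiny models.
"""

from __future__ import annotations

import itertools

from gtreach import expressions as E


def o_eval_cond(expr, state: dict) -> bool:
    if isinstance(expr, E.Const):
        return expr.value
    if isinstance(expr, E.Var):
        return state[expr.name]
    if isinstance(expr, E.Not):
        return not o_eval_cond(expr.child, state)
    if isinstance(expr, E.And):
        return all(o_eval_cond(c, state) for c in expr.children)
    if isinstance(expr, E.Or):
        return any(o_eval_cond(c, state) for c in expr.children)
    raise TypeError(type(expr))


def o_event_present(expr, present: frozenset, state: dict) -> bool:
    if isinstance(expr, E.EventAtom):
        return expr.name in present
    if isinstance(expr, E.Default):
        return o_event_present(expr.left, present, state) or o_event_present(
            expr.right, present, state
        )
    if isinstance(expr, E.When):
        return o_event_present(expr.event, present, state) and o_eval_cond(
            expr.cond, state
        )
    raise TypeError(type(expr))


def o_fires(tr, present: frozenset, state: dict) -> bool:
    return (
        state[tr.source]
        and o_event_present(tr.event, present, state)
        and o_eval_cond(tr.condition, state)
    )


def o_step(model, state: dict, present: frozenset) -> dict:
    nxt = {}
    for place in model.places:
        fired_in = any(
            o_fires(tr, present, state)
            for tr in model.transitions
            if tr.target == place
        )
        fired_out = any(
            o_fires(tr, present, state)
            for tr in model.transitions
            if tr.source == place
        )
        if fired_in:
            nxt[place] = True
        elif fired_out:
            nxt[place] = False
        else:
            nxt[place] = state[place]
    return nxt


def o_simulate(model, frontier: frozenset, timing) -> list[dict]:
    state = {p: p in frontier for p in model.places}
    states = [dict(state)]
    for present in timing:
        state = o_step(model, state, frozenset(present))
        states.append(dict(state))
    return states


# -- explicit-state BFS reachability ---------------------------------------


def _as_fset(state: dict) -> frozenset:
    return frozenset(p for p, v in state.items() if v)


def _successors(model, fstate: frozenset) -> set[frozenset]:
    state = {p: p in fstate for p in model.places}
    relevant = sorted(
        set().union(
            *(tr.event.atoms() for tr in model.transitions if state[tr.source]),
            set(),
        )
    )
    succs = {fstate}  # present-sets touching no relevant atom leave state as-is
    for r in range(1, len(relevant) + 1):
        for combo in itertools.combinations(relevant, r):
            succs.add(_as_fset(o_step(model, state, frozenset(combo))))
    return succs


def bfs_reachable(model, prop, horizon: int, mode: str = "any-step") -> bool:
    """Can any scenario make prop true within (or exactly at) the horizon?

    Searches from every subset of the frontier over every event-atom
    subset per step.  Idle steps keep the state, so any-step reachability
    is identical in strict and lenient realizations."""
    frontier = sorted(model.frontier())
    layer: set[frozenset] = set()
    for r in range(len(frontier) + 1):
        for combo in itertools.combinations(frontier, r):
            layer.add(frozenset(combo))

    def holds(fstate: frozenset) -> bool:
        return o_eval_cond(prop, {p: p in fstate for p in model.places})

    if mode == "any-step" and any(holds(s) for s in layer):
        return True
    visited = set(layer)
    succ_cache: dict[frozenset, set[frozenset]] = {}
    for _ in range(horizon):
        nxt: set[frozenset] = set()
        for s in layer:
            if s not in succ_cache:
                succ_cache[s] = _successors(model, s)
            nxt |= succ_cache[s]
        if mode == "any-step":
            if any(holds(s) for s in nxt):
                return True
            nxt -= visited
            visited |= nxt
        layer = nxt
        if not layer:
            break
    if mode == "final-step":
        return any(holds(s) for s in layer)
    return False


# -- exhaustive minimal-scenario enumeration (tiny models only) ------------


def _o_reaches(model, frontier, timing, prop, mode="any-step") -> bool:
    states = o_simulate(model, frozenset(frontier), timing)
    if mode == "final-step":
        return o_eval_cond(prop, states[-1])
    return any(o_eval_cond(prop, s) for s in states)


def o_is_minimal(model, frontier, timing, prop, mode="any-step") -> bool:
    if not _o_reaches(model, frontier, timing, prop, mode):
        return False
    for p in frontier:
        if _o_reaches(model, frontier - {p}, timing, prop, mode):
            return False
    for i, stp in enumerate(timing):
        for h in stp:
            trial = [set(s) for s in timing]
            trial[i].discard(h)
            if _o_reaches(model, frontier, trial, prop, mode):
                return False
    return True


def exhaustive_minimal_fsets(model, prop, horizon, mode="any-step", strict=False):
    """All F-sets admitting some minimal witness, by brute enumeration of
    every (F, T).  Exponential: only for models with a handful of atoms.

    Candidate timings allow empty steps: deletion-minimal timings carry
    only load-bearing occurrences, so their surplus steps are empty —
    with nonempty-step candidates a short path inside a longer horizon
    would always have a removable forced occurrence and nothing would be
    minimal."""
    atoms = sorted(model.events)
    subsets = []
    for r in range(0 if not strict else 1, len(atoms) + 1):
        subsets.extend(frozenset(c) for c in itertools.combinations(atoms, r))
    frontier = sorted(model.frontier())
    result = set()
    for r in range(len(frontier) + 1):
        for fc in itertools.combinations(frontier, r):
            f = frozenset(fc)
            if f in result:
                continue
            for timing in itertools.product(subsets, repeat=horizon):
                if o_is_minimal(model, f, list(timing), prop, mode):
                    result.add(f)
                    break
    return result
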