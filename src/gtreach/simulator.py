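"""Synchronous operational semantics of guarded-transition models.

For a transition ``A -[h [C]]-> B`` the *transition event* is
``h when (A and C)``: present exactly when ``h`` is present, the source is
True and the condition holds — all evaluated on the prior state.  For each
place, ``h_in`` merges the transition events of its in-transitions and
``h_out`` those of its out-transitions, and one step updates every place
simultaneously by the prioritized rule

    next(A) = True   if h_in present          (activation wins)
            = False  if h_out present (and not h_in)
            = A      otherwise                (frame: value kept)

so activation prevails over inactivation when both fire at once, and a
place not touched by any fired transition keeps its value.

A *realization* supplies, for each step, the set of present event atoms.
In strict mode the all-absent step is excluded, matching the definition of
a realization; lenient mode permits idle steps (useful inside minimality
checks, where deleting an occurrence may empty a step).
"""

from __future__ import annotations

from dataclasses import dataclass

from .expressions import CondExpr
from .model import GuardedTransition, GuardedTransitionModel, Scenario, State, Trajectory


class RealizationError(ValueError):
    pass


def eval_cond(cond: CondExpr, state: State) -> bool:
    """Standard Boolean semantics of a condition over the given state."""
    return cond.eval(state)


def eval_event(event, present, state: State) -> bool:
    """Presence of an event expression given present atoms and the state."""
    return event.present(present, state)


def transition_event_present(
    tr: GuardedTransition, present, state: State
) -> bool:
    """Whether the transition fires this step: h present, source True, C True."""
    return (
        state[tr.source]
        and tr.event.present(present, state)
        and tr.condition.eval(state)
    )


@dataclass
class StepReport:
    """What happened in one step, for inspection and testing."""

    fired: list[GuardedTransition]
    h_in: dict[str, bool]
    h_out: dict[str, bool]
    prior: State
    next: State


def step(
    model: GuardedTransitionModel,
    state: State,
    present,
    strict: bool = True,
) -> tuple[State, StepReport]:
    """One synchronous step; all guards read the prior state only."""
    present = frozenset(present)
    if strict and not present:
        raise RealizationError("empty event set in a strict realization step")
    unknown = present - model.events
    if unknown:
        raise RealizationError(f"undeclared event atoms: {sorted(unknown)}")

    fired = [tr for tr in model.transitions if transition_event_present(tr, present, state)]
    h_in = {p: False for p in model.places}
    h_out = {p: False for p in model.places}
    for tr in fired:
        h_in[tr.target] = True
        h_out[tr.source] = True

    nxt: State = {}
    for p in model.places:
        if h_in[p]:
            nxt[p] = True
        elif h_out[p]:
            nxt[p] = False
        else:
            nxt[p] = state[p]
    return nxt, StepReport(fired, h_in, h_out, dict(state), nxt)


def simulate(
    model: GuardedTransitionModel,
    scenario: Scenario,
    strict: bool = True,
) -> Trajectory:
    """Run a scenario: activate F at step 0, then one step per timing entry."""
    diags = scenario.validate_against(model)
    if diags:
        raise ValueError("scenario does not fit model: " + "; ".join(diags))
    state = model.initial_state(scenario.frontier)
    states = [dict(state)]
    for present in scenario.timing:
        state, _ = step(model, state, present, strict=strict)
        states.append(dict(state))
    return Trajectory(states)


def holds_on(trajectory: Trajectory, prop: CondExpr) -> int | None:
    """First step index at which the property is True, or None."""
    return trajectory.first_step_where(prop)
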