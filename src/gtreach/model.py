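"""Core guarded-transition model objects.

A model is a set of Boolean *places* (biomolecules in a given activity
state and compartment) connected by *guarded transitions*.  A transition
``A -[h [C]]-> B`` fires at a step when its event ``h`` is present, its
source ``A`` is True and its condition ``C`` (a formula over places) holds;
firing deactivates the source and activates the target.  Multi-molecule
reactions are represented as several single-source single-target
transitions sharing one event atom, so they fire simultaneously.

The *frontier* is the set of places with no incoming transition — the only
places that can be made True at initialization.  A *scenario* is a choice
of frontier places to activate plus a per-step timing of event atoms; a
*trajectory* is the per-step record of place values that a scenario
produces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .expressions import CondExpr, EventExpr, TRUE, Var

# A state is simply a total mapping place -> bool.
State = dict


def state_space_decimal_exponent(n_places: int) -> int:
    """Decimal order of magnitude of the Boolean state space: a model with
    n places has 2^n states, i.e. about 10^floor(n·log10 2).  This is why
    the reachability engine avoids explicit state graphs and encodes
    bounded dynamics for a SAT solver instead."""
    import math

    if n_places < 0:
        raise ValueError("n_places must be >= 0")
    return math.floor(n_places * math.log10(2))


@dataclass(frozen=True)
class GuardedTransition:
    source: str
    target: str
    event: EventExpr
    condition: CondExpr = TRUE

    def unparse(self) -> str:
        cond = self.condition.unparse()
        return f"trans {self.source} -[{self.event.unparse()} [{cond}]]-> {self.target};"

    def sort_key(self) -> tuple:
        return (self.source, self.target, self.event.unparse(), self.condition.unparse())


class GuardedTransitionModel:
    """Places, transitions and the derived in/out-transition maps."""

    def __init__(
        self,
        places: Iterable[str],
        transitions: Iterable[GuardedTransition] = (),
        name: str = "model",
        metadata: dict | None = None,
    ):
        self.name = name
        self.metadata = dict(metadata or {})
        self.places: list[str] = list(places)
        self.transitions: list[GuardedTransition] = list(transitions)
        self._rebuild()

    def _rebuild(self) -> None:
        self.place_set = set(self.places)
        self.t_in: dict[str, list[GuardedTransition]] = {p: [] for p in self.places}
        self.t_out: dict[str, list[GuardedTransition]] = {p: [] for p in self.places}
        for tr in self.transitions:
            if tr.target in self.t_in:
                self.t_in[tr.target].append(tr)
            if tr.source in self.t_out:
                self.t_out[tr.source].append(tr)

    # -- derived sets -------------------------------------------------------

    @property
    def events(self) -> set[str]:
        """Declared event-atom set: the union of atoms in transition guards."""
        out: set[str] = set()
        for tr in self.transitions:
            out |= tr.event.atoms()
        return out

    def frontier(self) -> set[str]:
        """Places with no incoming transitions.

        These are the only places that can be activated at initialization;
        everything else starts False and must be reached through firing.
        """
        return {p for p in self.places if not self.t_in[p]}

    # -- validation ---------------------------------------------------------

    def validate(self) -> list[str]:
        """Diagnostics for every violated structural invariant.

        Returns an empty list iff the model is well formed.  Never raises:
        a broken model is reported, not rejected, so importers can surface
        all problems at once.
        """
        diags: list[str] = []
        seen: set[str] = set()
        for p in self.places:
            if p in seen:
                diags.append(f"duplicate place name {p!r}")
            seen.add(p)
        for i, tr in enumerate(self.transitions):
            where = f"transition #{i} {tr.source}->{tr.target}"
            if tr.source not in self.place_set:
                diags.append(f"{where}: unregistered source place {tr.source!r}")
            if tr.target not in self.place_set:
                diags.append(f"{where}: unregistered target place {tr.target!r}")
            if tr.source == tr.target:
                diags.append(f"{where}: self-loop (permitted but unusual)")
            for name in sorted(tr.condition.places() | tr.event.condition_places()):
                if name not in self.place_set:
                    diags.append(f"{where}: condition references unknown place {name!r}")
        return diags

    def is_valid(self) -> bool:
        return not any(d for d in self.validate() if "self-loop" not in d)

    # -- misc ---------------------------------------------------------------

    def initial_state(self, active: Iterable[str] = ()) -> State:
        active = set(active)
        unknown = active - self.place_set
        if unknown:
            raise ValueError(f"unknown places in initial state: {sorted(unknown)}")
        return {p: p in active for p in self.places}

    def sorted_copy(self) -> "GuardedTransitionModel":
        return GuardedTransitionModel(
            sorted(self.places),
            sorted(self.transitions, key=GuardedTransition.sort_key),
            name=self.name,
            metadata=self.metadata,
        )

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<GuardedTransitionModel {self.name!r}: {len(self.places)} places, "
            f"{len(self.transitions)} transitions, {len(self.events)} events>"
        )


@dataclass(frozen=True)
class Scenario:
    """Initialization content plus timing: the (F, T) pair.

    ``frontier`` is the set of frontier places activated at step 0 and
    ``timing`` gives, for each step, the set of present event atoms.
    """

    frontier: frozenset[str]
    timing: tuple[frozenset[str], ...]

    @staticmethod
    def make(frontier: Iterable[str], timing: Iterable[Iterable[str]]) -> "Scenario":
        return Scenario(
            frozenset(frontier), tuple(frozenset(step) for step in timing)
        )

    @property
    def horizon(self) -> int:
        return len(self.timing)

    def validate_against(self, model: GuardedTransitionModel) -> list[str]:
        diags = []
        extra = self.frontier - model.frontier()
        if extra:
            diags.append(f"non-frontier places in F: {sorted(extra)}")
        declared = model.events
        for i, step in enumerate(self.timing):
            unknown = step - declared
            if unknown:
                diags.append(f"step {i}: undeclared event atoms {sorted(unknown)}")
        return diags


@dataclass
class Trajectory:
    """Per-step state snapshots of one run; snapshot 0 activates exactly F."""

    states: list[State]

    @property
    def activated(self) -> frozenset[str]:
        """All places ever True — the paper-style content of the trajectory."""
        out: set[str] = set()
        for s in self.states:
            out.update(p for p, v in s.items() if v)
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.states)

    def first_step_where(self, prop: CondExpr) -> int | None:
        for k, s in enumerate(self.states):
            if prop.eval(s):
                return k
        return None
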