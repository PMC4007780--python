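"""Synthetic models and hand-built fixtures.

Everything downstream is testable without downloads: a seeded random-model
generator, the canonical small motifs (chain, diamond, complex formation),
a deterministic motif-grammar enumerator for exhaustive semantic checks,
and a ~16-place toy TGF-β model whose expected answers (frontier content,
minimal scenarios, Smad classification) were computed with the
explicit-state oracle and shipped as JSON metadata next to the model file.
"""

from __future__ import annotations

import json
import random
from importlib import resources
from typing import Iterator

from .expressions import And, EventAtom, Not, Or, TRUE, Var
from .io import read_model
from .model import GuardedTransition, GuardedTransitionModel


def random_model(
    n_places: int,
    n_transitions: int,
    condition_density: float = 0.3,
    seed: int = 0,
    acyclic: bool = False,
    allow_negation: bool = True,
) -> GuardedTransitionModel:
    """Seed-reproducible random model; every transition has a fresh event.

    ``condition_density`` is the probability that a transition carries a
    nontrivial condition (one or two literals over existing places);
    ``allow_negation=False`` restricts conditions to positive literals,
    which keeps reachability monotone in the frontier set."""
    if n_places < 2:
        raise ValueError("need at least 2 places")
    if n_transitions < 0:
        raise ValueError("n_transitions must be >= 0")
    if acyclic and n_places < 2 and n_transitions > 0:
        raise ValueError("acyclic models need at least 2 places")
    rng = random.Random(seed)
    places = [f"P{i}" for i in range(n_places)]
    transitions = []
    for t in range(n_transitions):
        if acyclic:
            i, j = sorted(rng.sample(range(n_places), 2))
        else:
            i, j = rng.sample(range(n_places), 2)
        cond = TRUE
        if rng.random() < condition_density:
            k = rng.randint(1, 2)
            lits = []
            for name in rng.sample(places, k):
                lit = Var(name)
                if allow_negation and rng.random() < 0.4:
                    lit = Not(lit)
                lits.append(lit)
            cond = lits[0] if len(lits) == 1 else And(*lits)
        transitions.append(
            GuardedTransition(places[i], places[j], EventAtom(f"e{t}"), cond)
        )
    model = GuardedTransitionModel(
        places, transitions, name=f"random_s{seed}",
        metadata={"seed": seed},
    )
    return model


# -- canonical motifs ------------------------------------------------------

_LETTERS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


def chain_model(length: int = 3) -> GuardedTransitionModel:
    """A -h1-> B -h2-> C ...: frontier {A}, exactly one minimal scenario."""
    if not 2 <= length <= 26:
        raise ValueError("chain length must be in 2..26")
    places = list(_LETTERS[:length])
    transitions = [
        GuardedTransition(places[i], places[i + 1], EventAtom(f"h{i + 1}"))
        for i in range(length - 1)
    ]
    return GuardedTransitionModel(
        places, transitions, name=f"chain{length}",
        metadata={"expected": {"frontier": [places[0]],
                               "minimal_f_sets": [[places[0]]],
                               "goal": places[-1]}},
    )


def diamond_model() -> GuardedTransitionModel:
    """Two disjoint 2-step branches into P: exactly two minimal scenarios."""
    transitions = [
        GuardedTransition("S1", "A", EventAtom("h1")),
        GuardedTransition("A", "P", EventAtom("h2")),
        GuardedTransition("S2", "B", EventAtom("h3")),
        GuardedTransition("B", "P", EventAtom("h4")),
    ]
    return GuardedTransitionModel(
        ["S1", "A", "S2", "B", "P"], transitions, name="diamond",
        metadata={"expected": {"frontier": ["S1", "S2"],
                               "minimal_f_sets": [["S1"], ["S2"]],
                               "goal": "P"}},
    )


def complex_motif() -> GuardedTransitionModel:
    """Complex formation: both components feed CPLX on one shared event,
    each conditioned on the other's presence, so they are consumed
    simultaneously and the complex appears in a single step."""
    transitions = [
        GuardedTransition("S23", "CPLX", EventAtom("h1"), Var("S4")),
        GuardedTransition("S4", "CPLX", EventAtom("h1"), Var("S23")),
    ]
    return GuardedTransitionModel(
        ["S23", "S4", "CPLX"], transitions, name="complex_motif",
        metadata={"expected": {"frontier": ["S23", "S4"],
                               "minimal_f_sets": [["S23", "S4"]],
                               "goal": "CPLX"}},
    )


def motif_grammar(max_places: int = 8) -> Iterator[GuardedTransitionModel]:
    """Deterministic enumeration of small structured models.

    Chains, cycles, diamonds with all branch-length splits, complex
    formation with 2..k components, fan-out/fan-in stars, and chains
    decorated with a positive or negative condition dependency — every
    combination that fits in ``max_places`` places."""
    # chains
    for L in range(2, max_places + 1):
        yield chain_model(L)
    # cycles
    for L in range(2, max_places + 1):
        places = list(_LETTERS[:L])
        trs = [
            GuardedTransition(places[i], places[(i + 1) % L], EventAtom(f"h{i}"))
            for i in range(L)
        ]
        yield GuardedTransitionModel(places, trs, name=f"cycle{L}")
    # diamonds with branch lengths (a, b)
    for a in range(1, max_places):
        for b in range(a, max_places):
            if a + b + 3 > max_places:
                continue
            places = [f"A{i}" for i in range(a + 1)] + [f"B{i}" for i in range(b + 1)] + ["P"]
            trs = []
            for i in range(a):
                trs.append(GuardedTransition(f"A{i}", f"A{i+1}", EventAtom(f"ha{i}")))
            trs.append(GuardedTransition(f"A{a}", "P", EventAtom("hap")))
            for i in range(b):
                trs.append(GuardedTransition(f"B{i}", f"B{i+1}", EventAtom(f"hb{i}")))
            trs.append(GuardedTransition(f"B{b}", "P", EventAtom("hbp")))
            yield GuardedTransitionModel(places, trs, name=f"diamond{a}_{b}")
    # complex formation with k components
    for k in range(2, max_places):
        comps = [f"C{i}" for i in range(k)]
        trs = []
        for i, c in enumerate(comps):
            others = [Var(o) for o in comps if o != c]
            cond = others[0] if len(others) == 1 else And(*others)
            trs.append(GuardedTransition(c, "CPLX", EventAtom("h"), cond))
        yield GuardedTransitionModel(comps + ["CPLX"], trs, name=f"complex{k}")
    # fan-out and fan-in stars
    for k in range(2, max_places):
        hub = "H"
        leaves = [f"L{i}" for i in range(k)]
        yield GuardedTransitionModel(
            [hub] + leaves,
            [GuardedTransition(hub, l, EventAtom(f"h{i}")) for i, l in enumerate(leaves)],
            name=f"fanout{k}",
        )
        yield GuardedTransitionModel(
            [hub] + leaves,
            [GuardedTransition(l, hub, EventAtom(f"h{i}")) for i, l in enumerate(leaves)],
            name=f"fanin{k}",
        )
    # chains with one condition dependency (positive and negative)
    for L in range(3, max_places):
        for neg in (False, True):
            places = list(_LETTERS[:L]) + ["W"]
            cond = Not(Var("W")) if neg else Var("W")
            trs = [
                GuardedTransition(places[i], places[i + 1], EventAtom(f"h{i}"),
                                  cond if i == L - 2 else TRUE)
                for i in range(L - 1)
            ]
            yield GuardedTransitionModel(
                places, trs, name=f"condchain{L}{'n' if neg else 'p'}"
            )


# -- toy canonical TGF-beta model -----------------------------------------


def _data_text(name: str) -> str:
    return resources.files("gtreach.data").joinpath(name).read_text()


def toy_canonical_tgfb() -> GuardedTransitionModel:
    """The shipped toy TGF-β model with its verified expected answers in
    ``model.metadata['expected']``."""
    model = read_model(_data_text("toy_tgfb.model"), name="toy_tgfb")
    meta = json.loads(_data_text("toy_tgfb.meta.json"))
    model.metadata["expected"] = meta
    return model
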