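"""Reachability checking, minimal scenarios, enumeration, the gene screen."""

import random

import pytest

from gtreach import (
    EventAtom,
    GuardedTransition,
    GuardedTransitionModel,
    Scenario,
    Var,
    check,
    enumerate_minimal,
    enumerate_trajectories,
    gene_scenario_screen,
    is_minimal,
    shrink,
)
from gtreach.fixtures import diamond_model, random_model
from gtreach.reachability import ReachabilityQuery, Witness, reaches
from gtreach.simulator import simulate
from oracles import bfs_reachable, exhaustive_minimal_fsets


def test_check_chain_returns_witness(chain3):
    q = ReachabilityQuery(Var("C"), horizon=10)
    w = check(chain3, q)
    assert w is not None
    assert w.scenario.frontier == frozenset({"A"})
    assert reaches(chain3, w.scenario, q) == w.step


def test_check_unreachable_isolated_place():
    # B has an in-transition (not frontier) whose source can never activate
    m = GuardedTransitionModel(
        ["A", "B", "C"],
        [
            GuardedTransition("A", "B", EventAtom("h1")),
            GuardedTransition("C", "A", EventAtom("h2")),  # A not frontier
        ],
    )
    # only frontier is C; B reachable; but a place whose sources never fire:
    m2 = GuardedTransitionModel(
        ["X", "Y", "Z"],
        [
            GuardedTransition("X", "Y", EventAtom("h1")),
            GuardedTransition("Y", "X", EventAtom("h2")),
        ],
    )
    # X and Y form a 2-cycle with empty frontier: Z is frontier, X/Y never on
    assert check(m2, ReachabilityQuery(Var("X"), horizon=5)) is None


def test_check_verdicts_match_bfs_oracle():
    rng = random.Random(42)
    for seed in range(100):
        m = random_model(rng.randint(3, 10), rng.randint(1, 8), 0.4, seed=seed)
        prop = Var(rng.choice(m.places))
        q = ReachabilityQuery(prop, horizon=4)
        w = check(m, q)
        assert (w is not None) == bfs_reachable(m, prop, 4), (seed, m.name)
        if w is not None:  # self-verification: the witness re-simulates
            assert reaches(m, w.scenario, q) is not None


def test_is_minimal_chain_witness(chain3):
    q = ReachabilityQuery(Var("C"), horizon=2)
    sc = Scenario.make(["A"], [["h1"], ["h2"]])
    assert is_minimal(chain3, sc, q)


def test_is_minimal_rejects_spurious_frontier_place(diamond):
    q = ReachabilityQuery(Var("P"), horizon=2)
    good = Scenario.make(["S1"], [["h1"], ["h2"]])
    padded = Scenario.make(["S1", "S2"], [["h1"], ["h2"]])
    assert is_minimal(diamond, good, q)
    assert not is_minimal(diamond, padded, q)


def test_is_minimal_requires_witness(chain3):
    q = ReachabilityQuery(Var("C"), horizon=2)
    with pytest.raises(ValueError):
        is_minimal(chain3, Scenario.make([], [["h1"], ["h2"]]), q)


def test_is_minimal_diamond_both_branches(diamond):
    q = ReachabilityQuery(Var("P"), horizon=2)
    for start, events in (("S1", ["h1", "h2"]), ("S2", ["h3", "h4"])):
        sc = Scenario.make([start], [[e] for e in events])
        assert is_minimal(diamond, sc, q)


def test_shrink_removes_superset_frontier(diamond):
    q = ReachabilityQuery(Var("P"), horizon=4)
    fat = Scenario.make(["S1", "S2"], [["h1", "h3"], ["h2", "h4"], ["h1"], ["h2"]])
    traj = simulate(diamond, fat, strict=False)
    w = Witness(fat, traj, reaches(diamond, fat, q))
    small = shrink(diamond, w, q)
    assert small.scenario.frontier in ({"S1"}, {"S2"})
    assert is_minimal(diamond, small.scenario, q)


def test_shrink_leaves_minimal_witness_unchanged(chain3):
    q = ReachabilityQuery(Var("C"), horizon=2)
    sc = Scenario.make(["A"], [["h1"], ["h2"]])
    w = Witness(sc, simulate(chain3, sc, strict=False), 2)
    assert shrink(chain3, w, q).scenario == sc


def test_shrink_output_always_minimal_on_random_models():
    rng = random.Random(9)
    done = 0
    for seed in range(60):
        m = random_model(rng.randint(3, 7), rng.randint(1, 6), 0.4, seed=seed)
        prop = Var(rng.choice(m.places))
        q = ReachabilityQuery(prop, horizon=4)
        w = check(m, q)
        if w is None:
            continue
        small = shrink(m, w, q)
        assert is_minimal(m, small.scenario, q)
        done += 1
    assert done >= 20  # enough reachable instances actually exercised


def test_enumerate_minimal_chain_is_unique(chain3):
    q = ReachabilityQuery(Var("C"), horizon=10)
    ws = enumerate_minimal(chain3, q)
    assert [sorted(w.scenario.frontier) for w in ws] == [["A"]]


def test_enumerate_minimal_diamond_two_fsets(diamond):
    q = ReachabilityQuery(Var("P"), horizon=10)
    ws = enumerate_minimal(diamond, q)
    assert sorted(sorted(w.scenario.frontier) for w in ws) == [["S1"], ["S2"]]
    for w in ws:
        assert is_minimal(diamond, w.scenario, q)


def test_enumerate_minimal_unreachable_is_empty(chain3):
    m = GuardedTransitionModel(
        ["X", "Y"],
        [GuardedTransition("X", "Y", EventAtom("h1")),
         GuardedTransition("Y", "X", EventAtom("h2"))],
    )
    assert enumerate_minimal(m, ReachabilityQuery(Var("X"), horizon=4)) == []


def test_enumerate_minimal_matches_exhaustive_search():
    """On tiny models the SAT enumeration finds exactly the F-sets that
    brute force over every (F, T) declares minimal."""
    rng = random.Random(17)
    checked = 0
    for seed in range(40):
        m = random_model(4, rng.randint(1, 4), 0.4, seed=seed,
                         allow_negation=False)
        prop = Var(rng.choice(m.places))
        q = ReachabilityQuery(prop, horizon=3)
        got = {w.scenario.frontier for w in enumerate_minimal(m, q, limit=50)}
        expected = exhaustive_minimal_fsets(m, prop, 3)
        assert got == expected, (seed, sorted(map(sorted, got)),
                                 sorted(map(sorted, expected)))
        checked += 1
    assert checked == 40


def test_enumerate_trajectories_chain_single(chain3):
    q = ReachabilityQuery(Var("C"), horizon=4)
    sc = Scenario.make(["A"], [["h1"], ["h2"], [], []])
    trajs = enumerate_trajectories(chain3, sc, q, limit=10)
    assert [sorted(t.activated) for t in trajs] == [["A", "B", "C"]]


def test_enumerate_trajectories_side_branch_gives_two_sets():
    # A->B->P with an optional side branch A2->X that may or may not fire
    m = GuardedTransitionModel(
        ["A", "B", "P", "A2", "X", "Q"],
        [
            GuardedTransition("A", "B", EventAtom("h1")),
            GuardedTransition("B", "P", EventAtom("h2")),
            GuardedTransition("A2", "X", EventAtom("h3")),
        ],
    )
    q = ReachabilityQuery(Var("P"), horizon=4)
    sc = Scenario.make(["A", "A2"], [["h1"], ["h2"], [], []])
    trajs = enumerate_trajectories(m, sc, q, limit=10)
    sets = sorted(sorted(t.activated) for t in trajs)
    assert ["A", "A2", "B", "P"] in sets
    assert ["A", "A2", "B", "P", "X"] in sets
    assert len(sets) == 2
    assert len(enumerate_trajectories(m, sc, q, limit=1)) == 1


def test_trajectories_require_witness_scenario(chain3):
    q = ReachabilityQuery(Var("C"), horizon=4)
    with pytest.raises(ValueError):
        enumerate_trajectories(chain3, Scenario.make([], [[]] * 4), q)


def test_anti_monotonicity_on_negation_free_models():
    """Without inhibitors, enlarging F (same timing) cannot lose the goal."""
    rng = random.Random(23)
    for seed in range(30):
        m = random_model(6, 6, 0.4, seed=seed, allow_negation=False)
        prop = Var(rng.choice(m.places))
        q = ReachabilityQuery(prop, horizon=4)
        w = check(m, q)
        if w is None:
            continue
        frontier = m.frontier()
        extra = frontier - w.scenario.frontier
        if not extra:
            continue
        bigger = Scenario(
            w.scenario.frontier | {sorted(extra)[0]}, w.scenario.timing
        )
        assert reaches(m, bigger, q) is not None


def test_gene_screen_on_toy_fixture(toy):
    meta = toy.metadata["expected"]
    genes = [meta["smad_only_gene"], meta["bypass_gene"], "NOT_A_PLACE"]
    records = gene_scenario_screen(toy, genes, horizon=10)
    smad_rec = records[meta["smad_only_gene"]]
    got = sorted(sorted(f) for f in smad_rec.frontier_sets())
    assert got == meta["minimal_f_sets"][meta["smad_only_gene"]]
    # every scenario of the Smad-only gene contains the TGF-beta stimulus
    assert all("TGFB" in f for f in smad_rec.frontier_sets())
    assert records["NOT_A_PLACE"].error is not None
    assert records[meta["bypass_gene"]].scenarios  # screen continued


def test_gene_screen_empty_list(toy):
    assert gene_scenario_screen(toy, []) == {}
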