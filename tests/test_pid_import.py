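"""Reaction parsing, reaction-to-transition compilation, pathway merging."""

import pytest

from gtreach import Default, EventAtom, Not, Scenario, Var, simulate
from gtreach.model import GuardedTransitionModel
from gtreach.pid_import import (
    ReactionRecord,
    SpeciesName,
    merge_models,
    parse_pid_xml,
    parse_reactions_json,
    reaction_to_transitions,
    reactions_to_model,
)

THREE_REACTIONS_JSON = """
{"pathway": "toy", "reactions": [
  {"id": "r1", "kind": "complex-assembly",
   "inputs": ["SMAD2_3_active", "SMAD4"],
   "outputs": ["SMAD2_3_SMAD4_active_cytoplasm"]},
  {"id": "r2", "kind": "translocation",
   "inputs": ["SMAD2_3_SMAD4_active_cytoplasm"],
   "outputs": ["SMAD2_3_SMAD4_active_nucleus"],
   "activators": ["IMPORTIN"]},
  {"id": "r3", "kind": "transcription",
   "inputs": ["SMAD7_gene"], "outputs": ["SMAD7"],
   "activators": ["SMAD2_3_SMAD4_active_nucleus"], "inhibitors": ["SKI"]}
]}
"""

SAMPLE_XML = """<?xml version="1.0"?>
<Model>
 <MoleculeList>
  <Molecule id="m1"><Name value="SMAD3"/><Label value="active"/></Molecule>
  <Molecule id="m2"><Name value="SMAD4"/></Molecule>
  <Molecule id="m3" compartment="cytoplasm"><Name value="SMAD3_SMAD4"/><Label value="active"/></Molecule>
  <Molecule id="m4"><Name value="IMPORTIN"/></Molecule>
  <Molecule id="m5" compartment="nucleus"><Name value="SMAD3_SMAD4"/><Label value="active"/></Molecule>
 </MoleculeList>
 <InteractionList>
  <Interaction id="i1" interaction_type="complex-assembly">
   <InteractionComponentList>
    <InteractionComponent role_type="input" molecule_idref="m1"/>
    <InteractionComponent role_type="input" molecule_idref="m2"/>
    <InteractionComponent role_type="output" molecule_idref="m3"/>
   </InteractionComponentList>
  </Interaction>
  <Interaction id="i2" interaction_type="translocation">
   <InteractionComponentList>
    <InteractionComponent role_type="input" molecule_idref="m3"/>
    <InteractionComponent role_type="output" molecule_idref="m5"/>
    <InteractionComponent role_type="agent" molecule_idref="m4"/>
   </InteractionComponentList>
  </Interaction>
  <Interaction id="i3" interaction_type="macroprocess">
   <InteractionComponentList>
    <InteractionComponent role_type="input" molecule_idref="m1"/>
    <InteractionComponent role_type="output" molecule_idref="m2"/>
   </InteractionComponentList>
  </Interaction>
 </InteractionList>
</Model>
"""


def test_species_name_rendering_is_flat_and_deterministic():
    s = SpeciesName("SMAD3_SMAD4", ("active",), "nucleus")
    assert s.render() == "SMAD3_SMAD4_active_nucleus"
    assert SpeciesName("TGFB").render() == "TGFB"


def test_parse_json_three_reactions_with_roles():
    report = parse_reactions_json(THREE_REACTIONS_JSON)
    assert len(report.records) == 3 and report.skipped == 0
    r1, r2, r3 = report.records
    assert r1.kind == "complex-assembly" and len(r1.inputs) == 2
    assert r2.activators == ["IMPORTIN"]
    assert r3.inhibitors == ["SKI"] and r3.kind == "transcription"


def test_parse_json_unknown_kind_is_skipped_and_counted():
    report = parse_reactions_json(
        '[{"id": "x", "kind": "teleportation", "inputs": ["A"], "outputs": ["B"]}]'
    )
    assert report.records == [] and report.skipped == 1
    assert "teleportation" in report.messages[0]


def test_parse_json_empty_pathway():
    assert parse_reactions_json('{"reactions": []}').records == []


def test_parse_xml_roles_and_compartment_names():
    report = parse_pid_xml(SAMPLE_XML)
    assert len(report.records) == 2
    assert report.skipped == 1 and "macroprocess" in report.messages[0]
    r1, r2 = report.records
    assert sorted(r1.inputs) == ["SMAD3_active", "SMAD4"]
    assert r1.outputs == ["SMAD3_SMAD4_active_cytoplasm"]
    assert r2.activators == ["IMPORTIN"]
    assert r2.outputs == ["SMAD3_SMAD4_active_nucleus"]


def test_parse_xml_malformed_raises():
    with pytest.raises(ValueError, match="malformed"):
        parse_pid_xml("<Model><unclosed>")


def test_assembly_transitions_share_event_and_cross_condition():
    r = ReactionRecord("r1", "complex-assembly", ["S23", "S4"], ["CPLX"])
    trs = reaction_to_transitions(r)
    assert len(trs) == 2
    assert trs[0].event == trs[1].event == EventAtom("h_r1")
    by_src = {t.source: t for t in trs}
    assert by_src["S23"].condition == Var("S4")
    assert by_src["S4"].condition == Var("S23")


def test_assembly_fires_in_one_synchronized_step():
    r = ReactionRecord("r1", "complex-assembly", ["S23", "S4"], ["CPLX"])
    m = reactions_to_model([r])
    sc = Scenario.make(sorted(m.frontier()), [["h_r1"]])
    traj = simulate(m, sc)
    assert traj.states[1] == {"S23": False, "S4": False, "CPLX": True}


def test_dissociation_is_symmetric():
    r = ReactionRecord("r2", "complex-dissociation", ["CPLX"], ["S23", "S4"])
    trs = reaction_to_transitions(r)
    assert {t.target for t in trs} == {"S23", "S4"}
    assert len({t.event for t in trs}) == 1
    m = reactions_to_model([r])
    traj = simulate(m, Scenario.make(["CPLX"], [["h_r2"]]))
    assert traj.states[1] == {"CPLX": False, "S23": True, "S4": True}


def test_translocation_mediator_in_condition():
    r = ReactionRecord(
        "r3", "translocation", ["X_cytoplasm"], ["X_nucleus"],
        activators=["IMPORTIN"],
    )
    (tr,) = reaction_to_transitions(r)
    assert tr.condition == Var("IMPORTIN")


def test_inhibitor_becomes_negated_literal():
    r = ReactionRecord("r4", "modification", ["A"], ["B"], inhibitors=["SKI"])
    (tr,) = reaction_to_transitions(r)
    assert tr.condition == Not(Var("SKI"))


def test_generic_reaction_m_by_p_transitions():
    r = ReactionRecord("r5", "generic", ["A", "B"], ["C", "D"])
    trs = reaction_to_transitions(r)
    assert len(trs) == 4
    assert len({t.event for t in trs}) == 1
    m = reactions_to_model([r])
    traj = simulate(m, Scenario.make(["A", "B"], [["h_r5"]]))
    assert traj.states[1] == {"A": False, "B": False, "C": True, "D": True}


def test_empty_inputs_rejected():
    with pytest.raises(ValueError, match="no inputs"):
        reaction_to_transitions(ReactionRecord("r", "generic", [], ["B"]))


def test_merge_is_idempotent():
    report = parse_reactions_json(THREE_REACTIONS_JSON)
    m = reactions_to_model(report.records)
    merged = merge_models([m, m])
    assert len(merged.transitions) == len(m.transitions)
    assert merged.place_set == m.place_set


def test_merge_is_commutative_up_to_ordering():
    report = parse_reactions_json(THREE_REACTIONS_JSON)
    m1 = reactions_to_model(report.records[:2], name="p1")
    m2 = reactions_to_model(report.records[1:], name="p2")
    from gtreach.io import write_model

    assert write_model(merge_models([m1, m2], name="u")) == \
        write_model(merge_models([m2, m1], name="u"))


def test_merge_shared_species_counted_once():
    report = parse_reactions_json(THREE_REACTIONS_JSON)
    m1 = reactions_to_model(report.records[:2], name="p1")
    m2 = reactions_to_model(report.records[1:2], name="p2")
    shared = m1.place_set & m2.place_set
    merged = merge_models([m1, m2])
    assert len(merged.places) == len(m1.places) + len(m2.places) - len(shared)


def test_merge_combines_events_of_equal_transitions():
    # two reactions with the same input/output but different ids
    ra = ReactionRecord("a", "modification", ["A"], ["B"])
    rb = ReactionRecord("b", "modification", ["A"], ["B"])
    merged = merge_models(
        [reactions_to_model([ra]), reactions_to_model([rb])]
    )
    assert len(merged.transitions) == 1
    assert merged.transitions[0].event == Default(EventAtom("h_a"), EventAtom("h_b"))


def test_merge_loses_no_species():
    report = parse_reactions_json(THREE_REACTIONS_JSON)
    models = [reactions_to_model([r], name=r.id) for r in report.records]
    merged = merge_models(models)
    union = set().union(*(m.place_set for m in models))
    assert merged.place_set == union


def test_merged_fixture_trio_smaller_than_sum(toy):
    report = parse_reactions_json(THREE_REACTIONS_JSON)
    models = [reactions_to_model([r], name=r.id) for r in report.records]
    merged = merge_models(models)
    assert len(merged.places) < sum(len(m.places) for m in models)
    assert merged.validate() == []
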