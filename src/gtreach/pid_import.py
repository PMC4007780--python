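"""Compiling pathway reaction records into guarded-transition models.

Two input dialects are accepted:

* an NCI-PID-style XML structure (``Model/MoleculeList/Molecule`` with
  names, ``Model/InteractionList/Interaction`` with typed components in
  roles input / output / agent / inhibitor), parsed with lxml;
* a neutral JSON reaction dialect — the canonical tested path, since the
  original pathway database is frozen and offline::

      {"pathway": "...", "reactions": [
          {"id": "r1", "kind": "complex-assembly",
           "inputs": ["SMAD2_3_active", "SMAD4"],
           "outputs": ["SMAD2_3_SMAD4_active_cytoplasm"],
           "activators": [], "inhibitors": []}, ...]}

Each reaction becomes a set of single-source single-target transitions
sharing one fresh event atom (``h_<reaction id>``), so all of them fire in
the same step: an m-input, p-output reaction yields m×p transitions, each
input -> output, conditioned on the presence of the *other* inputs and the
activators and on the absence of the inhibitors.  Complex assembly and
dissociation are the m×1 and 1×p special cases — the shared event is what
synchronizes the consumption of every component with the appearance of the
complex.  Translocation, modification and transcription (gene -> protein)
are the 1×1 case, with mediators carried as activators in the condition.

Merging pathway models unifies each rendered species name to a single
place; transitions with identical (source, target, normalized condition)
coming from different reactions are merged into one transition whose event
is the ``default``-combination of the originals.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable

from lxml import etree

from .expressions import (
    And,
    CondExpr,
    EventAtom,
    Not,
    TRUE,
    Var,
    conjoin,
    merge_events,
    normalize_cond,
)
from .model import GuardedTransition, GuardedTransitionModel

logger = logging.getLogger(__name__)

REACTION_KINDS = {
    "complex-assembly",
    "complex-dissociation",
    "translocation",
    "modification",
    "transcription",
    "generic",
}


@dataclass(frozen=True)
class SpeciesName:
    """Flat, injective rendering of molecule + activity + compartment."""

    base: str
    labels: tuple[str, ...] = ()
    compartment: str = ""

    def render(self) -> str:
        parts = [self.base, *self.labels]
        if self.compartment:
            parts.append(self.compartment)
        return "_".join(parts)


@dataclass
class ReactionRecord:
    id: str
    kind: str
    inputs: list[str]
    outputs: list[str]
    activators: list[str] = field(default_factory=list)
    inhibitors: list[str] = field(default_factory=list)
    pathway: str = ""

    def validate(self) -> list[str]:
        diags = []
        if self.kind not in REACTION_KINDS:
            diags.append(f"reaction {self.id}: unknown kind {self.kind!r}")
        if not self.inputs:
            diags.append(f"reaction {self.id}: no inputs")
        if not self.outputs:
            diags.append(f"reaction {self.id}: no outputs")
        return diags


@dataclass
class ImportReport:
    records: list[ReactionRecord]
    skipped: int = 0
    messages: list[str] = field(default_factory=list)


# -- JSON dialect ----------------------------------------------------------


def parse_reactions_json(text: str) -> ImportReport:
    obj = json.loads(text)
    if isinstance(obj, list):
        obj = {"pathway": "", "reactions": obj}
    pathway = obj.get("pathway", "")
    records: list[ReactionRecord] = []
    skipped = 0
    messages: list[str] = []
    for i, r in enumerate(obj.get("reactions", [])):
        kind = r.get("kind", "generic")
        if kind not in REACTION_KINDS:
            skipped += 1
            messages.append(f"reaction #{i} ({r.get('id')}): unsupported kind {kind!r}")
            logger.warning(messages[-1])
            continue
        records.append(
            ReactionRecord(
                id=str(r.get("id", f"r{i}")),
                kind=kind,
                inputs=list(r.get("inputs", [])),
                outputs=list(r.get("outputs", [])),
                activators=list(r.get("activators", [])),
                inhibitors=list(r.get("inhibitors", [])),
                pathway=pathway,
            )
        )
    return ImportReport(records, skipped, messages)


# -- XML dialect -----------------------------------------------------------

_XML_KIND_MAP = {
    "complex-assembly": "complex-assembly",
    "complex-dissociation": "complex-dissociation",
    "translocation": "translocation",
    "modification": "modification",
    "transcription": "transcription",
    "reaction": "generic",
    "generic": "generic",
}

_ROLE_MAP = {
    "input": "inputs",
    "output": "outputs",
    "agent": "activators",
    "inhibitor": "inhibitors",
}


def _molecule_name(mol: etree._Element) -> str:
    base = mol.get("name") or ""
    name_el = mol.find("Name")
    if name_el is not None and name_el.get("value"):
        base = name_el.get("value")
    labels = tuple(
        lbl.get("value")
        for lbl in mol.findall("Label")
        if lbl.get("value")
    )
    compartment = mol.get("compartment", "")
    return SpeciesName(base, labels, compartment).render()


def parse_pid_xml(text: str | bytes) -> ImportReport:
    """Parse an NCI-PID-style XML document into reaction records.

    Unknown interaction types are counted and logged, never silently
    dropped; schema problems are reported with the element path."""
    if isinstance(text, str):
        text = text.encode()
    try:
        root = etree.fromstring(text)
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"malformed XML: {exc}") from exc

    molecules: dict[str, str] = {}
    for mol in root.iter("Molecule"):
        mid = mol.get("id")
        if mid is None:
            raise ValueError(f"Molecule without id at {root.getroottree().getpath(mol)}")
        molecules[mid] = _molecule_name(mol)

    records: list[ReactionRecord] = []
    skipped = 0
    messages: list[str] = []
    for inter in root.iter("Interaction"):
        iid = inter.get("id", f"i{len(records) + skipped}")
        itype = (inter.get("interaction_type") or "").strip().lower()
        kind = _XML_KIND_MAP.get(itype)
        if kind is None:
            skipped += 1
            path = root.getroottree().getpath(inter)
            messages.append(f"{path}: unsupported interaction_type {itype!r}")
            logger.warning(messages[-1])
            continue
        rec = ReactionRecord(id=iid, kind=kind, inputs=[], outputs=[])
        for comp in inter.iter("InteractionComponent"):
            role = (comp.get("role_type") or "").strip().lower()
            ref = comp.get("molecule_idref")
            if role not in _ROLE_MAP:
                raise ValueError(
                    f"{root.getroottree().getpath(comp)}: unknown role_type {role!r}"
                )
            if ref not in molecules:
                raise ValueError(
                    f"{root.getroottree().getpath(comp)}: unresolved molecule_idref {ref!r}"
                )
            getattr(rec, _ROLE_MAP[role]).append(molecules[ref])
        records.append(rec)
    return ImportReport(records, skipped, messages)


# -- reaction -> transitions ----------------------------------------------


def reaction_to_transitions(r: ReactionRecord) -> list[GuardedTransition]:
    """m×p single-source single-target transitions sharing one fresh event.

    Every transition's condition requires the other inputs (so a complex
    only forms when all components are present) and the activators, and
    forbids the inhibitors."""
    diags = r.validate()
    if diags:
        raise ValueError("; ".join(diags))
    event = EventAtom(f"h_{r.id}")
    base_terms: list[CondExpr] = [Var(a) for a in sorted(set(r.activators))]
    base_terms += [Not(Var(i)) for i in sorted(set(r.inhibitors))]
    out: list[GuardedTransition] = []
    for src in r.inputs:
        others = [Var(x) for x in r.inputs if x != src]
        cond = conjoin(others + base_terms)
        for dst in r.outputs:
            out.append(GuardedTransition(src, dst, event, cond))
    return out


def reactions_to_model(
    records: Iterable[ReactionRecord], name: str = "pathway"
) -> GuardedTransitionModel:
    places: dict[str, None] = {}
    transitions: list[GuardedTransition] = []
    for r in records:
        for tr in reaction_to_transitions(r):
            transitions.append(tr)
            for p in (
                [tr.source, tr.target]
                + sorted(tr.condition.places() | tr.event.condition_places())
            ):
                places.setdefault(p, None)
    return GuardedTransitionModel(list(places), transitions, name=name)


# -- union of pathway models ----------------------------------------------


def merge_models(
    models: Iterable[GuardedTransitionModel], name: str = "merged"
) -> GuardedTransitionModel:
    """Union with redundancy removal: one place per species name; identical
    transitions deduplicated; transitions equal up to the event merged into
    one with the ``default``-combined event.  Idempotent and commutative
    up to ordering."""
    places: set[str] = set()
    groups: dict[tuple[str, str, str], dict[str, object]] = {}
    for m in models:
        places |= m.place_set
        for tr in m.transitions:
            cond = normalize_cond(tr.condition)
            key = (tr.source, tr.target, cond.unparse())
            grp = groups.setdefault(key, {"cond": cond, "events": {}})
            grp["events"][tr.event.unparse()] = tr.event
    transitions = []
    for (src, dst, _), grp in sorted(groups.items()):
        event = merge_events(grp["events"].values())
        transitions.append(GuardedTransition(src, dst, event, grp["cond"]))
    merged = GuardedTransitionModel(sorted(places), transitions, name=name)
    return merged
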