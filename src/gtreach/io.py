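"""Reading and writing models in the plain-text dialect and its JSON mirror.

Text dialect, one statement per line, ``#`` starts a comment::

    place TGFB;
    trans TGFB -[a1 [TGFBR]]-> TGFB_TGFBR_active;
    trans SMAD2_3 -[(a2 when RECEPTOR) default a9]-> SMAD2_3_active;

A guard is an event expression (atoms, ``default``, ``when``) optionally
followed by a bracketed condition over places (``and``, ``or``, ``not``,
``true``, ``false``).  Writing sorts places and transitions by name, so the
output is bit-stable for a given model.

Timing scripts are one line per step, listing the present event atoms
separated by whitespace; ``%`` marks an explicitly idle (empty) step.
"""

from __future__ import annotations

import json
import re
from typing import Iterable

from .expressions import (
    And,
    CondExpr,
    Const,
    Default,
    EventAtom,
    EventExpr,
    FALSE,
    Not,
    Or,
    TRUE,
    Var,
    When,
)
from .model import GuardedTransition, GuardedTransitionModel


class ModelSyntaxError(ValueError):
    """Parse failure; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line else message)


_KEYWORDS = {"default", "when", "and", "or", "not", "true", "false"}
_TOKEN_RE = re.compile(r"\s*([A-Za-z_][\w.:-]*|[()\[\]])")


def _tokenize(text: str, line: int | None = None) -> list[str]:
    tokens: list[str] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if not m:
            if text[pos:].strip():
                raise ModelSyntaxError(f"unexpected character {text[pos:].strip()[0]!r}", line)
            break
        tokens.append(m.group(1))
        pos = m.end()
    return tokens


class _Parser:
    """Recursive-descent parser over a guard token stream."""

    def __init__(self, tokens: list[str], line: int | None = None):
        self.toks = tokens
        self.i = 0
        self.line = line

    def peek(self) -> str | None:
        return self.toks[self.i] if self.i < len(self.toks) else None

    def pop(self) -> str:
        if self.i >= len(self.toks):
            raise ModelSyntaxError("unexpected end of expression", self.line)
        tok = self.toks[self.i]
        self.i += 1
        return tok

    def expect(self, tok: str) -> None:
        got = self.pop()
        if got != tok:
            raise ModelSyntaxError(f"expected {tok!r}, got {got!r}", self.line)

    # events ---------------------------------------------------------------

    def event_expr(self) -> EventExpr:
        left = self.event_when()
        while self.peek() == "default":
            self.pop()
            left = Default(left, self.event_when())
        return left

    def event_when(self) -> EventExpr:
        left = self.event_primary()
        while self.peek() == "when":
            self.pop()
            left = When(left, self.cond_primary())
        return left

    def event_primary(self) -> EventExpr:
        tok = self.pop()
        if tok == "(":
            inner = self.event_expr()
            self.expect(")")
            return inner
        if tok in _KEYWORDS or tok in "()[]":
            raise ModelSyntaxError(f"expected event atom, got {tok!r}", self.line)
        return EventAtom(tok)

    # conditions -----------------------------------------------------------

    def cond_expr(self) -> CondExpr:
        terms = [self.cond_and()]
        while self.peek() == "or":
            self.pop()
            terms.append(self.cond_and())
        return terms[0] if len(terms) == 1 else Or(*terms)

    def cond_and(self) -> CondExpr:
        terms = [self.cond_unary()]
        while self.peek() == "and":
            self.pop()
            terms.append(self.cond_unary())
        return terms[0] if len(terms) == 1 else And(*terms)

    def cond_unary(self) -> CondExpr:
        if self.peek() == "not":
            self.pop()
            return Not(self.cond_unary())
        return self.cond_primary()

    def cond_primary(self) -> CondExpr:
        tok = self.pop()
        if tok == "(":
            inner = self.cond_expr()
            self.expect(")")
            return inner
        if tok == "true":
            return TRUE
        if tok == "false":
            return FALSE
        if tok in _KEYWORDS or tok in "()[]":
            raise ModelSyntaxError(f"expected place name, got {tok!r}", self.line)
        return Var(tok)

    def at_end(self) -> bool:
        return self.i >= len(self.toks)


def parse_cond(text: str, line: int | None = None) -> CondExpr:
    p = _Parser(_tokenize(text, line), line)
    expr = p.cond_expr()
    if not p.at_end():
        raise ModelSyntaxError(f"trailing tokens after condition: {p.peek()!r}", line)
    return expr


def parse_event(text: str, line: int | None = None) -> EventExpr:
    p = _Parser(_tokenize(text, line), line)
    expr = p.event_expr()
    if not p.at_end():
        raise ModelSyntaxError(f"trailing tokens after event: {p.peek()!r}", line)
    return expr


def parse_guard(text: str, line: int | None = None) -> tuple[EventExpr, CondExpr]:
    """Parse ``EVENT_EXPR [COND_EXPR]`` (the condition is optional)."""
    p = _Parser(_tokenize(text, line), line)
    event = p.event_expr()
    cond: CondExpr = TRUE
    if p.peek() == "[":
        p.pop()
        cond = p.cond_expr()
        p.expect("]")
    if not p.at_end():
        raise ModelSyntaxError(f"trailing tokens in guard: {p.peek()!r}", line)
    return event, cond


_TRANS_RE = re.compile(r"^trans\s+(\S+)\s+-\[(.*)\]->\s+(\S+)$")


def read_model(text: str, name: str = "model") -> GuardedTransitionModel:
    places: list[str] = []
    transitions: list[GuardedTransition] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if not line.endswith(";"):
            raise ModelSyntaxError("statement must end with ';'", lineno)
        stmt = line[:-1].strip()
        if stmt.startswith("place "):
            pname = stmt[len("place "):].strip()
            if not pname or len(pname.split()) != 1:
                raise ModelSyntaxError(f"bad place declaration {stmt!r}", lineno)
            places.append(pname)
        elif stmt.startswith("trans "):
            m = _TRANS_RE.match(stmt)
            if not m:
                raise ModelSyntaxError(f"bad transition syntax {stmt!r}", lineno)
            src, guard, dst = m.group(1), m.group(2), m.group(3)
            event, cond = parse_guard(guard, lineno)
            transitions.append(GuardedTransition(src, dst, event, cond))
        else:
            raise ModelSyntaxError(f"unknown statement {stmt.split()[0]!r}", lineno)
    return GuardedTransitionModel(places, transitions, name=name)


def write_model(model: GuardedTransitionModel) -> str:
    m = model.sorted_copy()
    lines = [f"# model {m.name}"]
    lines += [f"place {p};" for p in m.places]
    lines += [tr.unparse() for tr in m.transitions]
    return "\n".join(lines) + "\n"


# JSON mirror ---------------------------------------------------------------


def model_to_json(model: GuardedTransitionModel) -> str:
    m = model.sorted_copy()
    obj = {
        "name": m.name,
        "places": m.places,
        "transitions": [
            {
                "source": tr.source,
                "target": tr.target,
                "event": tr.event.unparse(),
                "condition": tr.condition.unparse(),
            }
            for tr in m.transitions
        ],
    }
    return json.dumps(obj, indent=1, sort_keys=True) + "\n"


def model_from_json(text: str) -> GuardedTransitionModel:
    obj = json.loads(text)
    transitions = [
        GuardedTransition(
            t["source"],
            t["target"],
            parse_event(t["event"]),
            parse_cond(t.get("condition", "true")),
        )
        for t in obj.get("transitions", [])
    ]
    return GuardedTransitionModel(
        obj.get("places", []), transitions, name=obj.get("name", "model")
    )


# Timing scripts ------------------------------------------------------------


def parse_timing(text: str) -> list[frozenset[str]]:
    steps: list[frozenset[str]] = []
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line == "%":
            steps.append(frozenset())
        else:
            steps.append(frozenset(line.split()))
    return steps


def write_timing(timing: Iterable[frozenset[str]]) -> str:
    lines = []
    for step in timing:
        lines.append(" ".join(sorted(step)) if step else "%")
    return "\n".join(lines) + "\n"
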