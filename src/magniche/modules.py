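"""KEGG-module completeness scoring from KO annotations.

A module definition is a boolean expression over KO identifiers:

* space — serial reaction steps, all required (AND); steps are counted at the
  top level of the definition only;
* comma — alternative orthologs or sub-paths (OR);
* plus — subunits of a complex, all required (AND within a step);
* minus — non-essential component (neither required nor counted);
* parentheses — grouping; a parenthesised sub-sequence counts as one step.

Completeness of a module for a given KO set is 100 × (satisfied steps) /
(total steps).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .io import FeatureMatrix, ModuleRow

logger = logging.getLogger("magniche.modules")

KO_RE = re.compile(r"K\d{5}")
IDENT_RE = re.compile(r"[A-Za-z][A-Za-z0-9_.]*")


class ModuleParseError(ValueError):
    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


@dataclass
class Node:
    """Expression-tree node: LEAF | OR | COMPLEX | SEQUENCE."""

    kind: str
    ko: str | None = None
    children: list["Node"] = field(default_factory=list)
    optional: list[bool] = field(default_factory=list)  # COMPLEX only, per child

    def evaluate(self, kos: frozenset[str] | set[str]) -> bool:
        if self.kind == "LEAF":
            return self.ko in kos
        if self.kind == "OR":
            return any(c.evaluate(kos) for c in self.children)
        if self.kind == "COMPLEX":
            required = [
                c for c, opt in zip(self.children, self.optional) if not opt
            ]
            return all(c.evaluate(kos) for c in required)  # all-optional => True
        if self.kind == "SEQUENCE":
            return all(c.evaluate(kos) for c in self.children)
        raise AssertionError(self.kind)

    def leaves(self) -> set[str]:
        if self.kind == "LEAF":
            return {self.ko}
        out: set[str] = set()
        for c in self.children:
            out |= c.leaves()
        return out

    def unparse(self) -> str:
        if self.kind == "LEAF":
            return self.ko
        if self.kind == "SEQUENCE":
            return " ".join(
                f"({c.unparse()})" if c.kind == "SEQUENCE" else c.unparse()
                for c in self.children
            )
        if self.kind == "OR":
            parts = []
            for c in self.children:
                s = c.unparse()
                parts.append(f"({s})" if c.kind in ("SEQUENCE", "OR") else s)
            return ",".join(parts)
        parts = []
        for c, opt in zip(self.children, self.optional):
            s = c.unparse()
            if c.kind != "LEAF":
                s = f"({s})"
            parts.append(("-" if opt else "+") + s if parts or opt else s)
        return "".join(parts)


@dataclass(frozen=True)
class ModuleDefinition:
    module_id: str
    name: str
    definition: str
    tree: Node

    @property
    def steps(self) -> list[Node]:
        return self.tree.children if self.tree.kind == "SEQUENCE" else [self.tree]


@dataclass(frozen=True)
class ModuleCompleteness:
    mag_id: str
    module_id: str
    n_steps: int
    n_satisfied: int

    @property
    def completeness(self) -> float:
        return 100.0 * self.n_satisfied / self.n_steps if self.n_steps else 0.0


class _Parser:
    """Recursive-descent parser; precedence: space < comma < plus/minus."""

    def __init__(self, text: str):
        self.text = text
        self.pos = 0

    def error(self, msg: str) -> ModuleParseError:
        return ModuleParseError(msg, self.pos)

    def peek(self) -> str:
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def parse(self) -> Node:
        node = self.parse_sequence()
        if self.pos < len(self.text):
            raise self.error(f"unexpected {self.peek()!r}")
        return node

    def skip_spaces(self) -> None:
        while self.peek() == " ":
            self.pos += 1

    def parse_sequence(self) -> Node:
        steps = [self.parse_alternatives()]
        while True:
            if self.peek() != " ":
                break
            self.skip_spaces()
            if self.peek() in ("", ")"):
                break
            steps.append(self.parse_alternatives())
        steps = [s for s in steps if s is not None]
        if not steps:
            raise self.error("empty definition")
        if len(steps) == 1:
            return steps[0]
        return Node("SEQUENCE", children=steps)

    def parse_alternatives(self) -> Node | None:
        branches = [self.parse_complex()]
        while self.peek() == ",":
            self.pos += 1
            nxt = self.parse_complex()
            branches.append(nxt)
        branches = [b for b in branches if b is not None]
        if not branches:
            return None
        if len(branches) == 1:
            return branches[0]
        return Node("OR", children=branches)

    def parse_complex(self) -> Node | None:
        first = self.parse_atom()
        children: list[Node] = [] if first is None else [first]
        optional: list[bool] = [] if first is None else [False]
        while self.peek() in ("+", "-"):
            opt = self.peek() == "-"
            self.pos += 1
            atom = self.parse_atom()
            if atom is None:
                continue  # gap token after the sign
            children.append(atom)
            optional.append(opt)
        if not children:
            return None
        if len(children) == 1 and not optional[0]:
            return children[0]
        return Node("COMPLEX", children=children, optional=optional)

    def parse_atom(self) -> Node | None:
        if self.peek() == "(":
            open_pos = self.pos
            self.pos += 1
            inner = self.parse_sequence()
            if self.peek() != ")":
                self.pos = open_pos
                raise self.error("unbalanced parenthesis")
            self.pos += 1
            return inner
        if self.text.startswith("--", self.pos):
            logger.warning("ignoring gap token '--' in module definition")
            self.pos += 2
            return None
        m = IDENT_RE.match(self.text, self.pos)
        if not m:
            if self.peek() == ")":
                raise self.error("unbalanced parenthesis")
            raise self.error(
                "expected identifier" if self.peek() else "empty alternative"
            )
        self.pos = m.end()
        return Node("LEAF", ko=m.group(0))


def parse_module(definition: str) -> Node:
    """Parse a module-definition expression into its tree."""
    definition = definition.strip()
    if not definition:
        raise ModuleParseError("empty definition", 0)
    return _Parser(definition).parse()


def load_modules(rows: Iterable[ModuleRow]) -> list[ModuleDefinition]:
    return [
        ModuleDefinition(r.module_id, r.name, r.definition, parse_module(r.definition))
        for r in rows
    ]


def module_completeness(module: ModuleDefinition, kos: Iterable[str],
                        mag_id: str = "") -> ModuleCompleteness:
    """Fraction of top-level steps whose expression is satisfied by the KO set."""
    koset = frozenset(kos)
    steps = module.steps
    satisfied = sum(1 for s in steps if s.evaluate(koset))
    return ModuleCompleteness(
        mag_id=mag_id, module_id=module.module_id,
        n_steps=len(steps), n_satisfied=satisfied,
    )


def completeness_report(
    modules: Sequence[ModuleDefinition],
    ko_features: FeatureMatrix,
    threshold: float = 75.0,
    extra_annotation_sets: dict[str, set[str]] | None = None,
) -> pd.DataFrame:
    """Per-MAG (and optional host/symbiont protein set) module completeness.

    ``flag`` marks completeness strictly above the reporting threshold
    (75 % by default). ``extra_annotation_sets`` maps additional labels
    (e.g. host and algal-symbiont proteomes) to their KO sets.
    """
    presence = ko_features.binarize()
    universe = set(presence.columns)
    rows = []
    entities: list[tuple[str, set[str]]] = [
        (mag, set(presence.columns[presence.loc[mag] > 0])) for mag in presence.index
    ]
    for label, kos in (extra_annotation_sets or {}).items():
        entities.append((label, set(kos)))
    for module in modules:
        if not (module.tree.leaves() & universe):
            logger.info("module %s references no KO in the annotation universe", module.module_id)
        for entity, kos in entities:
            mc = module_completeness(module, kos, mag_id=entity)
            rows.append(
                {
                    "mag_id": entity, "module_id": module.module_id,
                    "n_steps": mc.n_steps, "n_satisfied": mc.n_satisfied,
                    "completeness": mc.completeness,
                    "flag": mc.completeness > threshold,
                }
            )
    return pd.DataFrame(
        rows, columns=["mag_id", "module_id", "n_steps", "n_satisfied", "completeness", "flag"]
    )
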