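"""ACMG/AMP evidence-code combining engine.

Takes a set of standardized evidence codes (PVS1, PS1-4, PM1-6, PP1-5 on the
pathogenic side; BA1, BS1-4, BP1-7 on the benign side) and combines them into
a classification in {P, LP, VUS-LP, VUS, LB, B} using the published
combining-rule table, shipped as a human-readable TSV so the clause set can
be audited or swapped without touching code.

The VUS-LP ("VUS-favor pathogenic") sublabel is a refinement of VUS used by
the three-tier secondary-finding ranking: evidence that leans pathogenic
(at least one moderate and two supporting pathogenic criteria, no benign
criterion) without reaching the likely-pathogenic bar. It is isolated in a
single clause of the rule table.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

from .errors import ConfigError, VocabularyError

_RULES_RESOURCE = "combining_rules_v1.tsv"

#: Closed vocabulary of ACMG/AMP evidence codes, mapped to strength category.
CODE_STRENGTH: dict[str, str] = {"PVS1": "PVS", "BA1": "BA"}
CODE_STRENGTH.update({f"PS{i}": "PS" for i in range(1, 5)})
CODE_STRENGTH.update({f"PM{i}": "PM" for i in range(1, 7)})
CODE_STRENGTH.update({f"PP{i}": "PP" for i in range(1, 6)})
CODE_STRENGTH.update({f"BS{i}": "BS" for i in range(1, 5)})
CODE_STRENGTH.update({f"BP{i}": "BP" for i in range(1, 8)})

VALID_CODES = frozenset(CODE_STRENGTH)

STRENGTH_CATEGORIES = ("PVS", "PS", "PM", "PP", "BA", "BS", "BP")

CLASSIFICATION_RANK = {"B": 0, "LB": 1, "VUS": 2, "VUS-LP": 3, "LP": 4, "P": 5}

_CONDITION_RE = re.compile(r"^(PVS|PS|PM|PP|BA|BS|BP)(>=|==)(\d+)$")


def parse_codes(text: str) -> frozenset[str]:
    """Parse a comma-separated evidence-code string, e.g. ``"PVS1,PM2,PP5"``."""
    if not text or not text.strip():
        return frozenset()
    codes = [c.strip() for c in text.split(",") if c.strip()]
    return validate_codes(codes)


def validate_codes(codes: Iterable[str]) -> frozenset[str]:
    result = frozenset(codes)
    unknown = sorted(result - VALID_CODES)
    if unknown:
        raise VocabularyError(f"unknown ACMG evidence code(s): {', '.join(unknown)}")
    return result


def strength_counts(codes: Iterable[str]) -> dict[str, int]:
    """Count evidence codes per strength category (PVS, PS, PM, PP, BA, BS, BP)."""
    counts = {cat: 0 for cat in STRENGTH_CATEGORIES}
    for code in validate_codes(codes):
        counts[CODE_STRENGTH[code]] += 1
    return counts


@dataclass(frozen=True)
class Clause:
    """One combining-rule clause: an outcome and minimum/absence conditions."""

    name: str
    outcome: str
    conditions: tuple[tuple[str, str, int], ...]  # (category, op, count)

    def fires(self, counts: dict[str, int]) -> bool:
        for category, op, n in self.conditions:
            have = counts[category]
            if op == ">=" and have < n:
                return False
            if op == "==" and have != n:
                return False
        return True

    def describe(self) -> str:
        parts = [f"{cat}{op}{n}" for cat, op, n in self.conditions]
        return f"{self.name}[{' & '.join(parts)} -> {self.outcome}]"


@dataclass(frozen=True)
class CombiningRuleTable:
    """The full declarative clause set plus the VUS fallback."""

    clauses: tuple[Clause, ...]

    def __post_init__(self) -> None:
        outcomes = {c.outcome for c in self.clauses}
        for required in ("P", "LP", "B", "LB"):
            if required not in outcomes:
                raise ConfigError(f"rule table lacks any {required} clause")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CombiningRuleTable":
        clauses = []
        with open(path) as handle:
            header_seen = False
            for lineno, raw in enumerate(handle, 1):
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                if not header_seen:
                    if line.split("\t") != ["name", "outcome", "conditions"]:
                        raise ConfigError(f"{path}:{lineno}: bad rule-table header")
                    header_seen = True
                    continue
                fields = line.split("\t")
                if len(fields) != 3:
                    raise ConfigError(f"{path}:{lineno}: expected 3 tab-separated fields")
                name, outcome, cond_text = fields
                if outcome not in CLASSIFICATION_RANK:
                    raise ConfigError(f"{path}:{lineno}: unknown outcome {outcome!r}")
                conditions = []
                for token in cond_text.split(","):
                    m = _CONDITION_RE.match(token.strip())
                    if m is None:
                        raise ConfigError(f"{path}:{lineno}: bad condition {token!r}")
                    conditions.append((m.group(1), m.group(2), int(m.group(3))))
                clauses.append(Clause(name, outcome, tuple(conditions)))
        return cls(tuple(clauses))


def default_rule_table() -> CombiningRuleTable:
    source = resources.files("sfscreen.data").joinpath(_RULES_RESOURCE)
    with resources.as_file(source) as path:
        return CombiningRuleTable.from_tsv(path)


_DEFAULT_TABLE: Optional[CombiningRuleTable] = None


def _table(table: Optional[CombiningRuleTable]) -> CombiningRuleTable:
    global _DEFAULT_TABLE
    if table is not None:
        return table
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = default_rule_table()
    return _DEFAULT_TABLE


@dataclass(frozen=True)
class CombinationResult:
    """Classification plus the audit trail of fired clauses."""

    classification: str
    fired: tuple[Clause, ...]
    winning: Optional[Clause]

    @property
    def rank(self) -> int:
        return CLASSIFICATION_RANK[self.classification]


def explain(codes: Iterable[str], table: Optional[CombiningRuleTable] = None) -> CombinationResult:
    """Combine evidence codes and report every satisfied clause.

    Precedence: P over LP on the pathogenic side and B over LB on the benign
    side; if clauses fire on both sides the evidence is contradictory and the
    result is VUS. The VUS-LP sublabel clause applies only when neither side
    fires. An empty or insufficient code set falls back to VUS.
    """
    ruleset = _table(table)
    counts = strength_counts(codes)
    fired = tuple(c for c in ruleset.clauses if c.fires(counts))

    pathogenic = [c for c in fired if c.outcome in ("P", "LP")]
    benign = [c for c in fired if c.outcome in ("B", "LB")]
    sublabel = [c for c in fired if c.outcome == "VUS-LP"]

    if pathogenic and benign:
        return CombinationResult("VUS", fired, None)
    if pathogenic:
        winner = min(pathogenic, key=lambda c: 0 if c.outcome == "P" else 1)
        return CombinationResult(winner.outcome, fired, winner)
    if benign:
        winner = min(benign, key=lambda c: 0 if c.outcome == "B" else 1)
        return CombinationResult(winner.outcome, fired, winner)
    if sublabel:
        return CombinationResult("VUS-LP", fired, sublabel[0])
    return CombinationResult("VUS", fired, None)


def combine(codes: Iterable[str], table: Optional[CombiningRuleTable] = None) -> str:
    """Combine an evidence-code set into {P, LP, VUS-LP, VUS, LB, B}."""
    return explain(codes, table).classification


def classification_rank(value: str) -> int:
    if value not in CLASSIFICATION_RANK:
        raise VocabularyError(f"unknown classification {value!r}")
    return CLASSIFICATION_RANK[value]
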