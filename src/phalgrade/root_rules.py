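"""Rule-based root-system grading from eight per-view root counts.

A seedling's root vigor is judged from the eight side views.  Each view's
visible-root count is binned into three classes — at least 3 roots, exactly
2, or at most 1 — and the per-view bins are summarized into the triple
(a, b, c): the number of views falling in each bin (a + b + c = 8).  A small
rule table maps the summary to a root grade G in {1, 2, 3} (3 best).

The published rule rows do not cover every one of the 45 possible summaries;
uncovered combinations fall to a documented fallback and are flagged so the
provenance of every grade can be audited.  The rule set is data, not code:
farms can load their own standards from YAML/JSON.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

__all__ = [
    "RootViewSummary",
    "summarize_views",
    "Rule",
    "RuleSet",
    "DEFAULT_RULES",
    "rule_grade",
    "enumerate_rule_table",
]

# Bin edges: a view counts toward `a` with >=3 roots, `b` with exactly 2,
# `c` with <=1.
_MANY = 3


@dataclass(frozen=True)
class RootViewSummary:
    """Counts of views per root-count bin; a + b + c = number of views (8)."""

    a: int  # views with >= 3 visible roots
    b: int  # views with exactly 2
    c: int  # views with <= 1

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) < 0:
            raise ValueError(f"negative bin count in {self}")

    @property
    def n_views(self) -> int:
        return self.a + self.b + self.c


def summarize_views(counts) -> RootViewSummary:
    """Bin eight per-view root counts into the (a, b, c) summary."""
    counts = list(counts)
    if len(counts) != 8:
        raise ValueError(f"expected 8 per-view root counts, got {len(counts)}")
    if any(int(c) != c or c < 0 for c in counts):
        raise ValueError("root counts must be nonnegative integers")
    a = sum(1 for c in counts if c >= _MANY)
    b = sum(1 for c in counts if c == 2)
    return RootViewSummary(a=a, b=b, c=8 - a - b)


@dataclass(frozen=True)
class Rule:
    """One grading rule: conditions on a/b/c, each (op, value) with op in
    {'eq', 'le', 'ge'}; absent fields are unconstrained."""

    grade: int
    conditions: tuple[tuple[str, str, int], ...]  # (field, op, value)
    name: str = ""

    def matches(self, s: RootViewSummary) -> bool:
        for field_name, op, value in self.conditions:
            v = getattr(s, field_name)
            if op == "eq" and v != value:
                return False
            if op == "le" and v > value:
                return False
            if op == "ge" and v < value:
                return False
        return True


def _r(grade: int, name: str, **kw: str) -> Rule:
    conds = []
    for key, spec in kw.items():
        op, _, val = spec.partition(" ")
        conds.append((key, op, int(val)))
    return Rule(grade=grade, conditions=tuple(conds), name=name)


#: The shipped grading standard.  Nine printed rows, evaluated best grade
#: first; rows within a grade are mutually exclusive over a+b+c=8.
DEFAULT_RULES: tuple[Rule, ...] = (
    _r(3, "3.1", a="eq 8"),
    _r(3, "3.2", a="eq 7", b="eq 1"),
    _r(2, "2.1", a="eq 7", c="eq 1"),
    _r(2, "2.2", a="eq 6", b="eq 1", c="eq 1"),
    _r(2, "2.3", a="le 6", b="ge 2", c="eq 0"),
    _r(1, "1.1", a="le 6", c="ge 2"),
    _r(1, "1.2", a="eq 4", b="eq 2", c="eq 2"),
    _r(1, "1.3", a="le 4", b="ge 2", c="ge 2"),
)


class RuleSet:
    """An ordered rule list plus the fallback policy for uncovered summaries.

    Fallback: summaries with c >= 2 grade 1; otherwise a >= 5 grades 2;
    anything else grades 1.  This extends the pattern of the shipped table,
    where two or more weak views always mean the lowest grade and b-heavy
    mid-range summaries sit in the middle grade.
    """

    def __init__(self, rules: tuple[Rule, ...] = DEFAULT_RULES):
        self.rules = tuple(sorted(rules, key=lambda r: -r.grade))

    def grade(self, s: RootViewSummary) -> tuple[int, str, bool]:
        """Return (grade, rule name, is_fallback)."""
        for rule in self.rules:
            if rule.matches(s):
                return rule.grade, rule.name, False
        if s.c >= 2:
            return 1, "fallback", True
        if s.a >= 5:
            return 2, "fallback", True
        return 1, "fallback", True

    @classmethod
    def from_file(cls, path: str | Path) -> "RuleSet":
        """Load rules from YAML/JSON: a list of {grade, name, conditions:
        {a: "eq 8", ...}} mappings."""
        data = yaml.safe_load(Path(path).read_text())
        rules = []
        for i, entry in enumerate(data):
            rules.append(
                _r(int(entry["grade"]), str(entry.get("name", f"rule-{i}")),
                   **entry.get("conditions", {}))
            )
        return cls(tuple(rules))

    def to_file(self, path: str | Path) -> None:
        entries = [
            {
                "grade": r.grade,
                "name": r.name,
                "conditions": {f: f"{op} {v}" for f, op, v in r.conditions},
            }
            for r in self.rules
        ]
        Path(path).write_text(yaml.safe_dump(entries, sort_keys=False))


def rule_grade(s: RootViewSummary, rules: RuleSet | None = None) -> int:
    """Map an (a, b, c) summary to a root grade in {1, 2, 3}; total and
    deterministic over all 45 summaries."""
    return (rules or _DEFAULT_RULESET).grade(s)[0]


_DEFAULT_RULESET = RuleSet()


def enumerate_rule_table(rules: RuleSet | None = None) -> pd.DataFrame:
    """Exhaustive audit: all 45 summaries with a+b+c=8, their grades, the
    matching rule, and whether the fallback fired."""
    rules = rules or _DEFAULT_RULESET
    rows = []
    for a in range(9):
        for b in range(9 - a):
            s = RootViewSummary(a=a, b=b, c=8 - a - b)
            grade, name, fallback = rules.grade(s)
            rows.append(
                {"a": s.a, "b": s.b, "c": s.c, "grade": grade,
                 "rule": name, "fallback": fallback}
            )
    return pd.DataFrame(rows)
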