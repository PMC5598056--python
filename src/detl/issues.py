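"""Shared issue/severity types for rule-structure and data validation.

A :class:`ValidationIssue` never carries source data values: reports cite a
rule id, a location (table/column/line number) and a message only, so that
issue logs can be shared without exposing protected health information.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional


class Severity(enum.Enum):
    """ERROR fails the dataset (re-extraction required); WARNING never does."""

    ERROR = "ERROR"
    WARNING = "WARNING"


@dataclass(frozen=True)
class ValidationIssue:
    """One detected problem in extracted data or in a rule set.

    ``line_number`` is 1-based over *data* rows (the header row is excluded);
    it is ``None`` for issues that are not tied to a single line (e.g. a
    schema-level warning, or a rule-structure violation).
    """

    rule_id: str
    severity: Severity
    message: str
    table: Optional[str] = None
    column: Optional[str] = None
    line_number: Optional[int] = None

    def as_dict(self) -> dict:
        return {
            "rule_id": self.rule_id,
            "severity": self.severity.value,
            "table": self.table,
            "column": self.column,
            "line_number": self.line_number,
            "message": self.message,
        }


@dataclass
class ValidationReport:
    """Aggregated verdict over a list of issues.

    The dataset fails exactly when at least one ERROR is present; warnings
    are informational and never fail validation.
    """

    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def n_errors(self) -> int:
        return sum(1 for i in self.issues if i.severity is Severity.ERROR)

    @property
    def n_warnings(self) -> int:
        return sum(1 for i in self.issues if i.severity is Severity.WARNING)

    @property
    def passed(self) -> bool:
        return self.n_errors == 0

    @property
    def verdict(self) -> str:
        return "PASS" if self.passed else "FAIL"

    def counts_by_rule(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for i in self.issues:
            out[i.rule_id] = out.get(i.rule_id, 0) + 1
        return out

    def counts_by_table(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for i in self.issues:
            key = i.table or ""
            out[key] = out.get(key, 0) + 1
        return out

    def as_dict(self) -> dict:
        return {
            "verdict": self.verdict,
            "n_errors": self.n_errors,
            "n_warnings": self.n_warnings,
            "by_rule": self.counts_by_rule(),
            "by_table": self.counts_by_table(),
            "issues": [i.as_dict() for i in self.issues],
        }
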