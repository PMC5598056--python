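"""Pre-transformation validation of extracted CSV data.

Extracted data must satisfy the assumptions the transformation step makes:
date/timestamp cells parse, required fields are populated, numerics are
numbers, text fits its declared length, and foreign keys resolve.  Failing
cells are reported by table, column and 1-based data line number only —
never by value — so reports can circulate without exposing patient data.

Severities follow the standing convention: an ERROR means the extract fails
validation and must be re-extracted after the problem is fixed; a WARNING is
informational and dealing with it is optional.  ``strict`` mode keeps every
severity as classified; ``loose`` mode downgrades length-overflow and
numeric-parse failures to warnings for sites still converging on their
extraction conventions.
"""

from __future__ import annotations

import csv
import re
from decimal import Decimal, InvalidOperation
from pathlib import Path

from .issues import Severity, ValidationIssue, ValidationReport
from .schema import TableSpec

#: validation-rule identifiers (stable, machine-readable)
RULE_INVALID_DATE = "invalid-date"
RULE_MISSING_REQUIRED = "missing-required"
RULE_MISSING_LENGTH = "schema-missing-length"
RULE_INVALID_NUMERIC = "invalid-numeric"
RULE_OVERLENGTH = "overlength"
RULE_EXTRA_COLUMN = "extra-column"
RULE_MISSING_COLUMN = "missing-column"
RULE_ORPHAN_FK = "orphan-foreign-key"

#: rules whose severity drops to WARNING in loose mode
_LOOSE_DOWNGRADES = {RULE_OVERLENGTH, RULE_INVALID_NUMERIC}

#: hard cap on reported issues per (rule, table) pair; counts stay exact
ISSUE_CAP = 1000

_DATE_RE = re.compile(r"^\d{4}-\d{2}-\d{2}$")
_TIMESTAMP_RE = re.compile(
    r"^\d{4}-\d{2}-\d{2}([ T]\d{2}:\d{2}:\d{2}(\.\d+)?([+-]\d{2}:?\d{2}|Z)?)?$"
)
_INT_RE = re.compile(r"^[+-]?\d+$")


def is_missing(cell: str) -> bool:
    """Empty strings and the literal NULL (case-insensitive) denote missing."""
    s = cell.strip()
    return s == "" or s.upper() == "NULL"


def parses_as_date(cell: str) -> bool:
    """ISO 8601 calendar date (YYYY-MM-DD), the extraction convention."""
    if not _DATE_RE.match(cell.strip()):
        return False
    from datetime import date

    try:
        date.fromisoformat(cell.strip())
        return True
    except ValueError:
        return False


def parses_as_timestamp(cell: str) -> bool:
    """ISO 8601 date with optional time part."""
    s = cell.strip()
    if not _TIMESTAMP_RE.match(s):
        return False
    from datetime import date, datetime

    try:
        if len(s) == 10:
            date.fromisoformat(s)
        else:
            datetime.fromisoformat(s.replace("Z", "+00:00"))
        return True
    except ValueError:
        return False


def parses_as_numeric(cell: str, declared_type: str) -> bool:
    s = cell.strip()
    if declared_type == "integer":
        return bool(_INT_RE.match(s))
    try:
        Decimal(s)
        return True
    except InvalidOperation:
        return False


def _read_csv(path: str | Path) -> tuple[list[str], list[list[str]]]:
    with open(path, newline="", encoding="utf-8-sig") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file (no header row)") from None
        return [h.strip() for h in header], list(reader)


def validate_table(
    data_csv: str | Path, spec: TableSpec, mode: str = "strict"
) -> list[ValidationIssue]:
    """Validate one extracted CSV against its table spec.

    Emits per offending cell (line numbers are 1-based over data rows):

    * ERROR  — a date/timestamp cell cannot be parsed as a date;
    * ERROR  — data missing in a field the schema defines as required;
    * ERROR  — a numeric/decimal/integer cell is not a number;
    * ERROR  — data too long for a text/varchar field with a declared length
               (WARNING in loose mode, as is a numeric-parse failure);
    * WARNING, once per column — the schema itself lacks a length, precision
               or scale where its type calls for one;
    * WARNING — the file carries columns the spec does not declare.

    Type/length checks apply to non-missing cells only; missing cells are
    solely the required-field rule's concern.
    """
    if mode not in ("strict", "loose"):
        raise ValueError(f"mode must be 'strict' or 'loose', got {mode!r}")
    header, rows = _read_csv(data_csv)
    issues: list[ValidationIssue] = []
    cap_counts: dict[str, int] = {}

    def add(rule_id: str, message: str, column: str | None, line: int | None) -> None:
        severity = Severity.ERROR
        if rule_id in (RULE_MISSING_LENGTH, RULE_EXTRA_COLUMN):
            severity = Severity.WARNING
        elif mode == "loose" and rule_id in _LOOSE_DOWNGRADES:
            severity = Severity.WARNING
        cap_counts[rule_id] = cap_counts.get(rule_id, 0) + 1
        if cap_counts[rule_id] > ISSUE_CAP:
            return
        issues.append(
            ValidationIssue(
                rule_id=rule_id,
                severity=severity,
                message=message,
                table=spec.name,
                column=column,
                line_number=line,
            )
        )

    declared = set(spec.column_names)
    for col in header:
        if col not in declared:
            add(RULE_EXTRA_COLUMN, f"column not declared in the table spec", col, None)
    col_index = {c: header.index(c) for c in spec.column_names if c in header}
    for c in spec.column_names:
        if c not in header:
            add(RULE_MISSING_COLUMN, "declared column absent from the data file", c, None)

    # schema-completeness warnings, once per column
    for col in spec.columns:
        if col.type == "varchar" and col.length is None:
            add(RULE_MISSING_LENGTH, "varchar column has no declared length", col.name, None)
        elif col.type in ("numeric", "decimal") and col.precision is None:
            add(RULE_MISSING_LENGTH, "numeric column has no declared precision", col.name, None)

    for i, row in enumerate(rows, start=1):
        for col in spec.columns:
            idx = col_index.get(col.name)
            if idx is None or idx >= len(row):
                cell = ""
            else:
                cell = row[idx]
            if is_missing(cell):
                if col.required:
                    add(
                        RULE_MISSING_REQUIRED,
                        "data missing in a field defined as required by the schema",
                        col.name,
                        i,
                    )
                continue
            if col.type == "date" and not parses_as_date(cell):
                add(RULE_INVALID_DATE, "cell cannot be parsed as a date", col.name, i)
            elif col.type == "timestamp" and not parses_as_timestamp(cell):
                add(RULE_INVALID_DATE, "cell cannot be parsed as a timestamp", col.name, i)
            elif col.type in ("numeric", "decimal", "integer") and not parses_as_numeric(
                cell, col.type
            ):
                add(RULE_INVALID_NUMERIC, "cell is not a number", col.name, i)
            elif (
                col.type in ("text", "varchar")
                and col.length is not None
                and len(cell) > col.length
            ):
                add(
                    RULE_OVERLENGTH,
                    f"data too long for {col.type} field of length {col.length}",
                    col.name,
                    i,
                )
    return issues


def check_orphan_foreign_keys(
    child_csv: str | Path,
    parent_csv: str | Path,
    fk_columns: list[str] | tuple[str, ...],
    parent_columns: list[str] | tuple[str, ...],
    child_table: str = "",
    parent_table: str = "",
) -> list[ValidationIssue]:
    """Report child lines whose foreign-key value is absent from the parent.

    Missing foreign-key cells are not orphans (they are the required-field
    rule's concern); only populated references are checked.
    """
    if len(fk_columns) != len(parent_columns):
        raise ValueError("fk_columns and parent_columns must have equal length")
    child_header, child_rows = _read_csv(child_csv)
    parent_header, parent_rows = _read_csv(parent_csv)
    missing_child = [c for c in fk_columns if c not in child_header]
    missing_parent = [c for c in parent_columns if c not in parent_header]
    if missing_child or missing_parent:
        raise ValueError(
            f"foreign-key columns absent: child {missing_child}, parent {missing_parent}"
        )
    c_idx = [child_header.index(c) for c in fk_columns]
    p_idx = [parent_header.index(c) for c in parent_columns]
    parent_keys = {
        tuple(row[j] if j < len(row) else "" for j in p_idx) for row in parent_rows
    }
    issues: list[ValidationIssue] = []
    for i, row in enumerate(child_rows, start=1):
        key = tuple(row[j] if j < len(row) else "" for j in c_idx)
        if any(is_missing(v) for v in key):
            continue
        if key not in parent_keys:
            issues.append(
                ValidationIssue(
                    rule_id=RULE_ORPHAN_FK,
                    severity=Severity.ERROR,
                    message=(
                        "foreign-key value present in the child table but absent "
                        "from the parent key column"
                    ),
                    table=child_table or Path(child_csv).stem,
                    column=",".join(fk_columns),
                    line_number=i,
                )
            )
    return issues


def summarize_validation(issues: list[ValidationIssue]) -> ValidationReport:
    """Aggregate issues into a report; FAIL iff any ERROR is present."""
    return ValidationReport(issues=list(issues))
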