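"""The declarative ETL rule language: parse, validate and serialize CSV rule files.

A rule file is one RFC 4180 CSV per data source.  Each physical row is one
:class:`RuleRow` with 12 attributes; rows sharing a ``rule_order`` form one
:class:`Rule`, which compiles to exactly one INSERT...SELECT statement
against a single target table.  The row's ``map_type`` gives its role:

* ``PRIMARY`` — the main source table (always the first row of a rule);
  its ``source_value`` names the columns forming the target's primary key.
* ``JOIN`` / ``LEFT JOIN`` / ``RIGHT JOIN`` / ``FULL JOIN`` — an additional
  source table; ``source_value`` holds the join condition verbatim.
* ``WHERE`` — at most one per rule; ``source_value`` is the filter condition.
* ``VALUE`` — maps one target column; ``source_value`` is the SQL expression
  (native DBMS operators and functions are allowed) that populates it.
* ``CUSTOM`` — ``source_value`` is a complete verbatim SQL statement; a rule
  containing a CUSTOM row contains no other map types.

Rules are identified by the composite key (rule_order, rule_description,
data_source_id); ``rule_order`` is unique within one rule set but not
necessarily across sets, and ``data_source_id`` is rule-set-level metadata
supplied out of band rather than a 13th CSV column.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from .issues import Severity, ValidationIssue

#: canonical header, in canonical column order
RULE_ATTRIBUTES = (
    "rule_order",
    "rule_description",
    "target_database",
    "target_schema",
    "target_table",
    "target_column",
    "map_type",
    "map_order",
    "source_database",
    "source_schema",
    "source_table",
    "source_value",
)

MAP_TYPES = (
    "PRIMARY",
    "JOIN",
    "LEFT JOIN",
    "RIGHT JOIN",
    "FULL JOIN",
    "WHERE",
    "VALUE",
    "CUSTOM",
)

JOIN_MAP_TYPES = ("JOIN", "LEFT JOIN", "RIGHT JOIN", "FULL JOIN")

MAX_DESCRIPTION_LEN = 255


class RuleParseError(ValueError):
    """Raised when a rule CSV cannot be parsed into a RuleSet."""


def canonical_attribute(name: str) -> str:
    """Normalize a header cell to a canonical attribute name.

    Matching is case-insensitive and tolerant of spaces/hyphens, so headers
    authored in a spreadsheet ("Rule Order", "Map-Type") are accepted.
    """
    return re.sub(r"[\s\-]+", "_", name.strip().lower())


def normalize_map_type(raw: str) -> Optional[str]:
    """Map a raw map_type cell to its canonical token, or None if unknown."""
    tok = re.sub(r"\s+", " ", raw.strip().upper())
    return tok if tok in MAP_TYPES else None


@dataclass
class RuleRow:
    """One 12-attribute line of a rule."""

    rule_order: int
    map_type: str
    map_order: int
    rule_description: Optional[str] = None
    target_database: Optional[str] = None
    target_schema: Optional[str] = None
    target_table: Optional[str] = None
    target_column: Optional[str] = None
    source_database: Optional[str] = None
    source_schema: Optional[str] = None
    source_table: Optional[str] = None
    source_value: Optional[str] = None
    #: 1-based line number in the originating CSV (None for in-memory rows)
    source_line: Optional[int] = None

    def key_fields(self) -> tuple:
        """Structural identity, ignoring file provenance."""
        return (
            self.rule_order,
            self.rule_description,
            self.target_database,
            self.target_schema,
            self.target_table,
            self.target_column,
            self.map_type,
            self.map_order,
            self.source_database,
            self.source_schema,
            self.source_table,
            self.source_value,
        )


@dataclass
class Rule:
    """An ordered group of rows sharing one rule_order."""

    rows: list[RuleRow]
    data_source_id: str = ""

    @property
    def rule_order(self) -> int:
        return self.rows[0].rule_order

    @property
    def description(self) -> Optional[str]:
        return self.rows[0].rule_description

    @property
    def key(self) -> tuple[int, Optional[str], str]:
        """Composite rule identity: (rule_order, rule_description, data_source_id)."""
        return (self.rule_order, self.description, self.data_source_id)

    @property
    def target_table(self) -> Optional[str]:
        for r in self.rows:
            if r.target_table:
                return r.target_table
        return None

    @property
    def is_custom(self) -> bool:
        return any(r.map_type == "CUSTOM" for r in self.rows)

    def rows_of_type(self, *map_types: str) -> list[RuleRow]:
        return [r for r in self.rows if r.map_type in map_types]

    @property
    def primary_row(self) -> RuleRow:
        rows = self.rows_of_type("PRIMARY")
        if len(rows) != 1:
            raise ValueError(f"rule {self.rule_order} has {len(rows)} PRIMARY rows")
        return rows[0]

    @property
    def value_rows(self) -> list[RuleRow]:
        return self.rows_of_type("VALUE")

    @property
    def join_rows(self) -> list[RuleRow]:
        return self.rows_of_type(*JOIN_MAP_TYPES)

    @property
    def where_row(self) -> Optional[RuleRow]:
        rows = self.rows_of_type("WHERE")
        return rows[0] if rows else None

    def source_tables(self) -> list[str]:
        """Tables named on PRIMARY/JOIN rows, primary first, then join order."""
        out = []
        for r in self.rows_of_type("PRIMARY") + self.join_rows:
            if r.source_table and r.source_table not in out:
                out.append(r.source_table)
        return out


@dataclass
class RuleSet:
    """All rules loading one dataset, held in a single CSV file."""

    rules: list[Rule]
    data_source_id: str = ""
    source_file: Optional[Path] = None

    def __iter__(self) -> Iterable[Rule]:
        return iter(self.rules)

    def __len__(self) -> int:
        return len(self.rules)

    def rule(self, rule_order: int) -> Rule:
        for r in self.rules:
            if r.rule_order == rule_order:
                return r
        raise KeyError(f"no rule with rule_order {rule_order}")


def _cell(value: Optional[str]) -> Optional[str]:
    """Empty-string cells become absent; everything else (incl. 'NULL') verbatim."""
    if value is None:
        return None
    value = value.strip()
    return value if value != "" else None


def parse_rules(rule_csv: str | Path, data_source_id: str = "") -> RuleSet:
    """Parse one rule CSV into a :class:`RuleSet`.

    The header must name exactly the 12 rule attributes (any column order;
    case- and space-insensitive).  Rows are grouped by rule_order and sorted
    by map_order, so the physical row order of the file does not matter.

    Raises :class:`RuleParseError` naming the offending column for a missing,
    unknown or duplicated header column, and citing the file line number for
    a non-integer rule_order/map_order.
    """
    rule_csv = Path(rule_csv)
    with open(rule_csv, newline="", encoding="utf-8-sig") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise RuleParseError(f"{rule_csv}: empty file (no header row)") from None

        canon = [canonical_attribute(h) for h in header]
        unknown = [header[i] for i, c in enumerate(canon) if c not in RULE_ATTRIBUTES]
        if unknown:
            raise RuleParseError(
                f"{rule_csv}: unknown rule attribute column(s): {', '.join(repr(u) for u in unknown)}"
            )
        missing = [a for a in RULE_ATTRIBUTES if a not in canon]
        if missing:
            raise RuleParseError(
                f"{rule_csv}: missing rule attribute column(s): {', '.join(missing)}"
            )
        dupes = sorted({c for c in canon if canon.count(c) > 1})
        if dupes:
            raise RuleParseError(
                f"{rule_csv}: duplicated rule attribute column(s): {', '.join(dupes)}"
            )
        index = {c: i for i, c in enumerate(canon)}

        rows: list[RuleRow] = []
        for lineno, record in enumerate(reader, start=2):
            if not any(cell.strip() for cell in record):
                continue  # ignore fully blank lines
            if len(record) < len(header):
                record = record + [""] * (len(header) - len(record))

            def get(attr: str) -> Optional[str]:
                return _cell(record[index[attr]])

            raw_order = get("rule_order")
            raw_map_order = get("map_order")
            try:
                rule_order = int(raw_order) if raw_order is not None else None
            except ValueError:
                rule_order = None
            try:
                map_order = int(raw_map_order) if raw_map_order is not None else None
            except ValueError:
                map_order = None
            if rule_order is None:
                raise RuleParseError(
                    f"{rule_csv}: line {lineno}: rule_order is not an integer"
                )
            if map_order is None:
                raise RuleParseError(
                    f"{rule_csv}: line {lineno}: map_order is not an integer"
                )
            raw_map_type = get("map_type") or ""
            map_type = normalize_map_type(raw_map_type)
            rows.append(
                RuleRow(
                    rule_order=rule_order,
                    rule_description=get("rule_description"),
                    target_database=get("target_database"),
                    target_schema=get("target_schema"),
                    target_table=get("target_table"),
                    target_column=get("target_column"),
                    # keep the (normalized) raw token for unknown types so
                    # validate_ruleset can report them as issues, not crashes
                    map_type=map_type or re.sub(r"\s+", " ", raw_map_type.strip().upper()),
                    map_order=map_order,
                    source_database=get("source_database"),
                    source_schema=get("source_schema"),
                    source_table=get("source_table"),
                    source_value=get("source_value"),
                    source_line=lineno,
                )
            )

    grouped: dict[int, list[RuleRow]] = {}
    for row in rows:
        grouped.setdefault(row.rule_order, []).append(row)
    rules = [
        Rule(rows=sorted(grp, key=lambda r: r.map_order), data_source_id=data_source_id)
        for _, grp in sorted(grouped.items())
    ]
    return RuleSet(rules=rules, data_source_id=data_source_id, source_file=rule_csv)


def write_rules(rules: RuleSet, out: str | Path) -> Path:
    """Serialize a RuleSet to canonical CSV; inverse of :func:`parse_rules`."""
    out = Path(out)
    with open(out, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(RULE_ATTRIBUTES)
        for rule in rules:
            for r in rule.rows:
                writer.writerow(
                    "" if v is None else str(v)
                    for v in (
                        r.rule_order,
                        r.rule_description,
                        r.target_database,
                        r.target_schema,
                        r.target_table,
                        r.target_column,
                        r.map_type,
                        r.map_order,
                        r.source_database,
                        r.source_schema,
                        r.source_table,
                        r.source_value,
                    )
                )
    return out


def validate_ruleset(
    rules: RuleSet, excluded_columns: Optional[dict[str, set[str]]] = None
) -> list[ValidationIssue]:
    """Check every structural invariant of the rule language.

    Returns one issue per violation (issues are data, not exceptions); an
    empty list means every rule is well-formed.  ``excluded_columns`` maps a
    target table to the columns rules may not populate (the limited-data-set
    restriction list); a VALUE row targeting one yields an issue.
    """
    issues: list[ValidationIssue] = []

    def add(rule_id: str, msg: str, rule: Rule, column: Optional[str] = None) -> None:
        issues.append(
            ValidationIssue(
                rule_id=rule_id,
                severity=Severity.ERROR,
                message=msg,
                table=rule.target_table,
                column=column,
                line_number=None,
            )
        )

    seen_keys: dict[tuple, int] = {}
    seen_orders: dict[int, int] = {}
    for rule in rules:
        rid = f"rule {rule.rule_order}"

        if rule.key in seen_keys:
            add(
                "duplicate-rule-key",
                f"{rid}: composite key (rule_order, rule_description, data_source_id) "
                f"duplicates rule {seen_keys[rule.key]}",
                rule,
            )
        seen_keys[rule.key] = rule.rule_order
        if rule.rule_order in seen_orders:
            add(
                "duplicate-rule-order",
                f"{rid}: rule_order must be unique within a rule set",
                rule,
            )
        seen_orders[rule.rule_order] = rule.rule_order

        unknown = [r for r in rule.rows if r.map_type not in MAP_TYPES]
        for r in unknown:
            add(
                "unknown-map-type",
                f"{rid}, map_order {r.map_order}: map_type {r.map_type!r} is not one of "
                f"{', '.join(MAP_TYPES)}",
                rule,
            )

        descriptions = {r.rule_description for r in rule.rows}
        if len(descriptions) > 1:
            add(
                "mixed-rule-description",
                f"{rid}: all rows of a rule must share one rule_description",
                rule,
            )
        for r in rule.rows:
            if r.rule_description and len(r.rule_description) > MAX_DESCRIPTION_LEN:
                add(
                    "description-too-long",
                    f"{rid}: rule_description exceeds {MAX_DESCRIPTION_LEN} characters",
                    rule,
                )
                break

        map_orders = [r.map_order for r in rule.rows]
        if len(set(map_orders)) != len(map_orders):
            add(
                "duplicate-map-order",
                f"{rid}: map_order values must be unique within a rule",
                rule,
            )

        if rule.is_custom:
            non_custom = [r for r in rule.rows if r.map_type != "CUSTOM"]
            if non_custom:
                add(
                    "custom-mixed",
                    f"{rid}: a rule containing a CUSTOM row may contain no other map types",
                    rule,
                )
            for r in rule.rows_of_type("CUSTOM"):
                if not r.source_value:
                    add(
                        "custom-empty",
                        f"{rid}: CUSTOM row must carry the full SQL statement in source_value",
                        rule,
                    )
            continue

        primaries = rule.rows_of_type("PRIMARY")
        if len(primaries) != 1:
            add(
                "primary-cardinality",
                f"{rid}: a rule must have exactly one PRIMARY row (found {len(primaries)})",
                rule,
            )
        elif rule.rows[0].map_type != "PRIMARY":
            add(
                "primary-not-first",
                f"{rid}: the first row (lowest map_order) must be the PRIMARY row",
                rule,
            )
        wheres = rule.rows_of_type("WHERE")
        if len(wheres) > 1:
            add(
                "where-cardinality",
                f"{rid}: each rule can have at most one WHERE row (found {len(wheres)})",
                rule,
            )
        targets = {r.target_table for r in rule.rows if r.target_table}
        if len(targets) > 1:
            add(
                "single-target-table",
                f"{rid}: a rule can only populate one target table "
                f"(found {', '.join(sorted(targets))})",
                rule,
            )
        for r in rule.value_rows:
            if not r.target_column:
                add(
                    "value-missing-target-column",
                    f"{rid}, map_order {r.map_order}: VALUE rows must name a target_column",
                    rule,
                )
        if excluded_columns:
            tgt = rule.target_table
            banned = excluded_columns.get(tgt or "", set())
            for r in rule.value_rows:
                if r.target_column in banned:
                    add(
                        "excluded-column",
                        f"{rid}: target column is on the excluded-column list "
                        f"(limited data set restriction)",
                        rule,
                        column=r.target_column,
                    )
    return issues
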