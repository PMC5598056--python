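"""Compile mapping rules into executable INSERT...SELECT statements.

Each well-formed rule becomes exactly one SQL statement.  The engine works
in three steps mirrored in the emitted text:

1. the INSERT column list is taken from the rule's VALUE rows in map_order,
   and each column receives that row's ``source_value`` expression verbatim
   (native-dialect operators and functions pass through untouched);
2. every referenced source table is wrapped in a de-duplicating common table
   expression: exact duplicate records (identical in every column except the
   surrogate record identifier) collapse to one, and conflicting records
   (same identity key, different values) resolve to the row with the latest
   ETL timestamp;
3. the de-duplicated sources are joined (JOIN-family rows, ascending
   map_order, each ON condition verbatim) and filtered (the WHERE row, if
   present) before insertion.

CUSTOM rules bypass generation: their ``source_value`` is the statement.

Rule files are trusted input — expressions are embedded verbatim by design,
so the only injection hardening is the guarantee that a non-CUSTOM rule
yields exactly one statement (no stray semicolons).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Optional

from .rules import Rule, RuleSet
from .schema import TableSpec

#: suffix of the de-duplicating CTE wrapped around each source table
DEDUP_SUFFIX = "__dedup"

_IDENT_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")


class CompileError(ValueError):
    """A rule that cannot be turned into a statement."""


@dataclass
class CompileOptions:
    """Knobs for SQL generation.

    ``timestamp_column`` names the batch-load timestamp used to resolve
    conflicting records; when a source table's spec does not declare it the
    engine falls back to a deterministic lexicographic tie-break and records
    a warning on the statement.  ``source_specs`` supplies the table
    structures (identity keys, record-identifier columns) the de-duplication
    step needs; tables without a spec are read raw, with a warning.
    """

    dedup_enabled: bool = True
    timestamp_column: str = "etl_timestamp"
    select_distinct: bool = False
    dialect: str = "sqlite"  # "sqlite" (embedded) or "postgresql"
    source_specs: dict[str, TableSpec] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not _IDENT_RE.match(self.timestamp_column):
            raise ValueError(f"timestamp_column {self.timestamp_column!r} is not a valid identifier")
        if self.dialect not in ("sqlite", "postgresql"):
            raise ValueError(f"unsupported dialect {self.dialect!r}")


@dataclass
class GeneratedStatement:
    """One compiled statement plus provenance for the statement store."""

    sql_text: str
    rule_key: tuple[int, Optional[str], str]
    target_table: Optional[str]
    generated_at: str = ""
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.generated_at:
            self.generated_at = datetime.now(timezone.utc).isoformat(timespec="seconds")

    @property
    def rule_order(self) -> int:
        return self.rule_key[0]


@dataclass
class CompilationResult:
    """Fail-soft batch compilation: all compilable statements plus failures."""

    statements: list[GeneratedStatement] = field(default_factory=list)
    errors: list[tuple[tuple, str]] = field(default_factory=list)  # (rule_key, message)

    def __iter__(self):
        return iter(self.statements)

    def __len__(self) -> int:
        return len(self.statements)

    @property
    def ok(self) -> bool:
        return not self.errors


def strip_string_literals(expr: str) -> str:
    """Blank out single-quoted SQL string literals ('' escapes a quote)."""
    out = []
    i, n = 0, len(expr)
    in_str = False
    while i < n:
        ch = expr[i]
        if in_str:
            if ch == "'":
                if i + 1 < n and expr[i + 1] == "'":
                    i += 2
                    continue
                in_str = False
            i += 1
        else:
            if ch == "'":
                in_str = True
                out.append(" ")
                i += 1
            else:
                out.append(ch)
                i += 1
    return "".join(out)


def referenced_tables(expr: str) -> set[str]:
    """Table qualifiers (``tbl.`` prefixes) used in an expression."""
    return set(re.findall(r"\b([A-Za-z_][A-Za-z0-9_]*)\s*\.", strip_string_literals(expr)))


def _contains_statement_break(sql: str) -> bool:
    return ";" in strip_string_literals(sql)


def build_dedup_subquery(table: str, table_spec: TableSpec, opts: CompileOptions) -> str:
    """SQL subquery that replaces ``table`` with its de-duplicated view.

    Two nested window passes: the inner one collapses exact duplicates by
    partitioning on every column except the record identifier (keeping the
    smallest identifier); the outer one resolves conflicts by partitioning on
    the identity key and keeping the latest-timestamp row, with the full
    column list as a deterministic, input-order-independent tie-break.
    """
    cols = list(table_spec.column_names)
    ts = opts.timestamp_column
    has_ts = table_spec.has_column(ts)
    record_id = table_spec.record_id
    pk = [c for c in table_spec.primary_key if c != record_id]
    content = [c for c in cols if c != record_id]
    col_list = ", ".join(cols)

    # identifier columns declared integer order numerically, not as text
    rid_order = record_id
    if record_id is not None and table_spec.column(record_id).type == "integer":
        rid_order = f"CAST({record_id} AS INTEGER)"

    # pass 1: exact-duplicate collapse
    if record_id is not None:
        partition = ", ".join(content) if content else record_id
        inner = (
            f"SELECT {col_list}, ROW_NUMBER() OVER ("
            f"PARTITION BY {partition} ORDER BY {rid_order}) AS _dup_rn "
            f"FROM {table}"
        )
        stage1 = f"SELECT {col_list} FROM ({inner}) WHERE _dup_rn = 1"
    else:
        stage1 = f"SELECT DISTINCT {col_list} FROM {table}"

    if not pk:
        return f"({stage1})"

    # pass 2: conflict resolution within identity groups
    tie_break = [c for c in content if c not in pk and c != ts]
    order_terms: list[str] = []
    if has_ts:
        order_terms.append(f"{ts} DESC")
    order_terms.extend(tie_break)
    if record_id is not None:
        order_terms.append(rid_order)
    if not order_terms:
        order_terms = list(pk)
    outer = (
        f"SELECT {col_list}, ROW_NUMBER() OVER ("
        f"PARTITION BY {', '.join(pk)} ORDER BY {', '.join(order_terms)}) AS _cf_rn "
        f"FROM ({stage1})"
    )
    return f"(SELECT {col_list} FROM ({outer}) WHERE _cf_rn = 1)"


def _qualified_target(rule: Rule, opts: CompileOptions) -> str:
    """Target name: schema-qualified for postgresql, bare for the embedded engine."""
    first = rule.rows[0]
    table = rule.target_table
    if table is None:
        raise CompileError(f"rule {rule.rule_order}: no target table named")
    if opts.dialect == "postgresql" and first.target_schema:
        return f"{first.target_schema}.{table}"
    return table


def compile_custom(rule: Rule) -> GeneratedStatement:
    """Pass a CUSTOM rule's statement through verbatim, with provenance."""
    custom_rows = rule.rows_of_type("CUSTOM")
    if not custom_rows:
        raise CompileError(f"rule {rule.rule_order}: not a CUSTOM rule")
    sql = "\n".join((r.source_value or "").strip() for r in custom_rows).strip()
    if not sql:
        raise CompileError(f"rule {rule.rule_order}: CUSTOM rule has empty source_value")
    return GeneratedStatement(
        sql_text=sql, rule_key=rule.key, target_table=rule.target_table
    )


def compile_rule(rule: Rule, opts: Optional[CompileOptions] = None) -> GeneratedStatement:
    """Translate one validated rule into its INSERT...SELECT statement."""
    opts = opts or CompileOptions()
    if rule.is_custom:
        return compile_custom(rule)

    warnings: list[str] = []
    source_tables = rule.source_tables()
    if not source_tables:
        raise CompileError(f"rule {rule.rule_order}: PRIMARY row names no source table")

    # every table qualifier in any expression must come from PRIMARY/JOIN rows
    known = set(source_tables)
    for row in rule.value_rows + rule.join_rows + ([rule.where_row] if rule.where_row else []):
        expr = row.source_value
        if expr is None:
            continue
        unknown = referenced_tables(expr) - known
        if unknown:
            raise CompileError(
                f"rule {rule.rule_order}, map_order {row.map_order}: expression references "
                f"table(s) not introduced by PRIMARY/JOIN rows: {', '.join(sorted(unknown))}"
            )

    value_rows = rule.value_rows
    if not value_rows:
        raise CompileError(f"rule {rule.rule_order}: no VALUE rows to populate the target")
    for row in value_rows:
        if not row.target_column:
            raise CompileError(
                f"rule {rule.rule_order}, map_order {row.map_order}: VALUE row lacks target_column"
            )
        if row.source_value is None:
            raise CompileError(
                f"rule {rule.rule_order}, map_order {row.map_order}: VALUE row lacks source_value"
            )

    # de-duplicating CTEs, one per referenced source table
    ctes: list[str] = []
    table_ref: dict[str, str] = {}
    for table in source_tables:
        spec = opts.source_specs.get(table)
        if not opts.dedup_enabled:
            table_ref[table] = table
            continue
        if spec is None:
            warnings.append(
                f"no table spec for source table {table!r}; reading it raw (no de-duplication)"
            )
            table_ref[table] = table
            continue
        if not spec.has_column(opts.timestamp_column) and spec.primary_key:
            warnings.append(
                f"source table {table!r} has no {opts.timestamp_column!r} column; conflicting "
                f"records resolve by lexicographic order over all columns instead of latest timestamp"
            )
        cte_name = f"{table}{DEDUP_SUFFIX}"
        ctes.append(f"{cte_name} AS (\n  SELECT * FROM {build_dedup_subquery(table, spec, opts)}\n)")
        table_ref[table] = cte_name

    primary = rule.primary_row
    primary_table = primary.source_table
    from_clause = f"FROM {table_ref[primary_table]} AS {primary_table}"
    join_clauses: list[str] = []
    for row in rule.join_rows:
        if not row.source_table:
            raise CompileError(
                f"rule {rule.rule_order}, map_order {row.map_order}: {row.map_type} row "
                f"names no source table"
            )
        if not row.source_value:
            raise CompileError(
                f"rule {rule.rule_order}, map_order {row.map_order}: {row.map_type} row "
                f"has no join condition"
            )
        join_clauses.append(
            f"{row.map_type} {table_ref[row.source_table]} AS {row.source_table} "
            f"ON {row.source_value}"
        )

    insert_cols = ", ".join(r.target_column for r in value_rows)
    select_exprs = ",\n       ".join(r.source_value for r in value_rows)
    select_kw = "SELECT DISTINCT" if opts.select_distinct else "SELECT"

    parts: list[str] = []
    if ctes:
        parts.append("WITH " + ",\n".join(ctes))
    parts.append(f"INSERT INTO {_qualified_target(rule, opts)} ({insert_cols})")
    parts.append(f"{select_kw} {select_exprs}")
    parts.append(from_clause)
    parts.extend(join_clauses)
    if rule.where_row is not None:
        if not rule.where_row.source_value:
            raise CompileError(f"rule {rule.rule_order}: WHERE row has no condition")
        parts.append(f"WHERE {rule.where_row.source_value}")
    sql = "\n".join(parts)

    if _contains_statement_break(sql):
        raise CompileError(
            f"rule {rule.rule_order}: generated text contains a statement separator; "
            f"a non-CUSTOM rule must compile to exactly one statement"
        )
    return GeneratedStatement(
        sql_text=sql,
        rule_key=rule.key,
        target_table=rule.target_table,
        warnings=warnings,
    )


def compile_ruleset(rules: RuleSet, opts: Optional[CompileOptions] = None) -> CompilationResult:
    """Compile every rule, ordered by rule_order; fail-soft per rule."""
    opts = opts or CompileOptions()
    result = CompilationResult()
    for rule in sorted(rules, key=lambda r: r.rule_order):
        try:
            result.statements.append(compile_rule(rule, opts))
        except CompileError as exc:
            result.errors.append((rule.key, str(exc)))
    return result
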