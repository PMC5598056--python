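"""Stage CSV extracts into an embedded database and run compiled statements.

The staging database is SQLite (in-memory or file-backed), chosen so the
whole pipeline runs with no service dependency; generated SQL sticks to a
portable core (ANSI joins, ``||``, ``IN``, CTEs, window functions) so the
same statements target a PostgreSQL-compatible server unchanged.

Staging is an as-is load: every cell is stored verbatim as text, so
unloading a staged table reproduces the input CSV's data rows exactly.  A
batch-load timestamp column (``etl_timestamp`` by default) is injected when
the extract does not already carry one; conflict resolution between load
batches keys off it.

Generated statements are persisted in a statement store *inside the
database*, separate from the rules, before anything executes — the store
alone is sufficient to re-run the plan, and each stored statement can be
inspected or executed individually for debugging.  Execution is resumable:
a failed plan records a checkpoint (the first failed statement), and a
re-run from that checkpoint yields the same target state as an
uninterrupted run.
"""

from __future__ import annotations

import csv
import sqlite3
from dataclasses import dataclass, field, replace
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional

from .compiler import CompileOptions, GeneratedStatement, compile_rule
from .rules import Rule, RuleSet
from .schema import ColumnSpec, TableSpec

STATEMENT_STORE = "detl_statements"
BATCH_STORE = "detl_batches"


@dataclass
class StagedTable:
    name: str
    row_count: int
    load_batch_id: str
    etl_timestamp: str


@dataclass
class StatementStatus:
    rule_key: tuple
    status: str  # success | failed | skipped
    rows_inserted: int = 0
    error: Optional[str] = None
    sql_text: str = ""


@dataclass
class RunReport:
    """Per-statement outcome of one execution pass."""

    entries: list[StatementStatus] = field(default_factory=list)
    #: rule_key of the first failed statement, if any — resume from here
    checkpoint: Optional[tuple] = None

    @property
    def ok(self) -> bool:
        return all(e.status == "success" for e in self.entries)

    @property
    def n_failed(self) -> int:
        return sum(1 for e in self.entries if e.status == "failed")

    def as_dict(self) -> dict:
        return {
            "ok": self.ok,
            "checkpoint": list(self.checkpoint) if self.checkpoint else None,
            "statements": [
                {
                    "rule_key": list(e.rule_key),
                    "status": e.status,
                    "rows_inserted": e.rows_inserted,
                    "error": e.error,
                }
                for e in self.entries
            ],
        }


def _utcnow() -> str:
    return datetime.now(timezone.utc).isoformat(timespec="microseconds")


class StagingDatabase:
    """An embedded staging + target database for one ETL run."""

    def __init__(self, path: str | Path = ":memory:"):
        self.path = str(path)
        self.conn = sqlite3.connect(self.path)
        self.conn.execute(
            f"CREATE TABLE IF NOT EXISTS {STATEMENT_STORE} ("
            "rule_order INTEGER, rule_description TEXT, data_source_id TEXT, "
            "target_table TEXT, sql_text TEXT, generated_at TEXT)"
        )
        self.conn.execute(
            f"CREATE TABLE IF NOT EXISTS {BATCH_STORE} ("
            "batch_id TEXT, table_name TEXT, load_time TEXT, row_count INTEGER)"
        )
        #: effective specs of staged tables (timestamp column included)
        self.specs: dict[str, TableSpec] = {}

    def close(self) -> None:
        self.conn.close()

    def __enter__(self) -> "StagingDatabase":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    # -- staging ---------------------------------------------------------

    def create_table(self, spec: TableSpec, drop: bool = False) -> None:
        """Create a table with text affinity for every column (as-is load)."""
        if drop:
            self.conn.execute(f"DROP TABLE IF EXISTS {spec.name}")
        cols = ", ".join(f"{c.name} TEXT" for c in spec.columns)
        self.conn.execute(f"CREATE TABLE IF NOT EXISTS {spec.name} ({cols})")
        self.specs[spec.name] = spec

    def stage_csv(
        self,
        data_csv: str | Path,
        spec: TableSpec,
        batch_id: str = "batch-1",
        load_time: Optional[str] = None,
        timestamp_column: str = "etl_timestamp",
    ) -> StagedTable:
        """Load one extract as-is; inject the batch timestamp if absent.

        The table is created on first load and appended to on later batches
        (each batch carries its own load timestamp).  Returns the staged
        table handle; ``self.specs`` keeps the effective spec, with the
        injected timestamp column appended when the extract lacked it.
        """
        load_time = load_time or _utcnow()
        inject_ts = not spec.has_column(timestamp_column)
        eff_spec = spec
        if inject_ts:
            eff_spec = replace(
                spec, columns=spec.columns + [ColumnSpec(timestamp_column, "timestamp")]
            )
        if spec.name not in self.specs:
            self.create_table(eff_spec)
        with open(data_csv, newline="", encoding="utf-8-sig") as fh:
            reader = csv.reader(fh)
            header = [h.strip() for h in next(reader)]
            unknown = [h for h in header if not eff_spec.has_column(h)]
            if unknown:
                raise ValueError(
                    f"{data_csv}: columns not in spec for {spec.name!r}: {unknown}"
                )
            cols = list(header) + ([timestamp_column] if inject_ts else [])
            placeholders = ", ".join("?" for _ in cols)
            stmt = f"INSERT INTO {spec.name} ({', '.join(cols)}) VALUES ({placeholders})"
            n = 0
            for row in reader:
                row = list(row) + [""] * (len(header) - len(row))
                values = row[: len(header)] + ([load_time] if inject_ts else [])
                self.conn.execute(stmt, values)
                n += 1
        self.conn.execute(
            f"INSERT INTO {BATCH_STORE} VALUES (?, ?, ?, ?)",
            (batch_id, spec.name, load_time, n),
        )
        self.conn.commit()
        return StagedTable(
            name=spec.name, row_count=n, load_batch_id=batch_id, etl_timestamp=load_time
        )

    def unload_csv(
        self, table: str, out: str | Path, drop_columns: tuple[str, ...] = ("etl_timestamp",)
    ) -> Path:
        """Write a staged table back to CSV (minus injected columns)."""
        spec = self.specs[table]
        cols = [c.name for c in spec.columns if c.name not in drop_columns]
        rows = self.conn.execute(f"SELECT {', '.join(cols)} FROM {table}").fetchall()
        out = Path(out)
        with open(out, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(cols)
            writer.writerows(rows)
        return out

    def fetch_table(self, table: str, columns: Optional[list[str]] = None) -> list[tuple]:
        col_sql = ", ".join(columns) if columns else "*"
        return self.conn.execute(f"SELECT {col_sql} FROM {table}").fetchall()

    def table_columns(self, table: str) -> list[str]:
        return [r[1] for r in self.conn.execute(f"PRAGMA table_info({table})")]

    # -- statement store -------------------------------------------------

    def store_statements(self, stmts: list[GeneratedStatement]) -> None:
        for s in stmts:
            order, desc, dsid = s.rule_key
            self.conn.execute(
                f"INSERT INTO {STATEMENT_STORE} VALUES (?, ?, ?, ?, ?, ?)",
                (order, desc, dsid, s.target_table, s.sql_text, s.generated_at),
            )
        self.conn.commit()

    def load_statements(self) -> list[GeneratedStatement]:
        rows = self.conn.execute(
            f"SELECT rule_order, rule_description, data_source_id, target_table, "
            f"sql_text, generated_at FROM {STATEMENT_STORE} ORDER BY rule_order"
        ).fetchall()
        return [
            GeneratedStatement(
                sql_text=sql,
                rule_key=(order, desc, dsid),
                target_table=tgt,
                generated_at=gen,
            )
            for order, desc, dsid, tgt, sql, gen in rows
        ]

    # -- execution -------------------------------------------------------

    def execute_statements(
        self,
        stmts: list[GeneratedStatement],
        resume_from: Optional[tuple] = None,
        reset_targets: bool = False,
        store: bool = True,
    ) -> RunReport:
        """Run statements in rule order with per-statement fault isolation.

        On the first failure the remaining statements are marked ``skipped``
        and the failed statement's rule key becomes the resume checkpoint.
        With ``resume_from`` set, statements before that key are marked
        ``skipped`` (already applied) and execution picks up there.
        ``reset_targets`` clears the plan's target tables first (full
        refresh); it is ignored on resumed runs so partial progress stands.
        """
        stmts = sorted(stmts, key=lambda s: s.rule_order)
        if store:
            self.store_statements(stmts)
        if reset_targets and resume_from is None:
            for table in {s.target_table for s in stmts if s.target_table}:
                try:
                    self.conn.execute(f"DELETE FROM {table}")
                except sqlite3.Error:
                    pass
            self.conn.commit()
        report = RunReport()
        resuming = resume_from is not None
        failed = False
        for s in stmts:
            if resuming:
                if s.rule_key == tuple(resume_from):
                    resuming = False
                else:
                    report.entries.append(
                        StatementStatus(s.rule_key, "skipped", sql_text=s.sql_text)
                    )
                    continue
            if failed:
                report.entries.append(
                    StatementStatus(s.rule_key, "skipped", sql_text=s.sql_text)
                )
                continue
            try:
                before = self.conn.total_changes
                self.conn.execute(s.sql_text)
                self.conn.commit()
                report.entries.append(
                    StatementStatus(
                        s.rule_key,
                        "success",
                        rows_inserted=self.conn.total_changes - before,
                        sql_text=s.sql_text,
                    )
                )
            except sqlite3.Error as exc:
                self.conn.rollback()
                failed = True
                report.checkpoint = s.rule_key
                report.entries.append(
                    StatementStatus(s.rule_key, "failed", error=str(exc), sql_text=s.sql_text)
                )
        return report

    def run_single_rule(
        self,
        rules: RuleSet,
        rule_order: int,
        opts: Optional[CompileOptions] = None,
    ) -> RunReport:
        """Compile and execute one rule in isolation (debugging aid).

        The generated SQL text is available on the report entry for
        inspection, and is persisted to the statement store like any other
        compiled statement.
        """
        rule = rules.rule(rule_order)  # KeyError for an unknown rule_order
        opts = opts or CompileOptions(source_specs=self.specs)
        stmt = compile_rule(rule, opts)
        return self.execute_statements([stmt])


def compile_options_for(db: StagingDatabase, **kwargs) -> CompileOptions:
    """CompileOptions wired to the database's effective staged-table specs."""
    return CompileOptions(source_specs=dict(db.specs), **kwargs)
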