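"""Declarative table specifications for source extracts and target tables.

A :class:`TableSpec` records what the engine must know about a table that a
rule file cannot tell it: column types and lengths, required flags, the
identity key used for conflict grouping, the surrogate record-identifier
column excluded from duplicate comparison, and foreign keys.  Specs are
stored in a single YAML file per schema so extracts and their description
travel together.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

#: declared column types understood by the validator
COLUMN_TYPES = {"date", "timestamp", "numeric", "decimal", "integer", "text", "varchar"}


@dataclass(frozen=True)
class ColumnSpec:
    name: str
    type: str = "text"
    length: Optional[int] = None      # varchar/text max length
    precision: Optional[int] = None   # numeric/decimal
    scale: Optional[int] = None
    required: bool = False

    def __post_init__(self) -> None:
        if self.type not in COLUMN_TYPES:
            raise ValueError(f"unknown column type {self.type!r} for column {self.name!r}")


@dataclass(frozen=True)
class ForeignKey:
    columns: tuple[str, ...]
    parent_table: str
    parent_columns: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.columns) != len(self.parent_columns):
            raise ValueError("foreign key column lists must have equal length")


@dataclass
class TableSpec:
    """Structure of one source or target table.

    ``primary_key`` is the record *identity* (conflict groups share it);
    ``record_id`` is an optional surrogate identifier column that is ignored
    when deciding whether two rows are exact duplicates of each other.
    """

    name: str
    columns: list[ColumnSpec]
    primary_key: list[str] = field(default_factory=list)
    record_id: Optional[str] = None
    foreign_keys: list[ForeignKey] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [c.name for c in self.columns]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate column names in table {self.name!r}")
        missing = [c for c in self.primary_key if c not in names]
        if missing:
            raise ValueError(f"primary key columns {missing} not declared in {self.name!r}")
        if self.record_id is not None and self.record_id not in names:
            raise ValueError(f"record_id column {self.record_id!r} not declared in {self.name!r}")
        for fk in self.foreign_keys:
            bad = [c for c in fk.columns if c not in names]
            if bad:
                raise ValueError(f"foreign key columns {bad} not declared in {self.name!r}")

    @property
    def column_names(self) -> list[str]:
        return [c.name for c in self.columns]

    def column(self, name: str) -> ColumnSpec:
        for c in self.columns:
            if c.name == name:
                return c
        raise KeyError(f"no column {name!r} in table {self.name!r}")

    def has_column(self, name: str) -> bool:
        return any(c.name == name for c in self.columns)


def _column_to_dict(c: ColumnSpec) -> dict:
    d: dict = {"name": c.name, "type": c.type}
    if c.length is not None:
        d["length"] = c.length
    if c.precision is not None:
        d["precision"] = c.precision
    if c.scale is not None:
        d["scale"] = c.scale
    if c.required:
        d["required"] = True
    return d


def _table_to_dict(t: TableSpec) -> dict:
    d: dict = {"name": t.name, "columns": [_column_to_dict(c) for c in t.columns]}
    if t.primary_key:
        d["primary_key"] = list(t.primary_key)
    if t.record_id:
        d["record_id"] = t.record_id
    if t.foreign_keys:
        d["foreign_keys"] = [
            {
                "columns": list(fk.columns),
                "parent_table": fk.parent_table,
                "parent_columns": list(fk.parent_columns),
            }
            for fk in t.foreign_keys
        ]
    return d


def _table_from_dict(d: dict) -> TableSpec:
    cols = [
        ColumnSpec(
            name=c["name"],
            type=c.get("type", "text"),
            length=c.get("length"),
            precision=c.get("precision"),
            scale=c.get("scale"),
            required=bool(c.get("required", False)),
        )
        for c in d["columns"]
    ]
    fks = [
        ForeignKey(
            columns=tuple(fk["columns"]),
            parent_table=fk["parent_table"],
            parent_columns=tuple(fk["parent_columns"]),
        )
        for fk in d.get("foreign_keys", [])
    ]
    return TableSpec(
        name=d["name"],
        columns=cols,
        primary_key=list(d.get("primary_key", [])),
        record_id=d.get("record_id"),
        foreign_keys=fks,
    )


def save_schema(tables: list[TableSpec], path: str | Path) -> Path:
    """Write a schema-spec YAML file (``tables:`` list of table dicts)."""
    path = Path(path)
    doc = {"tables": [_table_to_dict(t) for t in tables]}
    path.write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")
    return path


def load_schema(path: str | Path) -> dict[str, TableSpec]:
    """Load a schema-spec YAML file; returns table specs keyed by name."""
    doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if not isinstance(doc, dict) or "tables" not in doc:
        raise ValueError(f"schema spec {path} must contain a top-level 'tables' list")
    tables = [_table_from_dict(d) for d in doc["tables"]]
    out = {t.name: t for t in tables}
    # every FK parent must itself be declared
    for t in tables:
        for fk in t.foreign_keys:
            if fk.parent_table not in out:
                raise ValueError(
                    f"table {t.name!r} references undeclared parent {fk.parent_table!r}"
                )
    return out
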