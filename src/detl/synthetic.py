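"""Reproducible toy claims + clinical extracts and a mini-OMOP target.

The generator emulates the shape of the extracts a claims/EHR data partner
would deliver for harmonization: a ``medical_claims`` table with a billing
provider reference, a ``provider`` roster, a ``demographic`` table whose
race field is coded in HL7 race categories, and a ``source_to_concept_map``
translating those codes to the OMOP/SNOMED race concepts.  Values are small
categorical draws from fixed vocabularies — structure, not clinical realism,
is what downstream modules need.

Data problems are *injected at declared rates and recorded in an injection
ledger* (table, line number, column, rule id), giving every validator and
de-duplication test an exact ground truth: full-row duplicates under a new
record identifier, conflicting records with a later ETL timestamp, orphan
provider references, unparseable dates, non-numeric amounts, over-length
text, and missing required fields.  Identity-group injections (duplicates,
conflicts) and cell-level injections never touch the same rows, so each
anomaly is detected by exactly one rule.

Output is byte-identical for identical (seed, config).
"""

from __future__ import annotations

import json
import random
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .rules import Rule, RuleRow, RuleSet
from .schema import ColumnSpec, ForeignKey, TableSpec, save_schema
from .validation import (
    RULE_INVALID_DATE,
    RULE_INVALID_NUMERIC,
    RULE_MISSING_REQUIRED,
    RULE_ORPHAN_FK,
    RULE_OVERLENGTH,
)

# fixed vocabularies ----------------------------------------------------

_CITIES = ["Aurora", "Denver", "Boulder", "Pueblo", "Golden"]
_STATES = ["CO", "NM", "WY"]
_ZIPS = ["80045", "80202", "80301", "81001", "80401"]
_STREETS = ["Main St", "Colfax Ave", "17th Ave", "Broadway", "Speer Blvd"]
_POS_CODES = ["11", "21", "22", "23", "31"]
_ORG_TYPES = ["1", "2", "3"]
_GENDERS = ["F", "M"]

#: HL7 (CDC) race category codes and their OMOP/SNOMED-mapped race concepts
HL7_RACE_CONCEPTS = {
    "1002-5": (8657, "American Indian or Alaska Native"),
    "2028-9": (8515, "Asian"),
    "2054-5": (8516, "Black or African American"),
    "2076-8": (8557, "Native Hawaiian or Other Pacific Islander"),
    "2106-3": (8527, "White"),
}

_BASE_TS = "2024-01-15T10:00:00"
_CONFLICT_TS = "2024-02-15T10:00:00"


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic extract set.

    Rates are per-row (duplicate/conflict/orphan) or per-cell (the error
    classes) Bernoulli probabilities.
    """

    seed: int = 0
    n_claims: int = 200
    n_providers: int = 50
    n_persons: int = 100
    dup_rate: float = 0.1
    conflict_rate: float = 0.05
    orphan_fk_rate: float = 0.05
    invalid_date_rate: float = 0.02
    invalid_numeric_rate: float = 0.02
    overlength_rate: float = 0.02
    missing_required_rate: float = 0.02

    def __post_init__(self) -> None:
        for name in (
            "dup_rate",
            "conflict_rate",
            "orphan_fk_rate",
            "invalid_date_rate",
            "invalid_numeric_rate",
            "overlength_rate",
            "missing_required_rate",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_claims", "n_providers", "n_persons"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def clean(cls, **kwargs) -> "GeneratorConfig":
        """A config with every injection rate zero."""
        zeros = dict(
            dup_rate=0.0,
            conflict_rate=0.0,
            orphan_fk_rate=0.0,
            invalid_date_rate=0.0,
            invalid_numeric_rate=0.0,
            overlength_rate=0.0,
            missing_required_rate=0.0,
        )
        zeros.update(kwargs)
        return cls(**zeros)


@dataclass
class InjectionLedger:
    """Ground truth of every injected anomaly.

    ``errors`` maps a validation-rule id to (table, line_number, column)
    entries; ``duplicates``/``conflicts`` record identity groups by record
    identifier so de-duplication output can be checked row for row.
    """

    errors: dict[str, list[dict]] = field(default_factory=dict)
    duplicates: list[dict] = field(default_factory=list)
    conflicts: list[dict] = field(default_factory=list)

    def add_error(self, rule_id: str, table: str, line_number: int, column: str) -> None:
        self.errors.setdefault(rule_id, []).append(
            {"table": table, "line_number": line_number, "column": column}
        )

    def expected_issues(self, table: str, rule_ids: set[str] | None = None) -> set[tuple]:
        """(rule_id, line_number, column) triples expected for one table."""
        out = set()
        for rid, entries in self.errors.items():
            if rule_ids is not None and rid not in rule_ids:
                continue
            for e in entries:
                if e["table"] == table:
                    out.add((rid, e["line_number"], e["column"]))
        return out

    def removed_record_ids(self, table: str) -> set[str]:
        """Record identifiers that de-duplication must remove for a table."""
        out: set[str] = set()
        for d in self.duplicates:
            if d["table"] == table:
                out.add(d["duplicate_record_id"])
        for c in self.conflicts:
            if c["table"] == table:
                out.update(c["losing_record_ids"])
        return out

    def as_dict(self) -> dict:
        return asdict(self)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.as_dict(), indent=2, sort_keys=True), encoding="utf-8")
        return path


# schemas ---------------------------------------------------------------


def source_schema() -> list[TableSpec]:
    """Specs for the four source extracts (claims, roster, clinical, map)."""
    provider = TableSpec(
        name="provider",
        columns=[
            ColumnSpec("provider_row_id", "integer", required=True),
            ColumnSpec("provider_id", "varchar", length=10, required=True),
            ColumnSpec("provider_organization_type", "varchar", length=2),
            ColumnSpec("provider_address_first_line", "varchar", length=40),
            ColumnSpec("provider_street", "varchar", length=40),
            ColumnSpec("provider_city", "varchar", length=30),
            ColumnSpec("provider_state", "varchar", length=2),
            ColumnSpec("provider_zip", "varchar", length=9),
            ColumnSpec("etl_timestamp", "timestamp", required=True),
        ],
        primary_key=["provider_id"],
        record_id="provider_row_id",
    )
    medical_claims = TableSpec(
        name="medical_claims",
        columns=[
            ColumnSpec("claim_line_id", "integer", required=True),
            ColumnSpec("claim_id", "varchar", length=10, required=True),
            ColumnSpec("member_id", "varchar", length=12),
            ColumnSpec("billing_provider_id", "varchar", length=10, required=True),
            ColumnSpec("place_of_service_code", "varchar", length=2),
            ColumnSpec("service_date", "date", required=True),
            ColumnSpec("claim_amount", "numeric", precision=10, scale=2),
            ColumnSpec("etl_timestamp", "timestamp", required=True),
        ],
        primary_key=["claim_id"],
        record_id="claim_line_id",
        foreign_keys=[ForeignKey(("billing_provider_id",), "provider", ("provider_id",))],
    )
    demographic = TableSpec(
        name="demographic",
        columns=[
            ColumnSpec("demographic_row_id", "integer", required=True),
            ColumnSpec("patient_id", "varchar", length=10, required=True),
            ColumnSpec("birth_date", "date"),
            ColumnSpec("gender", "varchar", length=1, required=True),
            ColumnSpec("race_hl7", "varchar", length=7),
            ColumnSpec("state", "varchar", length=2),
            ColumnSpec("zip3", "varchar", length=3),
            ColumnSpec("etl_timestamp", "timestamp", required=True),
        ],
        primary_key=["patient_id"],
        record_id="demographic_row_id",
    )
    concept_map = TableSpec(
        name="source_to_concept_map",
        columns=[
            ColumnSpec("source_code", "varchar", length=10, required=True),
            ColumnSpec("source_vocabulary_id", "varchar", length=20, required=True),
            ColumnSpec("source_code_description", "varchar", length=60),
            ColumnSpec("target_concept_id", "integer", required=True),
            ColumnSpec("target_vocabulary_id", "varchar", length=20, required=True),
        ],
        primary_key=["source_code", "source_vocabulary_id"],
    )
    return [provider, medical_claims, demographic, concept_map]


#: direct identifiers barred from the limited data set, per target table
DEFAULT_EXCLUDED_COLUMNS: dict[str, set[str]] = {
    "person": {"person_name", "ssn", "phone_number", "street_address"},
    "care_site": set(),
}


def mini_target_schema() -> list[TableSpec]:
    """A two-table OMOP-v4-style target: care_site and person.

    The limited-data-set restriction keeps dates, state and 3-digit ZIP but
    no direct identifiers; :data:`DEFAULT_EXCLUDED_COLUMNS` lists columns a
    rule may never populate.
    """
    care_site = TableSpec(
        name="care_site",
        columns=[
            ColumnSpec("care_site_id", "integer"),
            ColumnSpec("care_site_source_value", "varchar", length=60),
            ColumnSpec("organization_source_value", "varchar", length=50),
            ColumnSpec("place_of_service_source_value", "varchar", length=50),
            ColumnSpec("care_site_address_1", "varchar", length=50),
            ColumnSpec("care_site_address_2", "varchar", length=50),
            ColumnSpec("care_site_city", "varchar", length=50),
            ColumnSpec("care_site_state", "varchar", length=2),
            ColumnSpec("care_site_zip", "varchar", length=9),
            ColumnSpec("care_site_county", "varchar", length=20),
        ],
        primary_key=["care_site_id"],
    )
    person = TableSpec(
        name="person",
        columns=[
            ColumnSpec("person_id", "integer"),
            ColumnSpec("person_source_value", "varchar", length=50),
            ColumnSpec("gender_source_value", "varchar", length=50),
            ColumnSpec("year_of_birth", "integer"),
            ColumnSpec("race_concept_id", "integer"),
            ColumnSpec("race_source_value", "varchar", length=50),
            ColumnSpec("location_state", "varchar", length=2),
            ColumnSpec("location_zip3", "varchar", length=3),
        ],
        primary_key=["person_id"],
    )
    return [care_site, person]


# generation ------------------------------------------------------------


def _write_csv(path: Path, header: list[str], rows: list[list[str]]) -> None:
    import csv

    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        writer.writerows(rows)


def _inject_groups(
    rng: random.Random,
    rows: list[list[str]],
    spec: TableSpec,
    cfg: GeneratorConfig,
    ledger: InjectionLedger,
    conflict_column: str,
    conflict_values: list[str],
    next_record_id: int,
) -> tuple[list[list[str]], set[int], int]:
    """Append duplicate and conflicting copies of base rows.

    Returns (rows, protected-row-indices, next free record id).  Protected
    rows (any member of a duplicate/conflict group) are off limits for
    cell-level error injection so anomaly classes stay disjoint.
    """
    cols = spec.column_names
    rid_idx = cols.index(spec.record_id)
    ts_idx = cols.index("etl_timestamp")
    cf_idx = cols.index(conflict_column)
    pk_idx = [cols.index(c) for c in spec.primary_key]

    out: list[list[str]] = []
    protected: set[int] = set()
    for base in rows:
        pos = len(out)
        out.append(base)
        grouped = False
        if rng.random() < cfg.dup_rate:
            dup = list(base)
            dup[rid_idx] = str(next_record_id)
            next_record_id += 1
            out.append(dup)
            ledger.duplicates.append(
                {
                    "table": spec.name,
                    "pk": [base[i] for i in pk_idx],
                    "original_record_id": base[rid_idx],
                    "duplicate_record_id": dup[rid_idx],
                }
            )
            grouped = True
        if rng.random() < cfg.conflict_rate:
            cf = list(base)
            cf[rid_idx] = str(next_record_id)
            next_record_id += 1
            current = cf[cf_idx]
            choices = [v for v in conflict_values if v != current] or conflict_values
            cf[cf_idx] = rng.choice(choices)
            cf[ts_idx] = _CONFLICT_TS
            losing = [r[rid_idx] for r in out[pos:] if r[rid_idx] != cf[rid_idx]]
            out.append(cf)
            ledger.conflicts.append(
                {
                    "table": spec.name,
                    "pk": [base[i] for i in pk_idx],
                    "column": conflict_column,
                    "losing_record_ids": losing,
                    "winning_record_id": cf[rid_idx],
                }
            )
            grouped = True
        if grouped:
            protected.update(range(pos, len(out)))
    return out, protected, next_record_id


def _inject_cell_errors(
    rng: random.Random,
    rows: list[list[str]],
    spec: TableSpec,
    cfg: GeneratorConfig,
    ledger: InjectionLedger,
    protected: set[int],
    targets: dict[str, list[str]],
) -> None:
    """Mutate cells in place per error class; at most one class per cell.

    ``targets`` maps a validation-rule id to the columns eligible for that
    class in this table.
    """
    cols = spec.column_names
    rates = {
        RULE_INVALID_DATE: cfg.invalid_date_rate,
        RULE_INVALID_NUMERIC: cfg.invalid_numeric_rate,
        RULE_OVERLENGTH: cfg.overlength_rate,
        RULE_MISSING_REQUIRED: cfg.missing_required_rate,
        RULE_ORPHAN_FK: cfg.orphan_fk_rate,
    }
    for line, row in enumerate(rows, start=1):
        if (line - 1) in protected:
            continue
        touched: set[str] = set()
        for rule_id in (
            RULE_INVALID_DATE,
            RULE_INVALID_NUMERIC,
            RULE_OVERLENGTH,
            RULE_MISSING_REQUIRED,
            RULE_ORPHAN_FK,
        ):
            for col in targets.get(rule_id, []):
                if col in touched:
                    continue
                if rng.random() >= rates[rule_id]:
                    continue
                idx = cols.index(col)
                if rule_id == RULE_INVALID_DATE:
                    row[idx] = "2024-13-45"
                elif rule_id == RULE_INVALID_NUMERIC:
                    row[idx] = "12.34.56"
                elif rule_id == RULE_OVERLENGTH:
                    length = spec.column(col).length or 10
                    row[idx] = "X" * (length + 5)
                elif rule_id == RULE_MISSING_REQUIRED:
                    row[idx] = ""
                elif rule_id == RULE_ORPHAN_FK:
                    row[idx] = f"PX{rng.randrange(1000, 9999)}"
                touched.add(col)
                ledger.add_error(rule_id, spec.name, line, col)


def generate_extracts(
    cfg: GeneratorConfig, out_dir: str | Path
) -> tuple[dict[str, Path], InjectionLedger]:
    """Emit the four extracts, both schema specs and the injection ledger.

    Returns a mapping of artifact names to paths plus the ledger.  Identical
    (seed, config) yield byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = random.Random(cfg.seed)
    ledger = InjectionLedger()
    specs = {s.name: s for s in source_schema()}

    # provider roster -----------------------------------------------------
    provider_rows = []
    provider_ids = []
    for i in range(1, cfg.n_providers + 1):
        pid = f"P{i:04d}"
        provider_ids.append(pid)
        provider_rows.append(
            [
                str(i),
                pid,
                rng.choice(_ORG_TYPES),
                f"{100 + rng.randrange(900)} {rng.choice(_STREETS)}",
                f"Suite {rng.randrange(1, 40)}",
                rng.choice(_CITIES),
                rng.choice(_STATES),
                rng.choice(_ZIPS),
                _BASE_TS,
            ]
        )
    provider_rows, prot, next_rid = _inject_groups(
        rng, provider_rows, specs["provider"], cfg, ledger,
        conflict_column="provider_city", conflict_values=_CITIES,
        next_record_id=cfg.n_providers + 1,
    )
    _inject_cell_errors(
        rng, provider_rows, specs["provider"], cfg, ledger, prot,
        targets={RULE_OVERLENGTH: ["provider_city"]},
    )

    # medical claims ------------------------------------------------------
    claim_rows = []
    for i in range(1, cfg.n_claims + 1):
        claim_rows.append(
            [
                str(i),
                f"C{i:05d}",
                f"M{rng.randrange(100000, 999999)}",
                rng.choice(provider_ids) if provider_ids else "P0000",
                rng.choice(_POS_CODES),
                f"2023-{rng.randrange(1, 13):02d}-{rng.randrange(1, 29):02d}",
                f"{rng.randrange(10, 5000)}.{rng.randrange(100):02d}",
                _BASE_TS,
            ]
        )
    claim_rows, prot, _ = _inject_groups(
        rng, claim_rows, specs["medical_claims"], cfg, ledger,
        conflict_column="claim_amount",
        conflict_values=[f"{v}.00" for v in (111, 222, 333, 444)],
        next_record_id=cfg.n_claims + 1,
    )
    _inject_cell_errors(
        rng, claim_rows, specs["medical_claims"], cfg, ledger, prot,
        targets={
            RULE_INVALID_DATE: ["service_date"],
            RULE_INVALID_NUMERIC: ["claim_amount"],
            RULE_OVERLENGTH: ["member_id"],
            RULE_MISSING_REQUIRED: ["service_date"],
            RULE_ORPHAN_FK: ["billing_provider_id"],
        },
    )

    # demographics --------------------------------------------------------
    demo_rows = []
    race_codes = list(HL7_RACE_CONCEPTS)
    for i in range(1, cfg.n_persons + 1):
        demo_rows.append(
            [
                str(i),
                f"PT{i:04d}",
                f"{rng.randrange(1930, 2010)}-{rng.randrange(1, 13):02d}-{rng.randrange(1, 29):02d}",
                rng.choice(_GENDERS),
                rng.choice(race_codes),
                rng.choice(_STATES),
                rng.choice(_ZIPS)[:3],
                _BASE_TS,
            ]
        )
    demo_rows, prot, _ = _inject_groups(
        rng, demo_rows, specs["demographic"], cfg, ledger,
        conflict_column="state", conflict_values=_STATES,
        next_record_id=cfg.n_persons + 1,
    )
    _inject_cell_errors(
        rng, demo_rows, specs["demographic"], cfg, ledger, prot,
        targets={
            RULE_INVALID_DATE: ["birth_date"],
            RULE_MISSING_REQUIRED: ["gender"],
        },
    )

    # terminology map (always clean) --------------------------------------
    map_rows = [
        [code, "HL7 Race", desc, str(concept_id), "SNOMED"]
        for code, (concept_id, desc) in HL7_RACE_CONCEPTS.items()
    ]

    files: dict[str, Path] = {}
    for name, rows in (
        ("provider", provider_rows),
        ("medical_claims", claim_rows),
        ("demographic", demo_rows),
        ("source_to_concept_map", map_rows),
    ):
        path = out_dir / f"{name}.csv"
        _write_csv(path, specs[name].column_names, rows)
        files[name] = path

    files["source_schema"] = save_schema(list(specs.values()), out_dir / "source_schema.yaml")
    files["target_schema"] = save_schema(mini_target_schema(), out_dir / "target_schema.yaml")
    files["ledger"] = ledger.save(out_dir / "injection_ledger.json")
    return files, ledger


# packaged reference rules ---------------------------------------------


def reference_rules(data_source_id: str = "claims-demo") -> RuleSet:
    """The packaged rule set for the synthetic extracts.

    Rule 1 loads ``care_site`` from the claims extract joined to the
    provider roster, filtered to organization types '1' and '2', with a
    composite source value as the care-site identifier.  Rule 2 loads
    ``person`` from the demographic extract, translating HL7 race codes to
    SNOMED-mapped concept ids through the source-to-concept map.
    """

    def row(order, desc, tgt_table, tgt_col, mtype, morder, src_table, src_value):
        return RuleRow(
            rule_order=order,
            rule_description=desc,
            target_table=tgt_table,
            target_column=tgt_col,
            map_type=mtype,
            map_order=morder,
            source_table=src_table,
            source_value=src_value,
        )

    d1 = "Medical_claims to Care_site"
    rule1 = Rule(
        data_source_id=data_source_id,
        rows=[
            row(1, d1, "care_site", None, "PRIMARY", 1, "medical_claims",
                "medical_claims.billing_provider_id, medical_claims.place_of_service_code, "
                "provider.provider_organization_type"),
            row(1, d1, "care_site", None, "JOIN", 2, "provider",
                "medical_claims.billing_provider_id = provider.provider_id"),
            row(1, d1, "care_site", None, "WHERE", 3, None,
                "provider.provider_organization_type in ('1', '2')"),
            row(1, d1, "care_site", "care_site_source_value", "VALUE", 4, None,
                "medical_claims.billing_provider_id || '-' || "
                "medical_claims.place_of_service_code || '-' || "
                "provider.provider_organization_type"),
            row(1, d1, "care_site", "organization_source_value", "VALUE", 5, None, "NULL"),
            row(1, d1, "care_site", "place_of_service_source_value", "VALUE", 6, None,
                "medical_claims.place_of_service_code"),
            row(1, d1, "care_site", "care_site_address_1", "VALUE", 7, None,
                "provider.provider_address_first_line"),
            row(1, d1, "care_site", "care_site_address_2", "VALUE", 8, None,
                "provider.provider_street"),
            row(1, d1, "care_site", "care_site_city", "VALUE", 9, None,
                "provider.provider_city"),
            row(1, d1, "care_site", "care_site_state", "VALUE", 10, None,
                "provider.provider_state"),
            row(1, d1, "care_site", "care_site_zip", "VALUE", 11, None,
                "provider.provider_zip"),
            row(1, d1, "care_site", "care_site_county", "VALUE", 12, None, "NULL"),
        ],
    )

    d2 = "Demographic to Person"
    rule2 = Rule(
        data_source_id=data_source_id,
        rows=[
            row(2, d2, "person", None, "PRIMARY", 1, "demographic", "demographic.patient_id"),
            row(2, d2, "person", None, "JOIN", 2, "source_to_concept_map",
                "demographic.race_hl7 = source_to_concept_map.source_code"),
            row(2, d2, "person", None, "WHERE", 3, None,
                "source_to_concept_map.source_vocabulary_id = 'HL7 Race'"),
            row(2, d2, "person", "person_source_value", "VALUE", 4, None,
                "demographic.patient_id"),
            row(2, d2, "person", "gender_source_value", "VALUE", 5, None,
                "demographic.gender"),
            row(2, d2, "person", "year_of_birth", "VALUE", 6, None,
                "substr(demographic.birth_date, 1, 4)"),
            row(2, d2, "person", "race_concept_id", "VALUE", 7, None,
                "source_to_concept_map.target_concept_id"),
            row(2, d2, "person", "race_source_value", "VALUE", 8, None,
                "demographic.race_hl7"),
            row(2, d2, "person", "location_state", "VALUE", 9, None, "demographic.state"),
            row(2, d2, "person", "location_zip3", "VALUE", 10, None, "demographic.zip3"),
        ],
    )
    return RuleSet(rules=[rule1, rule2], data_source_id=data_source_id)
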