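# Methods

## The model

`detl` treats schema/terminology mapping as a compilation problem. The
source of truth is a set of declarative rules, authored in CSV by a domain
expert; the engine's job is purely mechanical: turn each well-formed rule
into exactly one `INSERT … SELECT` statement and run the statements in
rule order against a staging database holding the extracts as-is. Three
cleaning semantics are built into every generated statement rather than
left to rule authors:

* **duplicate collapse** — two records identical in every column except
  the surrogate record identifier are the same record; one survives;
* **conflict resolution** — records sharing an identity key but asserting
  different values are resolved to the one with the latest ETL load
  timestamp;
* **verbatim expressions** — `VALUE`, `JOIN` and `WHERE` expressions pass
  through untouched, so the full power of the backing DBMS dialect is
  available to rule authors.

The assumptions this encodes: extracts arrive as RFC 4180 CSV; each
extract table can declare an identity key (for conflict grouping) and
optionally a surrogate record-identifier column (excluded from duplicate
comparison); and rule files are trusted input — the engine enforces only
that a non-CUSTOM rule yields a single statement (no smuggled
semicolons), not that expressions are benign.

## De-duplication mechanics

Each referenced source table is replaced by a two-pass windowed CTE:

1. partition by every column except the record identifier, keep the row
   with the smallest identifier (numeric order when the identifier column
   is declared `integer`, text order otherwise) — collapses exact
   duplicates even when each copy carries a fresh surrogate id;
2. partition by the identity key, order by load timestamp descending,
   then by the remaining columns lexicographically, then by record
   identifier, keep the first row — resolves conflicts to the latest
   load, with a tie-break that is deterministic and independent of input
   order.

When a table declares no identity key, pass 2 is skipped (duplicate
collapse degenerates to `SELECT DISTINCT` if there is also no record
identifier). When the timestamp column is absent the lexicographic
tie-break alone decides, and the compiler attaches a warning to the
generated statement. De-duplication is applied to *every* table a rule
references, not only the primary table. It is idempotent by construction
(both passes keep one row per partition).

The load timestamp (`etl_timestamp` by default) is normally injected by
the staging loader as a batch-load column; extracts that already carry the
column keep their values, which is how a single file can encode multiple
load generations.

## Validation

Validation runs before transformation, against a declarative table spec
(types, lengths, required flags, keys). Cell-level rules: date/timestamp
cells must parse as ISO 8601 (`YYYY-MM-DD`, optional time part — a single
canonical grammar keeps the extraction convention explicit);
numeric/decimal/integer cells must parse as numbers; text/varchar cells
must fit their declared length; required cells must be populated (empty
string and the literal `NULL`, case-insensitive, both denote missing).
Orphan foreign keys are checked extract-to-extract by set membership;
missing references are left to the required-field rule. A spec column
whose type calls for a length/precision it lacks draws a one-per-column
warning.

Severities: an ERROR fails the extract; a WARNING never does. `strict`
mode keeps every severity as classified; `loose` mode downgrades
length-overflow and numeric-parse failures to warnings *at identical
locations* — detection never changes between modes, only severity, which
keeps the strict ⊇ loose containment property trivially auditable. Issue
messages carry table, column and 1-based data line number but never cell
contents; reporting is capped at 1000 issues per rule per table (counts
stay exact) to bound report size on pathological inputs.

## Staging and execution

The embedded engine is SQLite; generated SQL sticks to a portable core
(ANSI joins, `||`, `IN`, CTEs, window functions) and a `postgresql`
dialect tag switches on schema-qualified target names for
server-targeting use. Staging stores every cell as text, verbatim —
unloading a staged table reproduces the input file exactly, and all
comparisons (including timestamp ordering, which is ISO text) are
well-defined without type coercion. Typing happens where it belongs: in
rule expressions and in the validator.

Compiled statements are persisted to a statement store inside the
database (rule key, SQL text, generation time) before execution; the
store alone suffices to re-run a plan. Execution is fail-soft and
resumable: the first failure becomes a checkpoint, later statements are
marked skipped, and a re-run from the checkpoint reproduces the
uninterrupted end state. Re-running a full plan with `reset_targets`
clears the plan's target tables first; richer incremental-merge semantics
are deliberately out of scope. The packaged reference plan runs with
`SELECT DISTINCT` because its target entities (care sites, persons) are
keyed by source-value combinations rather than by source rows.

## Synthetic extracts

The generator emulates the *structure* of partner extracts, not clinical
content: small categorical vocabularies for cities, states, ZIPs,
place-of-service and organization-type codes, HL7 (CDC) race category
codes with their OMOP/SNOMED-mapped concepts, and a four-table layout
(claims, provider roster, demographics, concept map). Defaults: 200
claims, 50 providers, 100 persons; duplicate rate 0.1, conflict rate
0.05, orphan-FK rate 0.05, and 0.02 for each cell-error class (invalid
date, invalid numeric, over-length, missing required) — duplicate and
conflict rates follow the package's standing test conditions, the
cell-error rates are set low enough that clean rows dominate while every
class appears at default sizes.

Every injection is recorded in a ledger (table, line, column, rule id;
identity groups by record id), which is the exact ground truth the test
suite scores against. Two constructions keep that scoring exact: anomaly
classes never touch the same cell, and rows belonging to
duplicate/conflict groups are excluded from cell-error injection (an
error on a copy would silently break its "exact duplicate" status).
Conflict copies get a later timestamp than the base rows, so resolution
is exercised within a single staged file.

What the generator does *not* emulate — realistic value distributions,
free text, patient linkage across claims and clinical data, drifting
schemas — bounds what green tests show: they demonstrate the engine's
semantics (compilation, cleaning, validation, resumption) are correct,
not that any particular real extract will validate or map cleanly.

## Numerical/representational choices

* Rule CSV dialect: RFC 4180, UTF-8 (BOM tolerated), header required;
  attribute matching is case- and space-insensitive; map-type tokens are
  case-insensitive with internal whitespace collapsed.
* Empty cells parse as absent; the literal text `NULL` is preserved — in
  a `VALUE` row it deliberately emits SQL `NULL`.
* `data_source_id` is rule-set-level metadata supplied out of band (flag
  or API argument), not a 13th CSV column; the composite rule identity is
  (rule_order, rule_description, data_source_id).
* CUSTOM rules are a whole-statement escape hatch: a rule containing a
  CUSTOM row may contain nothing else, and its `source_value` is executed
  verbatim with normal provenance.
* Join clauses are emitted in ascending `map_order`; rule execution order
  is ascending `rule_order`.
* `rule_description` is required to be uniform across a rule's rows
  (it participates in the rule's identity).

## Problem sizes in the acceptance script

The script scores 100 randomized compiler instances (20–120 rows per
primary table), 1000-row extracts for the de-duplication and validation
ledger comparisons, a 500-claim clean end-to-end load, and 50 random rule
sets for round-trip identity — sizes at which the brute-force oracles are
exact and the whole run completes in seconds.

## Known limitations

* No schema-mapping inference, no GUI or real-time rule syntax checking,
  and no cross-dialect SQL translation; rules using dialect-specific
  functions must target that dialect.
* Conflict resolution assumes identity keys are declared correctly; with
  no key declared, conflicting records pass through unresolved.
* The mini-OMOP target is two tables (`care_site`, `person`); the
  limited-data-set restriction is modeled as a configurable
  excluded-column list, not a full compliance layer.
* The orphan-FK check loads parent key sets into memory; extracts beyond
  desk scale would want an engine-side join instead.
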