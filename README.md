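# detl

Rule-based ETL for harmonizing heterogeneous health data — claims and
clinical extracts — into an OMOP-style common data model.

Multi-site clinical research networks need every data partner to reshape
their EHR/claims extracts into one shared schema and terminology. The
database programming that usually requires (hand-written SQL per source) is
exactly the skill many partners lack. `detl` separates the two concerns: a
health-data domain expert writes *declarative mapping rules in a CSV file*,
and a rule engine compiles each rule into one executable `INSERT … SELECT`
statement, automatically weaving in record de-duplication, conflict
resolution, joins and filters. The generated SQL is stored verbatim, so
every transformation can be inspected, executed and debugged rule by rule.

## The rule language

A rule file is one CSV per data source. Each row has 12 attributes
(`rule_order`, `rule_description`, `target_database`, `target_schema`,
`target_table`, `target_column`, `map_type`, `map_order`,
`source_database`, `source_schema`, `source_table`, `source_value`); rows
sharing a `rule_order` form one rule, and a rule populates exactly one
target table. The row's `map_type` gives its role:

| map_type | meaning | `source_value` holds |
|---|---|---|
| `PRIMARY` | main source table (first row) | columns forming the target's key |
| `JOIN`, `LEFT/RIGHT/FULL JOIN` | additional source table | the join condition, verbatim |
| `WHERE` | optional filter (≤ 1 per rule) | the filter condition, verbatim |
| `VALUE` | one target column | any SQL expression; `NULL` for unpopulated columns |
| `CUSTOM` | escape hatch | a complete SQL statement, passed through |

A rule compiles to

```sql
INSERT INTO <target_table> (<VALUE columns, in map_order>)
SELECT <VALUE expressions, in map_order>
FROM <de-duplicated primary table>
<JOIN … ON …>          -- one per JOIN-family row
<WHERE …>              -- if a WHERE row is present
```

Every referenced source table is first wrapped in a de-duplicating common
table expression: *duplicate records* (identical in every column except the
surrogate record identifier) collapse to one, and *conflicting records*
(same identity key, different values) resolve to the row with the latest
ETL load timestamp, with a deterministic lexicographic tie-break.

Before any transformation, extracts are validated against a declared
schema: unparseable dates, missing required fields, non-numeric values in
numeric columns, over-length text and orphan foreign keys are reported by
table, column and line number — never by value, so reports stay free of
protected health information.

## Worked example

The package ships a synthetic data generator (claims + provider roster +
demographics + an HL7→SNOMED race concept map) and a reference rule set:
rule 1 loads `care_site` from claims joined to the provider roster,
restricted to organization types `'1'` and `'2'`; rule 2 loads `person`,
translating HL7 race codes to SNOMED-mapped concept ids through the
`source_to_concept_map` table.

```bash
detl gen-data --out-dir demo --seed 11 \
    --orphan-fk-rate 0 --invalid-date-rate 0 --invalid-numeric-rate 0 \
    --overlength-rate 0 --missing-required-rate 0
detl validate --data-dir demo --schema demo/source_schema.yaml
detl run --rules demo/rules.csv --data-dir demo \
    --source-schema demo/source_schema.yaml \
    --target-schema demo/target_schema.yaml \
    --data-source-id claims-demo --out-dir demo_run
```

prints

```
PASS: 0 error(s), 0 warning(s)
staged provider: 56 row(s)
staged medical_claims: 224 row(s)
staged demographic: 120 row(s)
staged source_to_concept_map: 5 row(s)
rule 1: success (105 row(s))
rule 2: success (100 row(s))
```

The extracts carry injected duplicates (rate 0.1) and conflicting records
(rate 0.05): 56 staged provider rows de-duplicate back to the 50 real
providers, 224 claim rows to 200 claims, and the 120 demographic rows to
the 100 real patients that appear as 100 `person` rows. `care_site` gets
one row per distinct (billing provider, place of service, organization
type) combination passing the filter — 105 here. The generated SQL for each
rule lands in `demo_run/rule_000N.sql` for inspection, and
`detl run --rule 1 …` executes a single rule for debugging. With nonzero
error-injection rates, `detl validate` exits nonzero and lists each
problem as e.g.
`ERROR [invalid-date] demographic.birth_date line 10: cell cannot be parsed as a date`.

The same workflow is available as a library — see
`detl.parse_rules`, `detl.compile_ruleset`, `detl.StagingDatabase`,
`detl.validate_table` and `detl.generate_extracts`.

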