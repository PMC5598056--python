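"""SQL generation: join/filter/projection semantics, de-duplication,
conflict resolution and the brute-force relational oracle comparison."""

from __future__ import annotations

import random

import pytest

from detl import (
    ColumnSpec,
    CompileError,
    CompileOptions,
    Rule,
    RuleRow,
    RuleSet,
    StagingDatabase,
    TableSpec,
    build_dedup_subquery,
    compile_custom,
    compile_rule,
    compile_ruleset,
    mini_target_schema,
    reference_rules,
)
from harness import as_multiset, rule_for_instance, run_instance_through_engine
from oracle import dedup_oracle, oracle_result, random_instance


def _row(map_type, map_order, **kw):
    kw.setdefault("rule_description", "d")
    kw.setdefault("target_table", "t")
    return RuleRow(rule_order=1, map_type=map_type, map_order=map_order, **kw)


@pytest.fixture
def claims_db():
    """Tiny hand-built claims/provider staging database (no anomalies)."""
    db = StagingDatabase()
    provider = TableSpec(
        "provider",
        [ColumnSpec(c) for c in (
            "provider_row_id", "provider_id", "provider_organization_type",
            "provider_address_first_line", "provider_street", "provider_city",
            "provider_state", "provider_zip", "etl_timestamp")],
        primary_key=["provider_id"],
        record_id="provider_row_id",
    )
    claims = TableSpec(
        "medical_claims",
        [ColumnSpec(c) for c in (
            "claim_line_id", "claim_id", "billing_provider_id",
            "place_of_service_code", "etl_timestamp")],
        primary_key=["claim_id"],
        record_id="claim_line_id",
    )
    db.create_table(provider)
    db.create_table(claims)
    ts = "2024-01-01T00:00:00"
    db.conn.executemany(
        "INSERT INTO provider VALUES (?,?,?,?,?,?,?,?,?)",
        [
            ("1", "P1", "1", "100 Main St", "Suite 1", "Aurora", "CO", "80045", ts),
            ("2", "P2", "3", "200 Oak St", "Suite 2", "Denver", "CO", "80202", ts),
            ("3", "P3", "2", "300 Elm St", "Suite 3", "Boulder", "CO", "80301", ts),
        ],
    )
    db.conn.executemany(
        "INSERT INTO medical_claims VALUES (?,?,?,?,?)",
        [
            ("1", "C1", "P1", "11", ts),
            ("2", "C2", "P2", "21", ts),  # filtered: org type 3
            ("3", "C3", "P3", "22", ts),
            ("4", "C4", "P9", "11", ts),  # no matching provider
        ],
    )
    for spec in mini_target_schema():
        db.create_table(spec)
    yield db
    db.close()


class TestWorkedExample:
    def test_care_site_statement_semantics(self, claims_db):
        """Executing the compiled care_site rule reproduces the documented
        projection over the filtered claims-provider join."""
        rule = reference_rules().rules[0]
        opts = CompileOptions(source_specs=dict(claims_db.specs))
        stmt = compile_rule(rule, opts)
        assert stmt.sql_text.count("INSERT INTO") == 1
        report = claims_db.execute_statements([stmt])
        assert report.ok
        rows = claims_db.fetch_table("care_site")
        expected = {
            # claim C1 -> provider P1 (type 1), claim C3 -> provider P3 (type 2)
            (None, "P1-11-1", None, "11", "100 Main St", "Suite 1", "Aurora",
             "CO", "80045", None),
            (None, "P3-22-2", None, "22", "300 Elm St", "Suite 3", "Boulder",
             "CO", "80301", None),
        }
        assert set(rows) == expected
        # column/expression alignment: the NULL rows land in their columns
        header = claims_db.table_columns("care_site")
        assert header[1] == "care_site_source_value"

    def test_insert_column_list_follows_map_order(self):
        rule = reference_rules().rules[0]
        stmt = compile_rule(rule, CompileOptions(dedup_enabled=False))
        cols_clause = stmt.sql_text.split("(")[1].split(")")[0]
        assert [c.strip() for c in cols_clause.split(",")] == [
            r.target_column for r in rule.value_rows
        ]


class TestCompileBasics:
    def test_minimal_rule(self):
        rule = Rule(
            rows=[
                _row("PRIMARY", 1, source_table="s", source_value="s.k"),
                _row("VALUE", 2, target_column="c", source_value="s.col"),
            ],
            data_source_id="d",
        )
        stmt = compile_rule(rule, CompileOptions(dedup_enabled=False))
        sql = " ".join(stmt.sql_text.split())
        assert sql == "INSERT INTO t (c) SELECT s.col FROM s AS s"

    def test_unknown_table_reference_names_the_table(self):
        rule = Rule(
            rows=[
                _row("PRIMARY", 1, source_table="s", source_value="s.k"),
                _row("VALUE", 2, target_column="c", source_value="mystery.col"),
            ],
            data_source_id="d",
        )
        with pytest.raises(CompileError, match="mystery"):
            compile_rule(rule, CompileOptions())

    def test_table_name_inside_string_literal_is_not_a_reference(self):
        rule = Rule(
            rows=[
                _row("PRIMARY", 1, source_table="s", source_value="s.k"),
                _row("VALUE", 2, target_column="c", source_value="'mystery.col'"),
            ],
            data_source_id="d",
        )
        compile_rule(rule, CompileOptions())  # must not raise

    def test_semicolon_smuggling_rejected(self):
        rule = Rule(
            rows=[
                _row("PRIMARY", 1, source_table="s", source_value="s.k"),
                _row("VALUE", 2, target_column="c",
                     source_value="s.col; DROP TABLE t"),
            ],
            data_source_id="d",
        )
        with pytest.raises(CompileError, match="one statement"):
            compile_rule(rule, CompileOptions())

    def test_select_distinct_option(self):
        rule = Rule(
            rows=[
                _row("PRIMARY", 1, source_table="s", source_value="s.k"),
                _row("VALUE", 2, target_column="c", source_value="s.col"),
            ],
            data_source_id="d",
        )
        stmt = compile_rule(rule, CompileOptions(dedup_enabled=False, select_distinct=True))
        assert "SELECT DISTINCT" in stmt.sql_text

    def test_postgresql_dialect_qualifies_target_schema(self):
        rule = Rule(
            rows=[
                _row("PRIMARY", 1, source_table="s", source_value="s.k",
                     target_schema="cdm"),
                _row("VALUE", 2, target_column="c", source_value="s.col",
                     target_schema="cdm"),
            ],
            data_source_id="d",
        )
        stmt = compile_rule(
            rule, CompileOptions(dedup_enabled=False, dialect="postgresql")
        )
        assert "INSERT INTO cdm.t" in stmt.sql_text


class TestCustomRules:
    def _custom(self, sql):
        return Rule(
            rows=[_row("CUSTOM", 1, source_value=sql)], data_source_id="d"
        )

    def test_passthrough_verbatim(self):
        stmt = compile_custom(self._custom("INSERT INTO t SELECT 1"))
        assert stmt.sql_text == "INSERT INTO t SELECT 1"
        assert stmt.rule_key[0] == 1

    def test_empty_custom_is_an_error(self):
        with pytest.raises(CompileError, match="empty"):
            compile_custom(self._custom(None))

    def test_compile_rule_dispatches_custom(self):
        stmt = compile_rule(self._custom("INSERT INTO t SELECT 1"))
        assert stmt.sql_text == "INSERT INTO t SELECT 1"

    def test_custom_execution_equals_manual_execution(self):
        sql = "INSERT INTO t (c) SELECT 'x'"
        with StagingDatabase() as db1, StagingDatabase() as db2:
            for db in (db1, db2):
                db.create_table(TableSpec("t", [ColumnSpec("c")]))
            report = db1.execute_statements([compile_custom(self._custom(sql))])
            assert report.ok
            db2.conn.execute(sql)
            assert db1.fetch_table("t") == db2.fetch_table("t")


class TestDeduplication:
    SPEC = TableSpec(
        "src",
        [ColumnSpec(c) for c in ("rid", "k", "city", "etl_timestamp")],
        primary_key=["k"],
        record_id="rid",
    )

    def _dedup_rows(self, rows, spec=None, opts=None):
        spec = spec or self.SPEC
        opts = opts or CompileOptions()
        with StagingDatabase() as db:
            db.create_table(spec)
            ph = ", ".join("?" for _ in spec.columns)
            db.conn.executemany(f"INSERT INTO {spec.name} VALUES ({ph})", rows)
            frag = build_dedup_subquery(spec.name, spec, opts)
            return db.conn.execute(f"SELECT * FROM {frag}").fetchall()

    def test_exact_duplicates_collapse_to_one(self):
        rows = [
            ("1", "K1", "Aurora", "2024-01-01"),
            ("2", "K1", "Aurora", "2024-01-01"),  # full-row copy, new record id
        ]
        out = self._dedup_rows(rows)
        assert len(out) == 1

    def test_conflict_resolves_to_latest_timestamp(self):
        rows = [
            ("1", "K1", "Aurora", "2024-01-01"),
            ("2", "K1", "Denver", "2024-02-01"),  # same identity, later load
        ]
        out = self._dedup_rows(rows)
        assert out == [("2", "K1", "Denver", "2024-02-01")]

    def test_tie_breaks_are_deterministic_without_timestamp(self):
        spec = TableSpec(
            "src", [ColumnSpec(c) for c in ("rid", "k", "city")],
            primary_key=["k"], record_id="rid",
        )
        rows = [("1", "K1", "Denver"), ("2", "K1", "Aurora")]
        out = self._dedup_rows(rows, spec=spec)
        assert out == [("2", "K1", "Aurora")]  # lexicographically first city
        # input order must not matter
        assert self._dedup_rows(list(reversed(rows)), spec=spec) == out

    def test_missing_timestamp_column_warns(self):
        spec = TableSpec(
            "src", [ColumnSpec(c) for c in ("rid", "k", "city")],
            primary_key=["k"], record_id="rid",
        )
        rule = Rule(
            rows=[
                _row("PRIMARY", 1, source_table="src", source_value="src.k"),
                _row("VALUE", 2, target_column="c", source_value="src.city"),
            ],
            data_source_id="d",
        )
        stmt = compile_rule(rule, CompileOptions(source_specs={"src": spec}))
        assert any("etl_timestamp" in w for w in stmt.warnings)

    def test_dedup_is_idempotent(self):
        rng = random.Random(5)
        rows = [
            (str(i), f"K{rng.randrange(6)}", rng.choice(["A", "B", "C"]),
             rng.choice(["2024-01-01", "2024-02-01"]))
            for i in range(1, 60)
        ]
        opts = CompileOptions()
        with StagingDatabase() as db:
            db.create_table(self.SPEC)
            db.conn.executemany("INSERT INTO src VALUES (?,?,?,?)", rows)
            frag = build_dedup_subquery("src", self.SPEC, opts)
            once = db.conn.execute(f"SELECT * FROM {frag}").fetchall()
            db.conn.execute(f"CREATE TABLE src2 AS SELECT * FROM {frag}")
            spec2 = TableSpec(
                "src2", self.SPEC.columns, primary_key=["k"], record_id="rid"
            )
            frag2 = build_dedup_subquery("src2", spec2, opts)
            twice = db.conn.execute(f"SELECT * FROM {frag2}").fetchall()
        assert as_multiset(once) == as_multiset(twice)

    def test_randomized_dedup_matches_groupby_argmax_oracle(self):
        rng = random.Random(17)
        for _ in range(10):
            rows = [
                (str(i), f"K{rng.randrange(8)}", rng.choice(["A", "B", "C", "D"]),
                 rng.choice(["2024-01-01", "2024-02-01", "2024-03-01"]))
                for i in range(1, rng.randrange(30, 120))
            ]
            engine = self._dedup_rows(rows)
            cols = ["rid", "k", "city", "etl_timestamp"]
            expected = dedup_oracle(
                [dict(zip(cols, r)) for r in rows], cols, ["k"], record_id="rid"
            )
            assert as_multiset(engine) == as_multiset(
                tuple(r[c] for c in cols) for r in expected
            )


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(25))
    def test_compiled_statement_equals_bruteforce_oracle(self, seed):
        """Projection over filtered joins of de-duplicated inputs, multiset
        exact, on randomized instances."""
        instance = random_instance(random.Random(1000 + seed))
        engine = run_instance_through_engine(instance)
        expected = oracle_result(instance)
        assert as_multiset(engine) == as_multiset(expected)

    def test_monotone_filtering(self):
        """Rows produced with a WHERE row are a sub-multiset of the rows
        produced after deleting it."""
        rng = random.Random(42)
        checked = 0
        for _ in range(20):
            instance = random_instance(rng)
            if instance["where"] is None:
                continue
            with_where = as_multiset(run_instance_through_engine(instance))
            instance_no_where = dict(instance, where=None)
            without = as_multiset(run_instance_through_engine(instance_no_where))
            assert all(with_where[k] <= without.get(k, 0) for k in with_where)
            checked += 1
        assert checked >= 5

    def test_column_alignment_with_sentinels(self):
        """The i-th inserted column receives the i-th VALUE expression."""
        instance = {
            "tables": {
                "src_a": {
                    "columns": ["rid", "k", "j", "c1", "c2"],
                    "rows": [{"rid": "1", "k": "K1", "j": "K1", "c1": "a", "c2": "b"}],
                    "pk": ["k"],
                    "record_id": "rid",
                },
                "src_b": {"columns": ["rid", "k"], "rows": [], "pk": ["k"],
                          "record_id": "rid"},
            },
            "primary": "src_a",
            "joins": [],
            "where": None,
            "value_exprs": ["'sent_0'", "'sent_1'", "NULL", "'sent_3'"],
            "has_ts": False,
        }
        rows = run_instance_through_engine(instance)
        assert rows == [("sent_0", "sent_1", None, "sent_3")]


class TestBatchCompilation:
    def test_statement_count_equals_rule_count(self):
        rs = reference_rules()
        result = compile_ruleset(rs, CompileOptions(dedup_enabled=False))
        assert len(result) == len(rs)
        assert [s.rule_order for s in result] == sorted(r.rule_order for r in rs)

    def test_fail_soft_collects_errors(self):
        good = reference_rules().rules[0]
        bad = Rule(
            rows=[
                RuleRow(rule_order=9, map_type="PRIMARY", map_order=1,
                        rule_description="bad", target_table="t",
                        source_table="s", source_value="s.k"),
                RuleRow(rule_order=9, map_type="VALUE", map_order=2,
                        rule_description="bad", target_table="t",
                        target_column="c", source_value="ghost.col"),
            ],
            data_source_id="d",
        )
        rs = RuleSet(rules=[good, bad], data_source_id="d")
        result = compile_ruleset(rs, CompileOptions(dedup_enabled=False))
        assert len(result) == 1 and len(result.errors) == 1
        assert result.errors[0][0][0] == 9
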