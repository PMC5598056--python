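"""Helpers shared by the test suite: run oracle instances through the real
engine, and generate random well-formed rule sets for round-trip checks."""

from __future__ import annotations

import random
from collections import Counter

from detl import (
    ColumnSpec,
    CompileOptions,
    Rule,
    RuleRow,
    RuleSet,
    StagingDatabase,
    TableSpec,
    compile_rule,
)


def specs_for_instance(instance: dict) -> dict[str, TableSpec]:
    out = {}
    for name, t in instance["tables"].items():
        out[name] = TableSpec(
            name=name,
            columns=[ColumnSpec(c, "text") for c in t["columns"]],
            primary_key=t["pk"],
            record_id=t["record_id"],
        )
    return out


def rule_for_instance(instance: dict, target: str = "target_t") -> Rule:
    rows = [
        RuleRow(
            rule_order=1,
            map_type="PRIMARY",
            map_order=1,
            rule_description="randomized instance",
            target_table=target,
            source_table=instance["primary"],
            source_value=f"{instance['primary']}.k",
        )
    ]
    order = 2
    for join_type, table, cond in instance["joins"]:
        rows.append(
            RuleRow(
                rule_order=1,
                map_type=join_type,
                map_order=order,
                rule_description="randomized instance",
                target_table=target,
                source_table=table,
                source_value=cond,
            )
        )
        order += 1
    if instance["where"] is not None:
        rows.append(
            RuleRow(
                rule_order=1,
                map_type="WHERE",
                map_order=order,
                rule_description="randomized instance",
                target_table=target,
                source_value=instance["where"],
            )
        )
        order += 1
    for i, expr in enumerate(instance["value_exprs"]):
        rows.append(
            RuleRow(
                rule_order=1,
                map_type="VALUE",
                map_order=order + i,
                rule_description="randomized instance",
                target_table=target,
                target_column=f"v{i}",
                source_value=expr,
            )
        )
    return Rule(rows=rows, data_source_id="test")


def run_instance_through_engine(instance: dict, dedup: bool = True) -> list[tuple]:
    """Compile the instance's rule and execute it on the embedded engine."""
    specs = specs_for_instance(instance)
    with StagingDatabase() as db:
        for name, spec in specs.items():
            db.create_table(spec)
            t = instance["tables"][name]
            cols = ", ".join(t["columns"])
            ph = ", ".join("?" for _ in t["columns"])
            db.conn.executemany(
                f"INSERT INTO {name} ({cols}) VALUES ({ph})",
                [[r[c] for c in t["columns"]] for r in t["rows"]],
            )
        n_vals = len(instance["value_exprs"])
        db.create_table(
            TableSpec("target_t", [ColumnSpec(f"v{i}", "text") for i in range(n_vals)])
        )
        rule = rule_for_instance(instance)
        opts = CompileOptions(dedup_enabled=dedup, source_specs=specs)
        stmt = compile_rule(rule, opts)
        report = db.execute_statements([stmt])
        assert report.ok, report.entries[0].error
        return db.fetch_table("target_t")


def as_multiset(rows) -> Counter:
    return Counter(tuple(r) for r in rows)


# --- random well-formed rule sets --------------------------------------

_WORDS = ["alpha", "beta", "gamma", "delta", "omega", "kappa"]


def random_ruleset(rng: random.Random, n_rules: int | None = None) -> RuleSet:
    """A structurally valid random rule set (for round-trip identity)."""
    n_rules = n_rules or rng.randrange(1, 6)
    rules = []
    orders = rng.sample(range(1, 100), n_rules)
    for order in orders:
        desc = " ".join(rng.choice(_WORDS) for _ in range(rng.randrange(1, 5)))
        if rng.random() < 0.2:
            desc += ", with 'quotes' and, commas"  # stress CSV quoting
        target = f"tgt_{rng.choice(_WORDS)}"
        rows = [
            RuleRow(
                rule_order=order,
                map_type="PRIMARY",
                map_order=1,
                rule_description=desc,
                target_table=target,
                source_table=f"src_{rng.choice(_WORDS)}",
                source_value=f"src_{rng.choice(_WORDS)}.k",
            )
        ]
        morder = 2
        for _ in range(rng.randrange(0, 3)):
            jt = rng.choice(["JOIN", "LEFT JOIN", "RIGHT JOIN", "FULL JOIN"])
            tbl = f"src_{rng.choice(_WORDS)}"
            rows.append(
                RuleRow(
                    rule_order=order,
                    map_type=jt,
                    map_order=morder,
                    rule_description=desc,
                    target_table=target,
                    source_table=tbl,
                    source_value=f"{rows[0].source_table}.k = {tbl}.k",
                )
            )
            morder += 1
        if rng.random() < 0.5:
            rows.append(
                RuleRow(
                    rule_order=order,
                    map_type="WHERE",
                    map_order=morder,
                    rule_description=desc,
                    target_table=target,
                    source_value=f"{rows[0].source_table}.c IN ('x', 'y')",
                )
            )
            morder += 1
        for i in range(rng.randrange(1, 6)):
            rows.append(
                RuleRow(
                    rule_order=order,
                    map_type="VALUE",
                    map_order=morder + i,
                    rule_description=desc,
                    target_table=target,
                    target_column=f"col_{i}",
                    source_value=rng.choice(
                        [f"{rows[0].source_table}.c{i}", "NULL", f"'{rng.choice(_WORDS)}'"]
                    ),
                )
            )
        rules.append(Rule(rows=rows, data_source_id="rt-test"))
    rules.sort(key=lambda r: r.rule_order)
    return RuleSet(rules=rules, data_source_id="rt-test")


def ruleset_signature(rs: RuleSet) -> list:
    """Field-by-field structural content, for round-trip equality checks."""
    return [
        (rule.data_source_id, [row.key_fields() for row in rule.rows])
        for rule in rs.rules
    ]
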