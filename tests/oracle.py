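"""Brute-force in-memory relational oracle, independent of any SQL engine.

Used to cross-check compiled statements: de-duplication as an explicit
group-by/arg-max over Python dicts, joins as nested loops, filters and
projections through a tiny recursive-descent evaluator for the restricted
expression grammar the synthetic rules use (string literals, NULL,
qualified columns, ``||`` concatenation, ``=``, ``IN``, ``AND``).

Everything here works on lists of dicts and compares values as text,
mirroring the as-is (text-affinity) staging convention.
"""

from __future__ import annotations

import random
import re
from typing import Optional

# --- expression evaluator ---------------------------------------------

_TOKEN_RE = re.compile(
    r"\s*(?:"
    r"(?P<concat>\|\|)"
    r"|(?P<op>=|<>)"
    r"|(?P<lpar>\()"
    r"|(?P<rpar>\))"
    r"|(?P<comma>,)"
    r"|(?P<string>'(?:[^']|'')*')"
    r"|(?P<ident>[A-Za-z_][A-Za-z0-9_]*(?:\.[A-Za-z_][A-Za-z0-9_]*)?)"
    r")"
)


def tokenize(expr: str) -> list[tuple[str, str]]:
    tokens = []
    pos = 0
    while pos < len(expr):
        m = _TOKEN_RE.match(expr, pos)
        if not m or m.end() == pos:
            if expr[pos:].strip() == "":
                break
            raise ValueError(f"cannot tokenize {expr!r} at {pos}")
        pos = m.end()
        kind = m.lastgroup
        tokens.append((kind, m.group(kind)))
    return tokens


class _Parser:
    def __init__(self, tokens: list[tuple[str, str]]):
        self.tokens = tokens
        self.i = 0

    def peek(self):
        return self.tokens[self.i] if self.i < len(self.tokens) else (None, None)

    def next(self):
        tok = self.peek()
        self.i += 1
        return tok

    def expect(self, kind: str):
        tok = self.next()
        if tok[0] != kind:
            raise ValueError(f"expected {kind}, got {tok}")
        return tok

    # condition := comparison (AND comparison)*
    def condition(self):
        node = self.comparison()
        while self.peek() == ("ident", "AND") or (
            self.peek()[0] == "ident" and self.peek()[1].upper() == "AND"
        ):
            self.next()
            node = ("and", node, self.comparison())
        return node

    # comparison := concat (('='|'<>') concat | IN '(' literals ')')?
    def comparison(self):
        left = self.concat()
        kind, val = self.peek()
        if kind == "op":
            self.next()
            return ("eq" if val == "=" else "ne", left, self.concat())
        if kind == "ident" and val.upper() == "IN":
            self.next()
            self.expect("lpar")
            items = [self.atom()]
            while self.peek()[0] == "comma":
                self.next()
                items.append(self.atom())
            self.expect("rpar")
            return ("in", left, items)
        return left

    # concat := atom ('||' atom)*
    def concat(self):
        node = self.atom()
        while self.peek()[0] == "concat":
            self.next()
            node = ("concat", node, self.atom())
        return node

    def atom(self):
        kind, val = self.next()
        if kind == "string":
            return ("lit", val[1:-1].replace("''", "'"))
        if kind == "ident":
            if val.upper() == "NULL":
                return ("null",)
            if "." in val:
                return ("col", val)
            raise ValueError(f"bare identifier {val!r} not supported")
        if kind == "lpar":
            node = self.condition()
            self.expect("rpar")
            return node
        raise ValueError(f"unexpected token {kind} {val!r}")


def parse_expr(expr: str):
    p = _Parser(tokenize(expr))
    node = p.condition()
    if p.i != len(p.tokens):
        raise ValueError(f"trailing tokens in {expr!r}")
    return node


def eval_node(node, env: dict[str, Optional[str]]):
    """Evaluate with SQL-ish semantics: None propagates, unknown is falsy."""
    kind = node[0]
    if kind == "lit":
        return node[1]
    if kind == "null":
        return None
    if kind == "col":
        return env.get(node[1])
    if kind == "concat":
        a, b = eval_node(node[1], env), eval_node(node[2], env)
        return None if a is None or b is None else str(a) + str(b)
    if kind in ("eq", "ne"):
        a, b = eval_node(node[1], env), eval_node(node[2], env)
        if a is None or b is None:
            return False
        return (a == b) if kind == "eq" else (a != b)
    if kind == "in":
        a = eval_node(node[1], env)
        if a is None:
            return False
        return any(a == eval_node(item, env) for item in node[2])
    if kind == "and":
        return bool(eval_node(node[1], env)) and bool(eval_node(node[2], env))
    raise ValueError(f"unknown node {node}")


def eval_expr(expr: str, env: dict[str, Optional[str]]):
    return eval_node(parse_expr(expr), env)


# --- de-duplication oracle --------------------------------------------


def dedup_oracle(
    rows: list[dict],
    columns: list[str],
    primary_key: list[str],
    record_id: Optional[str] = None,
    ts_col: Optional[str] = "etl_timestamp",
    numeric_record_id: bool = False,
) -> list[dict]:
    """Group-by/arg-max de-duplication over plain dicts.

    1. exact duplicates — identical in every column except ``record_id`` —
       collapse to the copy with the smallest record identifier (numeric
       order when the identifier column is declared integer, else text);
    2. within each identity (primary-key) group the survivor is the row
       with the latest ``ts_col`` value, ties broken lexicographically over
       the non-key columns, then by record identifier.
    """
    if ts_col is not None and ts_col not in columns:
        ts_col = None
    content = [c for c in columns if c != record_id]

    def rid_key(r: dict):
        v = r[record_id]
        return int(v) if numeric_record_id else str(v)

    if record_id is not None:
        seen: dict[tuple, dict] = {}
        for r in rows:
            key = tuple(r[c] for c in content)
            if key not in seen or rid_key(r) < rid_key(seen[key]):
                seen[key] = r
        stage1 = list(seen.values())
    else:
        stage1 = list({tuple(r[c] for c in columns): r for r in rows}.values())

    pk = [c for c in primary_key if c != record_id]
    if not pk:
        return stage1
    tie_break = [c for c in content if c not in pk and c != ts_col]
    groups: dict[tuple, list[dict]] = {}
    for r in stage1:
        groups.setdefault(tuple(r[c] for c in pk), []).append(r)
    out = []
    for grp in groups.values():
        if ts_col is not None:
            latest = max(str(r[ts_col]) for r in grp)
            grp = [r for r in grp if str(r[ts_col]) == latest]
        out.append(
            min(
                grp,
                key=lambda r: (
                    tuple(str(r[c]) for c in tie_break),
                    rid_key(r) if record_id else 0,
                ),
            )
        )
    return out


# --- rule evaluation ---------------------------------------------------


def _env_of(bound: dict[str, Optional[dict]]) -> dict[str, Optional[str]]:
    env: dict[str, Optional[str]] = {}
    for table, row in bound.items():
        if row is None:
            continue
        for col, val in row.items():
            env[f"{table}.{col}"] = val
    return env


def evaluate_rule(
    primary: str,
    joins: list[tuple[str, str, str]],  # (join_type, table, condition)
    where: Optional[str],
    value_exprs: list[str],
    tables: dict[str, list[dict]],
) -> list[tuple]:
    """Nested-loop join + filter + projection over (already deduped) rows.

    Supports inner JOIN and LEFT JOIN; a LEFT JOIN with no match binds the
    joined table to an all-NULL row.  Returns the projected row multiset as
    a list of tuples (None for SQL NULL).
    """
    bindings: list[dict[str, Optional[dict]]] = [{primary: r} for r in tables[primary]]
    for join_type, table, cond in joins:
        cond_ast = parse_expr(cond)
        new: list[dict[str, Optional[dict]]] = []
        for bound in bindings:
            matched = False
            for cand in tables[table]:
                trial = dict(bound)
                trial[table] = cand
                if eval_node(cond_ast, _env_of(trial)):
                    new.append(trial)
                    matched = True
            if not matched and join_type == "LEFT JOIN":
                trial = dict(bound)
                trial[table] = None
                new.append(trial)
        bindings = new
    if where is not None:
        where_ast = parse_expr(where)
        bindings = [b for b in bindings if eval_node(where_ast, _env_of(b))]
    projections = [parse_expr(e) for e in value_exprs]
    out = []
    for b in bindings:
        env = _env_of(b)
        row = []
        for p in projections:
            v = eval_node(p, env)
            row.append(None if v is None or isinstance(v, bool) else str(v))
        out.append(tuple(row))
    return out


# --- random instance generator ----------------------------------------

_VOCAB = ["a", "b", "c", "dd", "e1"]
_TS_VOCAB = ["2024-01-01T00:00:00", "2024-02-01T00:00:00", "2024-03-01T00:00:00"]


def random_instance(rng: random.Random) -> dict:
    """One randomized schema + data + rule for compiler/oracle comparison.

    Two source tables (``src_a`` primary, ``src_b`` optionally joined), with
    identity keys drawn from small vocabularies so duplicate and conflicting
    records arise naturally, an optional WHERE filter, and 2–4 VALUE
    expressions mixing columns, literals, NULL and concatenation.
    """
    has_ts = rng.random() < 0.8
    a_cols = ["rid", "k", "j", "c1", "c2"] + (["etl_timestamp"] if has_ts else [])
    b_cols = ["rid", "k", "c1", "c2"] + (["etl_timestamp"] if has_ts else [])

    def make_rows(cols: list[str], n: int, key_span: int) -> list[dict]:
        rows = []
        for i in range(n):
            r = {"rid": str(i + 1)}
            for c in cols:
                if c == "rid":
                    continue
                if c == "k":
                    r[c] = f"K{rng.randrange(key_span)}"
                elif c == "j":
                    r[c] = f"K{rng.randrange(8)}"
                elif c == "etl_timestamp":
                    r[c] = rng.choice(_TS_VOCAB)
                else:
                    r[c] = rng.choice(_VOCAB)
            rows.append(r)
        return rows

    n_a = rng.randrange(20, 120)
    n_b = rng.randrange(5, 40)
    rows_a = make_rows(a_cols, n_a, key_span=max(4, n_a // 2))
    rows_b = make_rows(b_cols, n_b, key_span=8)

    has_join = rng.random() < 0.75
    join_type = rng.choice(["JOIN", "LEFT JOIN"]) if has_join else None
    joins = [(join_type, "src_b", "src_a.j = src_b.k")] if has_join else []

    where = None
    if rng.random() < 0.5:
        choices = ["src_a.c1 IN ('a', 'b')", "src_a.c2 = 'c'", "src_a.c1 = src_a.c2"]
        if has_join:
            choices += ["src_b.c1 = 'a'", "src_a.c1 = src_b.c2"]
        where = rng.choice(choices)

    def value_expr() -> str:
        pool = ["src_a.k", "src_a.c1", "src_a.c2"]
        if has_join:
            pool += ["src_b.c1", "src_b.c2"]
        kind = rng.random()
        if kind < 0.45:
            return rng.choice(pool)
        if kind < 0.6:
            return f"'{rng.choice(_VOCAB)}'"
        if kind < 0.7:
            return "NULL"
        return f"{rng.choice(pool)} || '-' || {rng.choice(pool)}"

    value_exprs = [value_expr() for _ in range(rng.randrange(2, 5))]
    return {
        "tables": {
            "src_a": {"columns": a_cols, "rows": rows_a, "pk": ["k"], "record_id": "rid"},
            "src_b": {"columns": b_cols, "rows": rows_b, "pk": ["k"], "record_id": "rid"},
        },
        "primary": "src_a",
        "joins": joins,
        "where": where,
        "value_exprs": value_exprs,
        "has_ts": has_ts,
    }


def oracle_result(instance: dict, dedup: bool = True) -> list[tuple]:
    """Evaluate one random instance entirely in memory."""
    deduped = {}
    for name, t in instance["tables"].items():
        rows = t["rows"]
        if dedup:
            rows = dedup_oracle(
                rows,
                t["columns"],
                t["pk"],
                record_id=t["record_id"],
                ts_col="etl_timestamp" if instance["has_ts"] else None,
            )
        deduped[name] = rows
    return evaluate_rule(
        instance["primary"],
        instance["joins"],
        instance["where"],
        instance["value_exprs"],
        deduped,
    )
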