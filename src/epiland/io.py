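"""Readers and writers for the plain-text network formats.

Two formats are supported:

* **Rule files** (``.bnet``): one line per node, ``target, expression``
  with operators ``&``, ``|``, ``!``, parentheses and the constants
  ``0``/``1``.  Expressions are compiled to truth tables on load; the
  writer emits a canonical sum-of-products expression per node.
* **SIF signed edge lists**: tab-separated ``source  +/-  target``.

A third loader accepts explicit truth tables as TSV (one file per node
set: regulator columns plus an ``output`` column).
"""

from __future__ import annotations

import ast
import re
from pathlib import Path
from typing import Iterable

from .network import BooleanNetwork, TruthTable

_NAME_RE = re.compile(r"[A-Za-z_][A-Za-z0-9_.]*")

# Python-identifier aliases for node names that contain characters the
# expression parser cannot digest (e.g. "NF-kB" -> "NF_kB").
def _pyname(name: str) -> str:
    return re.sub(r"[^A-Za-z0-9_]", "_", name)


def parse_expression(expr: str, regulators: Iterable[str]) -> TruthTable:
    """Compile a Boolean expression into a truth table over ``regulators``.

    The regulator order given here defines the row-index bit order.
    """
    regs = tuple(regulators)
    alias = {_pyname(r): r for r in regs}
    py = expr.replace("&", " and ").replace("|", " or ").replace("!", " not ")
    py = re.sub(
        _NAME_RE,
        lambda m: _pyname(m.group(0)) if m.group(0) not in ("and", "or", "not") else m.group(0),
        py,
    ).strip()
    tree = ast.parse(py, mode="eval")
    code = compile(tree, "<rule>", "eval")
    outputs = []
    for row in range(2 ** len(regs)):
        env = {
            _pyname(r): bool((row >> (len(regs) - 1 - j)) & 1)
            for j, r in enumerate(regs)
        }
        outputs.append(int(bool(eval(code, {"__builtins__": {}}, env))))
    del alias
    return TruthTable(regulators=regs, outputs=tuple(outputs))


def _expression_names(expr: str) -> list[str]:
    seen: list[str] = []
    for m in _NAME_RE.finditer(expr.replace("&", " ").replace("|", " ").replace("!", " ")):
        tok = m.group(0)
        if tok not in ("and", "or", "not") and tok not in seen:
            seen.append(tok)
    return seen


def read_bnet(path: str | Path) -> BooleanNetwork:
    """Read a rule file: ``target, expression`` per line.

    Node names may contain ``-`` (as in ``NF-kB``); occurrences in
    expressions are matched against the declared targets greedily before
    tokenisation.
    """
    lines = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.lower().replace(" ", "").startswith("targets,factors"):
            continue
        lines.append(line)
    targets, exprs = [], []
    for line in lines:
        target, _, expr = line.partition(",")
        target, expr = target.strip(), expr.strip()
        if not expr:
            raise ValueError(f"malformed rule line: {line!r}")
        targets.append(target)
        exprs.append(expr)
    # map hyphenated node names to parser-safe aliases inside expressions
    sub = {t: _pyname(t) for t in targets}
    back = {v: k for k, v in sub.items()}
    rules = {}
    for target, expr in zip(targets, exprs):
        safe = expr
        for name in sorted(sub, key=len, reverse=True):
            safe = safe.replace(name, sub[name])
        if safe.strip() in ("0", "1"):
            rules[target] = TruthTable(regulators=(), outputs=(int(safe.strip()),))
            continue
        names = [nm for nm in _expression_names(safe) if nm not in ("0", "1")]
        regs = tuple(back.get(nm, nm) for nm in names)
        unknown = [r for r in regs if r not in targets]
        if unknown:
            raise ValueError(f"rule for {target!r} names unknown nodes {unknown}")
        tt = parse_expression(safe, tuple(sub[r] for r in regs))
        rules[target] = TruthTable(regulators=regs, outputs=tt.outputs)
    return BooleanNetwork(nodes=tuple(targets), rules=rules)


def _sop_expression(tt: TruthTable, alias: dict[str, str] | None = None) -> str:
    """Canonical sum-of-products form of a truth table."""
    regs = tt.regulators
    name = (alias or {}).__getitem__ if alias else (lambda r: r)
    get = (lambda r: alias[r]) if alias else (lambda r: r)
    if not regs:
        return str(tt.outputs[0])
    if all(o == 0 for o in tt.outputs):
        return "0"
    if all(o == 1 for o in tt.outputs):
        return "1"
    terms = []
    for row, out in enumerate(tt.outputs):
        if not out:
            continue
        lits = []
        for j, r in enumerate(regs):
            bit = (row >> (len(regs) - 1 - j)) & 1
            lits.append(get(r) if bit else f"!{get(r)}")
        terms.append("(" + " & ".join(lits) + ")")
    return " | ".join(terms)


def write_bnet(net: BooleanNetwork, path: str | Path) -> None:
    """Write a rule file with canonical sum-of-products expressions."""
    out = ["targets, factors"]
    for node in net.nodes:
        out.append(f"{node}, {_sop_expression(net.rules[node])}")
    Path(path).write_text("\n".join(out) + "\n")


def read_truth_table_tsv(path: str | Path) -> TruthTable:
    """Load one node's explicit truth table from TSV.

    Header: regulator names then ``output``; one row per regulator
    pattern.  Rows may come in any order; the pattern itself indexes the
    table.
    """
    lines = [
        l.split("\t")
        for l in Path(path).read_text().splitlines()
        if l.strip() and not l.startswith("#")
    ]
    header = lines[0]
    if header[-1] != "output":
        raise ValueError("last TSV column must be 'output'")
    regs = tuple(header[:-1])
    k = len(regs)
    outputs = [None] * 2**k
    for row in lines[1:]:
        bits = [int(v) for v in row[:-1]]
        idx = 0
        for b in bits:
            idx = (idx << 1) | b
        outputs[idx] = int(row[-1])
    if any(o is None for o in outputs):
        raise ValueError("truth-table TSV does not cover all regulator rows")
    return TruthTable(regulators=regs, outputs=tuple(outputs))


def read_sif(path: str | Path) -> list[tuple[str, str, str]]:
    """Read a signed edge list: ``source<TAB>+/-<TAB>target`` per line."""
    edges = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        src, sign, dst = line.split("\t")
        if sign not in ("+", "-"):
            raise ValueError(f"sign must be + or -, got {sign!r}")
        edges.append((src, sign, dst))
    return edges


def write_sif(edges: Iterable[tuple[str, str, str]], path: str | Path) -> None:
    Path(path).write_text(
        "\n".join(f"{s}\t{sign}\t{t}" for s, sign, t in edges) + "\n"
    )
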