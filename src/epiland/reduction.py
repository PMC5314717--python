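"""Network reduction: collapse of simple mediator and source nodes.

Large literature-curated interaction graphs are condensed to a core
module by iteratively removing

* **source nodes** — no regulators — together with their out-edges, and
* **simple mediator nodes** — in-degree one and out-degree one — whose
  incoming edge ``(a, m, s1)`` and outgoing edge ``(m, b, s2)`` are
  replaced by the composed edge ``(a, b, s1*s2)``.

The structural variant operates on signed digraphs; the functional
variant substitutes the mediator's Boolean function into its target's
truth table, which preserves fixed points under projection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx

from .network import BooleanNetwork, TruthTable


@dataclass
class SignedDigraph:
    """Signed directed graph; parallel edges of opposite sign are allowed."""

    nodes: list[str]
    edges: list[tuple[str, str, str]]  # (source, target, sign)

    def __post_init__(self) -> None:
        for s, t, sign in self.edges:
            if sign not in ("+", "-"):
                raise ValueError(f"sign must be + or -, got {sign!r}")
            if s not in self.nodes or t not in self.nodes:
                raise ValueError(f"edge ({s},{t}) references unknown node")

    def to_networkx(self) -> nx.MultiDiGraph:
        g = nx.MultiDiGraph()
        g.add_nodes_from(self.nodes)
        for s, t, sign in self.edges:
            g.add_edge(s, t, sign=sign)
        return g

    def ambivalent_pairs(self) -> list[tuple[str, str]]:
        """Node pairs connected by parallel edges of opposite sign."""
        signs: dict[tuple[str, str], set[str]] = {}
        for s, t, sign in self.edges:
            signs.setdefault((s, t), set()).add(sign)
        return sorted(k for k, v in signs.items() if v == {"+", "-"})


def _compose(sign1: str, sign2: str) -> str:
    return "+" if sign1 == sign2 else "-"


def reduce_digraph(g: SignedDigraph, keep: Iterable[str]) -> SignedDigraph:
    """Iteratively remove sources and simple mediators not in ``keep``.

    The result is order-independent: removal is repeated until no
    removable node remains.  Self-loops make a node ineligible (a
    self-regulating node is not a simple mediator).
    """
    keep = set(keep)
    unknown = keep - set(g.nodes)
    if unknown:
        raise ValueError(f"keep names unknown nodes: {sorted(unknown)}")
    nodes = list(g.nodes)
    edges = list(g.edges)
    changed = True
    while changed:
        changed = False
        for node in list(nodes):
            if node in keep:
                continue
            ins = [e for e in edges if e[1] == node]
            outs = [e for e in edges if e[0] == node]
            selfloop = any(e[0] == e[1] == node for e in edges)
            if not ins:  # source
                nodes.remove(node)
                edges = [e for e in edges if e[0] != node]
                changed = True
            elif len(ins) == 1 and len(outs) == 1 and not selfloop:
                (a, _, s1), (_, b, s2) = ins[0], outs[0]
                nodes.remove(node)
                edges = [e for e in edges if node not in (e[0], e[1])]
                edges.append((a, b, _compose(s1, s2)))
                changed = True
    return SignedDigraph(nodes=nodes, edges=edges)


def _substitute(target_tt: TruthTable, mediator: str, med_tt: TruthTable) -> TruthTable:
    """Compose ``mediator``'s function into a truth table that reads it."""
    if mediator not in target_tt.regulators:
        return target_tt
    new_regs: list[str] = [r for r in target_tt.regulators if r != mediator]
    for r in med_tt.regulators:
        if r not in new_regs:
            new_regs.append(r)
    k = len(new_regs)
    outputs = []
    for row in range(2**k):
        env = {
            r: (row >> (k - 1 - j)) & 1 for j, r in enumerate(new_regs)
        }
        env[mediator] = med_tt([env[r] for r in med_tt.regulators])
        outputs.append(target_tt([env[r] for r in target_tt.regulators]))
    return TruthTable(regulators=tuple(new_regs), outputs=tuple(outputs))


def reduce_boolean(net: BooleanNetwork, keep: Iterable[str]) -> BooleanNetwork:
    """Remove constant sources and simple mediators by function composition.

    A node is removable when it is (a) a constant source (no regulators),
    whose value is substituted into every table that reads it, or (b) a
    simple mediator: exactly one regulator (not itself) and exactly one
    downstream reader.  Fixed points of the reduced network are exactly
    the projections of the original's fixed points.
    """
    keep = set(keep)
    unknown = keep - set(net.nodes)
    if unknown:
        raise ValueError(f"keep names unknown nodes: {sorted(unknown)}")
    if net.clamps:
        raise ValueError("reduce_boolean does not support clamped networks")
    nodes = list(net.nodes)
    rules = dict(net.rules)

    def readers(node: str) -> list[str]:
        return [t for t in nodes if t != node and node in rules[t].regulators]

    changed = True
    while changed:
        changed = False
        for node in list(nodes):
            if node in keep:
                continue
            tt = rules[node]
            outs = readers(node)
            if not tt.regulators:  # constant source
                value = tt.outputs[0]
                const = TruthTable(regulators=(node,), outputs=(0, 1))
                for t in outs:
                    rules[t] = _substitute(
                        rules[t], node, TruthTable(regulators=(), outputs=(value,))
                    )
                del const
                nodes.remove(node)
                del rules[node]
                changed = True
            elif (
                len(tt.regulators) == 1
                and node not in tt.regulators
                and len(outs) == 1
            ):
                rules[outs[0]] = _substitute(rules[outs[0]], node, tt)
                nodes.remove(node)
                del rules[node]
                changed = True
    return BooleanNetwork(nodes=tuple(nodes), rules=rules)


def project_state(
    net: BooleanNetwork, state: Sequence[int], reduced: BooleanNetwork
) -> tuple[int, ...]:
    """Restrict a full-network state to the reduced network's nodes."""
    d = net.state_dict(tuple(state))
    return tuple(d[nd] for nd in reduced.nodes)
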