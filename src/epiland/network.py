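"""Deterministic synchronous Boolean-network engine.

A network is a list of named nodes, each with a truth table over its
declared regulators.  States are fixed-length 0/1 vectors aligned to the
node order; every state also has an integer code.  The encoding convention
is fixed throughout the package:

* node 0 is the most significant bit of the state code;
* within a truth table, the first declared regulator is the most
  significant bit of the row index.

Synchronous update, exhaustive attractor enumeration and basin
partitioning are exact: the full ``2**n`` state space is iterated, so the
engine is guarded to ``n <= 24`` nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

MAX_EXHAUSTIVE_NODES = 24


@dataclass(frozen=True)
class TruthTable:
    """Update rule of one node: output column over all regulator rows.

    ``outputs[r]`` is the node's next value when the regulators take the
    bit pattern ``r`` (first regulator = most significant bit).  A node
    with no regulators is a constant and has a single output row.
    """

    regulators: tuple[str, ...]
    outputs: tuple[int, ...]

    def __post_init__(self) -> None:
        k = len(self.regulators)
        if len(self.outputs) != 2**k:
            raise ValueError(
                f"truth table needs {2**k} rows for {k} regulators, "
                f"got {len(self.outputs)}"
            )
        if any(o not in (0, 1) for o in self.outputs):
            raise ValueError("truth-table outputs must be 0 or 1")
        if len(set(self.regulators)) != k:
            raise ValueError("duplicate regulator names")

    def __call__(self, values: Sequence[int]) -> int:
        idx = 0
        for v in values:
            idx = (idx << 1) | int(v)
        return self.outputs[idx]


@dataclass(frozen=True)
class BooleanNetwork:
    """Named nodes with per-node truth tables and optional clamps.

    ``clamps`` maps node names to a fixed 0/1 value; clamped nodes ignore
    their rule entirely.
    """

    nodes: tuple[str, ...]
    rules: Mapping[str, TruthTable]
    clamps: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("node names must be unique")
        missing = set(self.nodes) - set(self.rules)
        if missing:
            raise ValueError(f"nodes without rules: {sorted(missing)}")
        for node in self.nodes:
            for reg in self.rules[node].regulators:
                if reg not in self.nodes:
                    raise ValueError(
                        f"rule for {node!r} names unknown regulator {reg!r}"
                    )
        for node, val in self.clamps.items():
            if node not in self.nodes:
                raise ValueError(f"clamp on unknown node {node!r}")
            if val not in (0, 1):
                raise ValueError("clamp values must be 0 or 1")

    @property
    def n(self) -> int:
        return len(self.nodes)

    def index(self, node: str) -> int:
        return self.nodes.index(node)

    # -- state encoding -------------------------------------------------
    def encode(self, bits: Sequence[int]) -> int:
        if len(bits) != self.n:
            raise ValueError(f"state length {len(bits)} != {self.n} nodes")
        code = 0
        for b in bits:
            code = (code << 1) | int(b)
        return code

    def decode(self, code: int) -> tuple[int, ...]:
        if not 0 <= code < 2**self.n:
            raise ValueError(f"state code {code} out of range")
        return tuple((code >> (self.n - 1 - i)) & 1 for i in range(self.n))

    def state_dict(self, state: Sequence[int] | int) -> dict[str, int]:
        bits = self.decode(state) if isinstance(state, (int, np.integer)) else tuple(state)
        return dict(zip(self.nodes, bits))

    # -- clamping -------------------------------------------------------
    def clamp(self, node: str, value: int) -> "BooleanNetwork":
        """Return a copy with ``node`` held at ``value`` permanently."""
        if node not in self.nodes:
            raise KeyError(f"unknown node {node!r}")
        if value not in (0, 1):
            raise ValueError("clamp value must be 0 or 1")
        clamps = dict(self.clamps)
        clamps[node] = value
        return replace(self, clamps=clamps)

    def clamp_mask(self) -> tuple[int, int]:
        """(mask, values) over state codes for the clamped bits."""
        mask = vals = 0
        for node, v in self.clamps.items():
            bit = 1 << (self.n - 1 - self.index(node))
            mask |= bit
            if v:
                vals |= bit
        return mask, vals

    def consistent_states(self) -> np.ndarray:
        """Codes of all states compatible with the clamps."""
        codes = np.arange(2**self.n, dtype=np.int64)
        mask, vals = self.clamp_mask()
        return codes[(codes & mask) == vals]

    # -- dynamics -------------------------------------------------------
    def successor_table(self) -> np.ndarray:
        """Vector of successor codes for every state code (clamps applied).

        For codes violating a clamp the table still holds the successor of
        the clamp-corrected update, so lookups on the consistent subspace
        are exact.
        """
        if self.n > MAX_EXHAUSTIVE_NODES:
            raise ValueError(
                f"{self.n} nodes exceeds the exhaustive-enumeration guard "
                f"({MAX_EXHAUSTIVE_NODES})"
            )
        codes = np.arange(2**self.n, dtype=np.int64)
        bits = {
            name: (codes >> (self.n - 1 - i)) & 1
            for i, name in enumerate(self.nodes)
        }
        succ = np.zeros_like(codes)
        mask, vals = self.clamp_mask()
        for i, node in enumerate(self.nodes):
            shift = self.n - 1 - i
            if node in self.clamps:
                col = np.full_like(codes, self.clamps[node])
            else:
                tt = self.rules[node]
                k = len(tt.regulators)
                idx = np.zeros_like(codes)
                for j, reg in enumerate(tt.regulators):
                    idx |= bits[reg] << (k - 1 - j)
                col = np.asarray(tt.outputs, dtype=np.int64)[idx]
            succ |= col << shift
        return succ


def synchronous_step(net: BooleanNetwork, state: Sequence[int]) -> tuple[int, ...]:
    """One synchronous update: every node reads the current state at once.

    Raises if the state length mismatches or a clamped node is presented
    with a value other than its clamp.
    """
    bits = tuple(int(b) for b in state)
    if len(bits) != net.n:
        raise ValueError(f"state length {len(bits)} != {net.n} nodes")
    values = dict(zip(net.nodes, bits))
    for node, v in net.clamps.items():
        if values[node] != v:
            raise ValueError(
                f"state sets {node}={values[node]} but it is clamped to {v}"
            )
    out = []
    for node in net.nodes:
        if node in net.clamps:
            out.append(net.clamps[node])
        else:
            tt = net.rules[node]
            out.append(tt([values[r] for r in tt.regulators]))
    return tuple(out)


@dataclass(frozen=True)
class AttractorSet:
    """Enumerated attractors: each a state cycle (fixed point = length 1)."""

    cycles: tuple[tuple[int, ...], ...]  # state codes, in cycle order
    network: BooleanNetwork
    labels: tuple[str, ...] | None = None

    def __len__(self) -> int:
        return len(self.cycles)

    @property
    def fixed_points(self) -> tuple[int, ...]:
        return tuple(c[0] for c in self.cycles if len(c) == 1)

    def all_fixed_points(self) -> bool:
        return all(len(c) == 1 for c in self.cycles)

    def states(self, i: int) -> list[tuple[int, ...]]:
        return [self.network.decode(c) for c in self.cycles[i]]

    def to_frame(self) -> pd.DataFrame:
        """Attractor table: one row per attractor state, per-node columns."""
        rows = []
        for i, cyc in enumerate(self.cycles):
            label = self.labels[i] if self.labels else ""
            for code in cyc:
                row = {"attractor": i, "label": label, "state_code": code}
                row.update(self.network.state_dict(code))
                rows.append(row)
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class BasinPartition:
    """Total map state code -> attractor index, with basin sizes."""

    attractors: AttractorSet
    assignment: Mapping[int, int]
    counts: tuple[int, ...]

    @property
    def total(self) -> int:
        return sum(self.counts)

    @property
    def percentages(self) -> tuple[float, ...]:
        return tuple(100.0 * c / self.total for c in self.counts)

    def to_frame(self) -> pd.DataFrame:
        labels = self.attractors.labels or [""] * len(self.counts)
        return pd.DataFrame(
            {
                "attractor": range(len(self.counts)),
                "label": labels,
                "count": self.counts,
                "percent": [round(p, 2) for p in self.percentages],
            }
        )


def _cycle_from(succ: np.ndarray, start: int) -> tuple[int, ...]:
    """Walk the successor table from ``start`` until the cycle, return it."""
    seen: dict[int, int] = {}
    s = int(start)
    while s not in seen:
        seen[s] = len(seen)
        s = int(succ[s])
    cyc = [s]
    nxt = int(succ[s])
    while nxt != s:
        cyc.append(nxt)
        nxt = int(succ[nxt])
    # canonical rotation: start the cycle at its smallest code
    k = cyc.index(min(cyc))
    return tuple(cyc[k:] + cyc[:k])


def find_attractors(net: BooleanNetwork) -> AttractorSet:
    """Exhaustively enumerate all attractors reachable from any state.

    Every state consistent with the clamps is iterated to its cycle.
    Cycles are reported in canonical rotation (smallest code first) and
    sorted by that code.
    """
    succ = net.successor_table()
    states = net.consistent_states()
    # pointer-doubling: compose the successor map with itself until every
    # state has been pushed >= 2**n steps ahead, i.e. onto its cycle
    f = succ.copy()
    for _ in range(net.n + 1):
        f = f[f]
    on_cycle = np.unique(f[states])
    cycles: dict[int, tuple[int, ...]] = {}
    for code in on_cycle:
        cyc = _cycle_from(succ, int(code))
        cycles[cyc[0]] = cyc
    ordered = tuple(cycles[k] for k in sorted(cycles))
    return AttractorSet(cycles=ordered, network=net)


def basin_partition(
    net: BooleanNetwork, attractors: AttractorSet | None = None
) -> BasinPartition:
    """Assign every consistent state to the attractor its trajectory reaches."""
    if attractors is None:
        attractors = find_attractors(net)
    succ = net.successor_table()
    states = net.consistent_states()
    f = succ.copy()
    for _ in range(net.n + 1):
        f = f[f]
    # f[s] lies on s's cycle; map cycle states to attractor index
    member_to_attr: dict[int, int] = {}
    for i, cyc in enumerate(attractors.cycles):
        for code in cyc:
            member_to_attr[code] = i
    assignment = {int(s): member_to_attr[int(f[s])] for s in states}
    counts = [0] * len(attractors)
    for a in assignment.values():
        counts[a] += 1
    return BasinPartition(
        attractors=attractors, assignment=assignment, counts=tuple(counts)
    )


def clamp(net: BooleanNetwork, node: str, value: int) -> BooleanNetwork:
    """Functional alias for :meth:`BooleanNetwork.clamp`."""
    return net.clamp(node, value)
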