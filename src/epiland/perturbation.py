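"""In-silico mutants (node clamping) and regulatory-logic robustness."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import AttractorSet, BasinPartition, BooleanNetwork, TruthTable, basin_partition, find_attractors


@dataclass(frozen=True)
class PerturbationSpec:
    """Loss (clamp 0) or gain (clamp 1) of function for one node."""

    node: str
    mode: str  # "loss" | "gain"

    def __post_init__(self) -> None:
        if self.mode not in ("loss", "gain"):
            raise ValueError(f"mode must be 'loss' or 'gain', got {self.mode!r}")

    @property
    def value(self) -> int:
        return 0 if self.mode == "loss" else 1


@dataclass(frozen=True)
class MutantReport:
    spec: PerturbationSpec
    attractors: AttractorSet
    basins: BasinPartition

    @property
    def n_attractors(self) -> int:
        return len(self.attractors)


def simulate_mutant(
    net: BooleanNetwork, spec: PerturbationSpec, label_with=None
) -> MutantReport:
    """Clamp the node and enumerate attractors/basins on the clamped subspace.

    ``label_with``: optional callable AttractorSet -> AttractorSet used to
    attach phenotype labels (e.g. ``immortalization.label_attractors``).
    """
    if spec.node not in net.nodes:
        raise KeyError(f"unknown node {spec.node!r}")
    clamped = net.clamp(spec.node, spec.value)
    attrs = find_attractors(clamped)
    if label_with is not None:
        attrs = label_with(attrs)
    basins = basin_partition(clamped, attrs)
    return MutantReport(spec=spec, attractors=attrs, basins=basins)


CANONICAL_PANEL = (
    PerturbationSpec("ESE-2", "loss"),
    PerturbationSpec("ESE-2", "gain"),
    PerturbationSpec("Snai2", "loss"),
    PerturbationSpec("Snai2", "gain"),
    PerturbationSpec("p16", "loss"),
    PerturbationSpec("p16", "gain"),
)


def mutant_panel(
    net: BooleanNetwork, specs=CANONICAL_PANEL, label_with=None
) -> list[MutantReport]:
    """Run the canonical six-mutant panel (ESE-2, Snai2, p16 x loss/gain)."""
    return [simulate_mutant(net, spec, label_with=label_with) for spec in specs]


def _flip_bit(net: BooleanNetwork, node: str, row: int) -> BooleanNetwork:
    tt = net.rules[node]
    outputs = list(tt.outputs)
    outputs[row] = 1 - outputs[row]
    rules = dict(net.rules)
    rules[node] = TruthTable(regulators=tt.regulators, outputs=tuple(outputs))
    return BooleanNetwork(nodes=net.nodes, rules=rules, clamps=net.clamps)


def enumerate_table_bits(net: BooleanNetwork) -> list[tuple[str, int]]:
    """All (node, row) positions a single-bit logic perturbation can hit."""
    return [
        (node, row)
        for node in net.nodes
        for row in range(len(net.rules[node].outputs))
    ]


def logic_robustness(
    net: BooleanNetwork,
    n_perturbations: int | None = None,
    rng: np.random.Generator | None = None,
) -> dict:
    """Fraction of single-bit rule flips that preserve the wild-type attractors.

    Each perturbation permanently flips one truth-table output bit and
    the attractors are recomputed.  With ``n_perturbations=None`` every
    bit is flipped exactly once (exhaustive); otherwise bits are sampled
    uniformly with replacement.  Returns the overall persistence fraction
    (all wild-type fixed points still attractors) and the per-attractor
    persistence fractions.
    """
    wild = find_attractors(net)
    if not wild.all_fixed_points():
        raise ValueError("robustness analysis expects fixed-point attractors")
    targets = wild.fixed_points
    bits = enumerate_table_bits(net)
    if n_perturbations is None:
        chosen = bits
    else:
        if n_perturbations < 1:
            raise ValueError("n_perturbations must be >= 1")
        rng = np.random.default_rng() if rng is None else rng
        chosen = [bits[i] for i in rng.integers(0, len(bits), n_perturbations)]
    kept_all = 0
    kept_each = np.zeros(len(targets), dtype=np.int64)
    for node, row in chosen:
        perturbed = _flip_bit(net, node, row)
        attrs = set(find_attractors(perturbed).fixed_points)
        present = [t in attrs for t in targets]
        kept_each += np.array(present, dtype=np.int64)
        if all(present):
            kept_all += 1
    n = len(chosen)
    return {
        "n_perturbations": n,
        "persistence_all": kept_all / n,
        "persistence_per_attractor": tuple(kept_each / n),
        "attractor_states": targets,
    }
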