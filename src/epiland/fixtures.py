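"""Synthetic-data generators: random Boolean networks and planted chains.

Every pipeline stage is testable without external data: random networks
exercise the deterministic engine and the reduction operator, and
random row-stochastic matrices with a planted dominant path exercise
the landscape layer's ordering recovery.

Generators take an explicit seed and are reproducible: the same spec
and seed always produce the identical object.  Fixture randomness is
kept in its own named stream (a generator seeded from the spec) so that
fixture identity never depends on analysis sampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import BooleanNetwork, TruthTable


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a random Boolean network.

    ``rule_family``: ``"random-table"`` draws output bits uniformly;
    ``"sign-consistent-monotone"`` assigns each regulator a sign
    (activator with probability ``activation_fraction``) and builds a
    random monotone rule consistent with those signs.
    """

    n_nodes: int
    max_in_degree: int = 3
    activation_fraction: float = 0.6
    rule_family: str = "random-table"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 1:
            raise ValueError("n_nodes must be >= 1")
        if self.max_in_degree > self.n_nodes:
            raise ValueError("max_in_degree cannot exceed n_nodes")
        if self.rule_family not in ("random-table", "sign-consistent-monotone"):
            raise ValueError(f"unknown rule family {self.rule_family!r}")
        if not 0.0 <= self.activation_fraction <= 1.0:
            raise ValueError("activation_fraction must lie in [0, 1]")


def _random_monotone_outputs(
    k: int, signs: np.ndarray, rng: np.random.Generator
) -> tuple[int, ...]:
    """Random rule monotone non-decreasing in +regulators, non-increasing in -."""
    # draw a random threshold-ish monotone function: sample weights with the
    # right signs and a threshold, which is always sign-monotone
    w = rng.uniform(0.5, 1.5, size=k) * signs
    theta = rng.uniform(-0.5, 0.5) + w[w > 0].sum() * rng.uniform(0.2, 0.8)
    outputs = []
    for row in range(2**k):
        bits = np.array([(row >> (k - 1 - j)) & 1 for j in range(k)])
        outputs.append(int(w @ bits >= theta))
    if all(o == outputs[0] for o in outputs) and k > 0:
        # avoid constant rules: force the all-activators-on row to 1 and
        # the all-activators-off row to 0 where signs permit
        hi = sum(1 << (k - 1 - j) for j in range(k) if signs[j] > 0)
        lo = sum(1 << (k - 1 - j) for j in range(k) if signs[j] < 0)
        outputs[hi] = 1
        outputs[lo] = 0
    return tuple(outputs)


def random_boolean_network(spec: FixtureSpec) -> BooleanNetwork:
    """Sample a random Boolean network per the fixture spec."""
    rng = np.random.default_rng(spec.seed)
    names = tuple(f"n{i}" for i in range(spec.n_nodes))
    rules = {}
    for i, name in enumerate(names):
        k = int(rng.integers(0, spec.max_in_degree + 1))
        regs = tuple(
            names[j] for j in sorted(rng.choice(spec.n_nodes, size=k, replace=False))
        )
        if spec.rule_family == "random-table":
            outputs = tuple(int(b) for b in rng.integers(0, 2, size=2**k))
        else:
            signs = np.where(
                rng.random(k) < spec.activation_fraction, 1.0, -1.0
            )
            outputs = _random_monotone_outputs(k, signs, rng)
        rules[name] = TruthTable(regulators=regs, outputs=outputs)
    return BooleanNetwork(nodes=names, rules=rules)


def random_chain(
    n_attractors: int, flow_strength: float, seed: int = 0
) -> tuple[np.ndarray, tuple[int, ...]]:
    """Row-stochastic matrix with a planted dominant path 0 -> 1 -> ... -> k-1.

    ``flow_strength`` in (0, 1) sets how strongly each super-diagonal
    transition dominates the reverse one.  Returns (pi, planted_path).
    """
    if n_attractors < 2:
        raise ValueError("need at least 2 attractors")
    if not 0.0 < flow_strength < 1.0:
        raise ValueError("flow_strength must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    k = n_attractors
    pi = np.zeros((k, k))
    base = 0.05 * (1.0 - flow_strength)
    for i in range(k):
        pi[i] = rng.uniform(0.0, base, size=k)
        if i + 1 < k:
            pi[i, i + 1] = flow_strength * 0.2
        if i - 1 >= 0:
            pi[i, i - 1] = flow_strength * 0.2 * (1.0 - flow_strength)
        pi[i, i] = 0.0
        pi[i, i] = max(1.0 - pi[i].sum(), 0.05)
        pi[i] /= pi[i].sum()
    return pi, tuple(range(k))
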