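"""Stochastic dynamics and epigenetic-landscape characterisation.

The deterministic network is extended with the *stochasticity-in-nodes*
(SIN) noise model: at every step each non-clamped node disobeys its
update rule independently with probability ``xi``.  Noise-induced hops
between basins define an attractor-level Markov chain Π with entries
``pi[i, j] = P(A_{t+1} = j | A_t = i)``, estimated by simulating one
noisy step from every state of every basin.  From Π the module derives

* the temporal evolution of the attractor occupation probability,
  ``p(t+1)_j = sum_i p(t)_i pi[i, j]``,
* mean first-passage times (MFPT) between attractors, by sampled paths
  and by the exact fundamental-matrix linear solve,
* net transition rates ``d[i, j] = 1/MFPT[i, j] - 1/MFPT[j, i]`` and the
  consistent global ordering: the attractor permutation along which
  every consecutive net rate is positive.

MFPT is a proxy for the height of the epigenetic-landscape barrier
between two phenotypes; a positive net rate marks the direction in which
probability preferentially flows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .network import BasinPartition, BooleanNetwork, synchronous_step

MAX_EXACT_NODES = 12


@dataclass(frozen=True)
class NoiseModel:
    """Per-node, per-step disobedience probability."""

    xi: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.xi <= 1.0:
            raise ValueError(f"xi must lie in [0, 1], got {self.xi}")


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic attractor-level transition matrix."""

    pi: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        pi = np.asarray(self.pi, dtype=float)
        if pi.ndim != 2 or pi.shape[0] != pi.shape[1]:
            raise ValueError("pi must be square")
        if (pi < 0).any():
            raise ValueError("pi entries must be non-negative")
        if not np.allclose(pi.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("pi rows must sum to 1")

    @property
    def n(self) -> int:
        return self.pi.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pi, index=self.labels, columns=self.labels)


@dataclass(frozen=True)
class LandscapeSummary:
    """MFPT matrix, antisymmetric net-rate matrix and global ordering."""

    mfpt: np.ndarray
    net_rates: np.ndarray
    ordering: tuple[int, ...] | None
    labels: tuple[str, ...]

    def ordering_labels(self) -> tuple[str, ...] | None:
        if self.ordering is None:
            return None
        return tuple(self.labels[i] for i in self.ordering)


def stochastic_step(
    net: BooleanNetwork,
    state: Sequence[int],
    noise: NoiseModel,
    rng: np.random.Generator,
) -> tuple[int, ...]:
    """Deterministic successor, then independent per-node disobedience.

    Clamped nodes never flip.
    """
    nxt = list(synchronous_step(net, state))
    flips = rng.random(len(nxt)) < noise.xi
    for i, node in enumerate(net.nodes):
        if flips[i] and node not in net.clamps:
            nxt[i] = 1 - nxt[i]
    return tuple(nxt)


def exact_one_step_operator(net: BooleanNetwork, noise: NoiseModel) -> np.ndarray:
    """Full-state-space SIN transition matrix.

    ``P[s, s'] = xi**h * (1-xi)**(n-h)`` with ``h`` the Hamming distance
    between ``s'`` and the deterministic successor of ``s`` (clamped bits
    excluded from flipping).  Rows over the clamp-consistent subspace sum
    to one.
    """
    if net.n > MAX_EXACT_NODES:
        raise ValueError(
            f"{net.n} nodes exceeds the exact-operator guard ({MAX_EXACT_NODES})"
        )
    xi = noise.xi
    size = 2**net.n
    succ = net.successor_table()
    states = net.consistent_states()
    mask, _ = net.clamp_mask()
    free = net.n - bin(mask).count("1")
    P = np.zeros((size, size))
    diff = states[None, :] ^ succ[states][:, None]  # (from, to) XOR
    h = np.array(
        [[bin(int(x)).count("1") for x in row] for row in diff]
    )
    probs = xi**h * (1 - xi) ** (free - h)
    P[np.ix_(states, states)] = probs
    return P


def aggregate_by_basins(P: np.ndarray, basins: BasinPartition) -> TransitionMatrix:
    """Exact attractor-level chain: pool the operator's rows by basin.

    Each basin state carries equal weight; entries are the pooled
    probability of landing anywhere in the target basin.
    """
    k = len(basins.attractors)
    labels = basins.attractors.labels or tuple(str(i) for i in range(k))
    states = sorted(basins.assignment)
    attr = np.array([basins.assignment[s] for s in states])
    sub = P[np.ix_(states, states)]
    pi = np.zeros((k, k))
    for i in range(k):
        rows = sub[attr == i]
        for j in range(k):
            pi[i, j] = rows[:, attr == j].sum()
        pi[i] /= rows.shape[0]
    return TransitionMatrix(pi=pi, labels=tuple(labels))


def estimate_transition_matrix(
    net: BooleanNetwork,
    noise: NoiseModel,
    basins: BasinPartition,
    reps: int = 10_000,
    rng: np.random.Generator | None = None,
) -> TransitionMatrix:
    """Monte-Carlo Π: ``reps`` noisy one-step transitions from every state.

    Counts are pooled over all states of the source basin (equal weight
    per state) and normalised row-wise.  A noisy step is applied to the
    raw basin state — no deterministic relaxation in between.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    net_ = basins.attractors.network
    succ = net_.successor_table()
    states = np.array(sorted(basins.assignment))
    attr = np.array([basins.assignment[int(s)] for s in states])
    k = len(basins.attractors)
    labels = basins.attractors.labels or tuple(str(i) for i in range(k))
    mask, vals = net_.clamp_mask()
    free_bits = np.array(
        [1 << (net_.n - 1 - i) for i, nd in enumerate(net_.nodes) if nd not in net_.clamps],
        dtype=np.int64,
    )
    # state -> basin lookup over the full code range
    lookup = np.full(2**net_.n, -1, dtype=np.int64)
    lookup[states] = attr
    counts = np.zeros((k, k), dtype=np.int64)
    det = succ[states]
    for chunk in np.array_split(np.arange(reps), max(1, reps // 500)):
        c = len(chunk)
        flips = rng.random((len(states), c, len(free_bits))) < noise.xi
        noisy = np.broadcast_to(det[:, None], (len(states), c)).copy()
        for b, bit in enumerate(free_bits):
            noisy ^= np.where(flips[:, :, b], bit, 0)
        dest = lookup[noisy]
        for i in range(k):
            rows = dest[attr == i].ravel()
            counts[i] += np.bincount(rows, minlength=k)
    pi = counts / counts.sum(axis=1, keepdims=True)
    return TransitionMatrix(pi=pi, labels=tuple(labels))


def iterate_distribution(
    tm: TransitionMatrix, p0: Sequence[float], steps: int
) -> np.ndarray:
    """Evolve the attractor distribution: returns array of shape (steps+1, k).

    Orientation: Π is row-stochastic, so the update is
    ``p(t+1) = p(t) @ pi`` (equivalently left-multiplication by Π
    transposed).
    """
    p = np.asarray(p0, dtype=float)
    if p.shape != (tm.n,):
        raise ValueError("p0 length must match the number of attractors")
    if not np.isclose(p.sum(), 1.0):
        raise ValueError("p0 must sum to 1")
    out = np.empty((steps + 1, tm.n))
    out[0] = p
    for t in range(steps):
        p = p @ tm.pi
        out[t + 1] = p
    return out


def temporal_attainment(
    tm: TransitionMatrix, p0: Sequence[float], steps: int
) -> tuple[tuple[int, ...], np.ndarray, np.ndarray]:
    """Most-probable-attractor trace and first-attainment sequence.

    Returns ``(sequence, curves, argmax_trace)``: the order in which
    distinct attractors first become the most probable one (ties broken
    toward the incumbent), the full probability curves (steps+1, k), and
    the per-step argmax attractor index.
    """
    curves = iterate_distribution(tm, p0, steps)
    seq: list[int] = []
    trace = np.empty(steps + 1, dtype=int)
    current = -1
    for t, p in enumerate(curves):
        best = int(np.argmax(p))
        if current >= 0 and np.isclose(p[best], p[current]):
            best = current  # incumbent keeps the lead on ties
        trace[t] = best
        if best != current:
            if best not in seq:
                seq.append(best)
            current = best
    return tuple(seq), curves, trace


def mfpt_analytic(tm: TransitionMatrix) -> np.ndarray:
    """Exact MFPT via the fundamental-matrix linear solve.

    For target ``j``, solve ``(I - Q) m = 1`` where ``Q`` deletes row and
    column ``j``.  Unreachable pairs yield ``inf``.
    """
    k = tm.n
    out = np.zeros((k, k))
    for j in range(k):
        idx = [i for i in range(k) if i != j]
        Q = tm.pi[np.ix_(idx, idx)]
        try:
            m = np.linalg.solve(np.eye(k - 1) - Q, np.ones(k - 1))
        except np.linalg.LinAlgError:
            m = np.full(k - 1, np.inf)
        if (m < 0).any():  # singular-ish: unreachable target
            m = np.full(k - 1, np.inf)
        for row, i in enumerate(idx):
            out[i, j] = m[row]
    return out


def mfpt_simulated(
    tm: TransitionMatrix,
    n_paths: int = 10_000,
    max_steps: int = 100_000,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """MFPT from sampled chains; returns (mfpt, censored_counts).

    For each ordered pair (i, j), ``n_paths`` chains start with all mass
    on attractor i; the first-hit step of j is averaged.  Paths that do
    not reach j within ``max_steps`` are censored (excluded from the
    mean, counted separately); an all-censored pair yields ``inf``.
    """
    rng = np.random.default_rng() if rng is None else rng
    k = tm.n
    cum = np.cumsum(tm.pi, axis=1)
    mfpt = np.zeros((k, k))
    censored = np.zeros((k, k), dtype=np.int64)
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            state = np.full(n_paths, i)
            hit = np.zeros(n_paths, dtype=np.int64)
            active = np.ones(n_paths, dtype=bool)
            for step in range(1, max_steps + 1):
                if not active.any():
                    break
                u = rng.random(active.sum())
                state[active] = (
                    u[:, None] > cum[state[active]]
                ).sum(axis=1)
                arrived = active & (state == j)
                hit[arrived] = step
                active &= ~arrived
            censored[i, j] = int(active.sum())
            done = hit[~active]
            mfpt[i, j] = done.mean() if done.size else np.inf
    return mfpt, censored


def net_rates_and_ordering(
    mfpt: np.ndarray, labels: Sequence[str] | None = None
) -> LandscapeSummary:
    """Net-rate matrix and exhaustive search for a consistent ordering.

    ``d[i, j] = 1/MFPT[i, j] - 1/MFPT[j, i]`` is antisymmetric by
    construction.  The ordering is the permutation (if any) in which
    every consecutive net rate is strictly positive; ``None`` when no
    permutation qualifies.
    """
    from itertools import permutations

    mfpt = np.asarray(mfpt, dtype=float)
    k = mfpt.shape[0]
    labels = tuple(labels) if labels is not None else tuple(str(i) for i in range(k))
    with np.errstate(divide="ignore"):
        inv = np.where(mfpt > 0, 1.0 / mfpt, 0.0)
    np.fill_diagonal(inv, 0.0)
    d = inv - inv.T
    ordering = None
    for perm in permutations(range(k)):
        if all(d[perm[a], perm[a + 1]] > 0 for a in range(k - 1)):
            ordering = perm
            break
    return LandscapeSummary(mfpt=mfpt, net_rates=d, ordering=ordering, labels=labels)
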