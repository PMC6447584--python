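"""Deterministic linear-threshold cascade engine.

The dynamics are the fixed-threshold linear threshold model: an inactive node
activates once its number of active neighbors reaches its integer resistance.
Propagation is level-synchronous (frontier BFS); because activation is
monotone and irreversible the fixed point is independent of update order, and
levels provide the natural "sphere of influence" truncation used by the
CI-TM-style scorer.

Nodes with resistance 0 (supplied threshold phi = 0 on a connected node)
activate in the first evaluation of any cascade state, even with no active
neighbor — i.e. immediately when a :class:`CascadeState` is created.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from ._kernels import NO_LIMIT, UNREACHABLE
from .network import Network


class ContractViolation(RuntimeError):
    """Raised when an operation's calling contract is broken (e.g. seeding
    an already-active node)."""


@dataclass(frozen=True)
class CascadeResult:
    """Fixed point of one cascade run: the activated node set (seeds and free
    r=0 activations included), its size f(X), and the number of propagation
    levels used."""

    activated: np.ndarray
    spread_size: int
    steps: int


class CascadeState:
    """Mutable spread state supporting incremental seeding.

    Invariants: ``active[i]`` implies ``residual[i] == 0``; ``inact_deg[i]``
    equals the number of inactive neighbors of ``i``; ``activated_count``
    equals the number of active nodes.
    """

    __slots__ = ("net", "active", "residual", "inact_deg", "unreachable",
                 "activated_count", "_stamp", "_queue", "_token")

    def __init__(self, net: Network, active, residual, inact_deg, unreachable,
                 activated_count: int) -> None:
        self.net = net
        self.active = active
        self.residual = residual
        self.inact_deg = inact_deg
        self.unreachable = unreachable
        self.activated_count = activated_count
        self._stamp = np.zeros(net.n_nodes, np.int64)
        self._queue = np.empty(net.n_nodes, np.int64)
        self._token = 0

    @classmethod
    def fresh(cls, net: Network, resist: np.ndarray) -> "CascadeState":
        """Initial state for a resistance vector; r=0 nodes activate at once."""
        resist = np.asarray(resist, dtype=np.int64)
        if resist.shape != (net.n_nodes,):
            raise ValueError("resistance length must equal the number of nodes")
        residual = resist.copy()
        active = np.zeros(net.n_nodes, np.bool_)
        inact_deg = net.degree.copy()
        unreachable = resist >= UNREACHABLE
        state = cls(net, active, residual, inact_deg, unreachable, 0)
        free = np.flatnonzero((resist <= 0) & ~unreachable)
        if free.size:
            out = np.empty(net.n_nodes, np.int64)
            total, _ = _kernels.add_seeds(net.indptr, net.indices, active,
                                          residual, inact_deg, free, out, NO_LIMIT)
            state.activated_count = int(total)
        return state

    def copy(self) -> "CascadeState":
        return CascadeState(self.net, self.active.copy(), self.residual.copy(),
                            self.inact_deg.copy(), self.unreachable,
                            self.activated_count)

    @property
    def inactive_count(self) -> int:
        return self.net.n_nodes - self.activated_count

    def _validate_seeds(self, seeds: np.ndarray) -> None:
        if seeds.size and (seeds.min() < 0 or seeds.max() >= self.net.n_nodes):
            raise ValueError("unknown node id in seeds")
        if np.any(self.active[seeds]):
            raise ContractViolation("seeding an already-active node")

    def add_seeds(self, seeds, max_levels: int | None = None) -> np.ndarray:
        """Seed one or more inactive nodes and cascade to the fixed point
        (or ``max_levels``).  Returns the newly activated nodes, seeds first.

        The end state is identical to re-running the full cascade with the
        enlarged seed set on the original graph (permutation invariance of
        the fixed point).
        """
        seeds = np.atleast_1d(np.asarray(seeds, dtype=np.int64))
        if np.unique(seeds).size != seeds.size:
            raise ValueError("duplicate seeds")
        self._validate_seeds(seeds)
        out = np.empty(self.net.n_nodes, np.int64)
        lim = NO_LIMIT if max_levels is None else max_levels
        total, _ = _kernels.add_seeds(self.net.indptr, self.net.indices,
                                      self.active, self.residual,
                                      self.inact_deg, seeds, out, lim)
        self.activated_count += int(total)
        return out[:total].copy()

    def add_seed_incremental(self, seed: int) -> int:
        """Seed a single inactive node; returns the marginal spread."""
        return int(self.add_seeds(int(seed)).size)


def run_cascade(net: Network, resist: np.ndarray, seeds,
                max_levels: int | None = None) -> CascadeResult:
    """Run one cascade from a seed set on a fresh state.

    Seeds that coincide with freely-activated r=0 nodes are ignored (they are
    active either way).  ``max_levels=None`` means unbounded; any value at or
    above N is equivalent.
    """
    state = CascadeState.fresh(net, resist)
    seeds = np.unique(np.atleast_1d(np.asarray(seeds, dtype=np.int64))) \
        if np.size(seeds) else np.empty(0, np.int64)
    if seeds.size and (seeds.min() < 0 or seeds.max() >= net.n_nodes):
        raise ValueError("unknown node id in seeds")
    seeds = seeds[~state.active[seeds]]
    steps = 0
    if seeds.size:
        out = np.empty(net.n_nodes, np.int64)
        lim = NO_LIMIT if max_levels is None else max_levels
        total, steps = _kernels.add_seeds(net.indptr, net.indices, state.active,
                                          state.residual, state.inact_deg,
                                          seeds, out, lim)
        state.activated_count += int(total)
    return CascadeResult(activated=np.flatnonzero(state.active),
                         spread_size=state.activated_count, steps=int(steps))


def total_resistance(state: CascadeState) -> int:
    """Sum of residual resistances over inactive reachable nodes.

    Unreachable (isolated) nodes are excluded; their count is available as
    ``unreachable_inactive_count``.  Zero iff every reachable node is active.
    """
    mask = ~state.active & ~state.unreachable
    return int(state.residual[mask].sum())


def unreachable_inactive_count(state: CascadeState) -> int:
    return int(np.count_nonzero(~state.active & state.unreachable))
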