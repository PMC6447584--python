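"""Group Performance Index: scoring nodes by the size of random winning teams.

A trial draws uniformly random inactive nodes one at a time (cascading after
each) until the spread covers the remaining goal; the GPI of a node is the
mean size of the trial teams it belonged to.  Small GPI marks nodes that
appear in efficient teams — and, because trials only ever draw inactive
nodes, nodes that diffusion does not activate for free.  Selection proceeds
in batches of the ceil(s*N) best-ranked (smallest-GPI) nodes, re-running the
trials on the updated state between batches.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _kernels
from ._kernels import NO_LIMIT
from .cascade import CascadeState
from .network import Network
from .strategies import SeedTrajectory


@dataclass(frozen=True)
class GPIConfig:
    """Control parameters: batch granularity ``s`` (batch size ceil(s*N)),
    number of random trials ``v`` per batch, and the spread goal ``s_goal``
    as a fraction of N.  Defaults follow the reference study conditions."""

    s: float = 1e-3
    v: int = 100_000
    s_goal: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.s:
            raise ValueError("s must be positive")
        if self.v < 0:
            raise ValueError("v must be nonnegative")
        if not 0.0 < self.s_goal <= 1.0:
            raise ValueError("s_goal must lie in (0, 1]")


@dataclass
class GPITrialLog:
    """Aggregated trial statistics: per-node membership counts, per-node
    size-weighted sums, and the size of every trial team."""

    counts: np.ndarray
    size_sums: np.ndarray
    trial_sizes: np.ndarray

    @property
    def n_trials(self) -> int:
        return int(self.trial_sizes.size)


def run_random_trials(state: CascadeState, remaining_goal: int, v: int,
                      rng_seed: int, max_levels: int | None = None) -> GPITrialLog:
    """Run ``v`` independent random-team trials against the current state.

    Trials operate on disposable copies; the outer state is never mutated.
    ``remaining_goal <= 0`` or ``v == 0`` yields an empty (all-zero) log.
    """
    n = state.net.n_nodes
    if remaining_goal <= 0 or v <= 0:
        return GPITrialLog(np.zeros(n, np.int64), np.zeros(n, np.int64),
                           np.empty(0, np.int64))
    if state.inactive_count == 0:
        raise ValueError("no inactive nodes left to sample")
    net = state.net
    lim = NO_LIMIT if max_levels is None else max_levels
    counts, size_sums, trial_sizes = _kernels.gpi_trials(
        net.indptr, net.indices, state.active, state.residual, state.inact_deg,
        int(remaining_goal), int(v), int(rng_seed) % 2147483647, lim)
    return GPITrialLog(counts, size_sums, trial_sizes)


def gpi_rank(log: GPITrialLog, rng_seed: int = 0):
    """Rank sampled nodes by ascending GPI (mean team size; smaller is
    better), ties broken by the seeded RNG.  Nodes never drawn in any trial
    are excluded; an all-zero log yields an empty ranking."""
    sampled = np.flatnonzero(log.counts > 0)
    if sampled.size == 0:
        return np.empty(0, np.int64), np.empty(0, np.float64)
    scores = log.size_sums[sampled] / log.counts[sampled]
    tie = np.random.default_rng(rng_seed).random(sampled.size)
    order = np.lexsort((tie, scores))
    return sampled[order], scores[order]


def _trial_seed(rng_seed: int, step: int) -> int:
    # Per-(run, outer-step) base; the kernel adds the trial index, so earlier
    # trials are reproduced exactly when v changes.
    return (int(rng_seed) * 1_000_003 + step * 7_919) % 2_147_483_647


def gpi_select(net: Network, resist: np.ndarray, config: GPIConfig = GPIConfig(),
               rng_seed: int = 0, budget: int | None = None,
               max_levels: int | None = None) -> SeedTrajectory:
    """Batch seed selection by GPI ranking until spread >= s_goal * N.

    Each outer step runs ``config.v`` trials on the current state, ranks, and
    seeds the batch of ceil(s*N) best-ranked nodes one by one.  Batch members
    activated by an earlier seed of the same batch are excluded from the
    initiator set (not replaced); seeding stops as soon as the goal is met,
    so the final |Y|/N is the trajectory's goal-crossing fraction.  Fully
    reproducible for a fixed seed.
    """
    state = CascadeState.fresh(net, resist)
    n = net.n_nodes
    goal = math.ceil(config.s_goal * n)
    cap = n if budget is None else min(int(budget), n)
    batch_size = max(1, math.ceil(config.s * n))
    seeds: list[int] = []
    spreads: list[int] = []
    batches: list[int] = []
    initial = state.activated_count
    step = 0
    while state.activated_count < goal and len(seeds) < cap:
        if state.inactive_count == 0:
            break
        remaining = goal - state.activated_count
        base = _trial_seed(rng_seed, step)
        log = run_random_trials(state, remaining, config.v, base,
                                max_levels=max_levels)
        ranked, _ = gpi_rank(log, rng_seed=base + 1)
        if ranked.size < batch_size:
            # Never-sampled inactive nodes are worst-ranked: they are the
            # nodes diffusion activates for free.  Shuffled for tie fairness.
            inact = np.flatnonzero(~state.active)
            extra = inact[~np.isin(inact, ranked)]
            np.random.default_rng(base + 2).shuffle(extra)
            ranked = np.concatenate([ranked, extra])
        batch = ranked[:batch_size]
        batches.append(len(seeds))
        for node in batch:
            if state.activated_count >= goal or len(seeds) >= cap:
                break
            if state.active[node]:
                continue  # activated by an earlier seed in this batch
            state.add_seeds(int(node))
            seeds.append(int(node))
            spreads.append(state.activated_count)
        step += 1
    return SeedTrajectory("gpi", n, np.array(seeds, np.int64),
                          np.array(spreads, np.int64), initial, batches=batches)
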