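"""Sequential seed selection on the dynamic inactive subgraph.

Every heuristic scores inactive nodes from the *current* cascade state (all
quantities dynamic), seeds the argmax, updates the state and rescores.  The
score formulas have bounded dependence radius (2 hops for thres/deg/res/DD/
ID/BI, L+1 for the CI-TM-style scorer), so after each seeding event only
inactive nodes within that radius of any newly activated node are rescored;
a full-rescan mode is kept as the exactness oracle.

Heuristics (r = dynamic resistance, k_out = dynamic out-degree, the sum runs
over inactive neighbors j with r_j = 1, i.e. subcritical nodes):

=========  ==================================================================
thres      r_i / k_i (original degree; equals phi_i before any spread)
deg        k_i^out
res        r_i
dd         r_i + k_i^out                     (direct drop of total resistance)
id         dd + sum_j (k_j^out - 1)          (adds the indirect first-shell drop)
bi         a*r_i + b*k_i^out + c*sum_j (k_j^out - 1),  a + b + c = 1
citm(L)    k_i^out plus (k^out - 1) summed over nodes reachable through
           chains of subcritical nodes within L levels
=========  ==================================================================

Corner identities: bi(1,0,0)=res, bi(0,1,0)=deg, bi(1/2,1/2,0)=dd/2,
bi(1/3,1/3,1/3)=id/3, bi(0,1/2,1/2)=citm(L=1)/2, and citm(L=1) = id - r.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from ._kernels import NO_LIMIT
from .cascade import CascadeState, ContractViolation
from .network import Network

_CODES = {"thres": _kernels.THRES, "deg": _kernels.DEG, "res": _kernels.RES,
          "dd": _kernels.DD, "id": _kernels.ID, "bi": _kernels.BI,
          "citm": _kernels.CITM}

SCORE_STRATEGIES = tuple(_CODES)


@dataclass(frozen=True)
class BIWeights:
    """Balanced-Index weights (a, b, c) on resistance, out-degree and the
    subcritical-neighbor term; must be nonnegative and sum to 1."""

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) < 0:
            raise ValueError("BI weights must be nonnegative")
        if abs(self.a + self.b + self.c - 1.0) > 1e-9:
            raise ValueError("BI weights must sum to 1")


@dataclass
class SeedTrajectory:
    """Ordered seed list with the cumulative cascade size after each seed.

    ``initial_spread`` is the free activation before any seed (r=0 nodes);
    ``batches`` (GPI only) holds the seed index at which each batch starts.
    """

    strategy: str
    n_nodes: int
    seeds: np.ndarray
    cumulative_spread: np.ndarray
    initial_spread: int = 0
    batches: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.seeds = np.asarray(self.seeds, dtype=np.int64)
        self.cumulative_spread = np.asarray(self.cumulative_spread, dtype=np.int64)
        if self.seeds.size != self.cumulative_spread.size:
            raise ValueError("seeds and cumulative_spread must align")
        if np.any(np.diff(self.cumulative_spread) < 0):
            raise ValueError("cumulative spread must be nondecreasing")

    @property
    def p(self) -> np.ndarray:
        """Initiator fractions m/N after each seed."""
        return np.arange(1, self.seeds.size + 1) / self.n_nodes

    @property
    def s_eq(self) -> np.ndarray:
        """Cascade-size fractions after each seed."""
        return self.cumulative_spread / self.n_nodes

    def spread_at(self, n_seeds: int) -> int:
        """Cumulative spread after the first ``n_seeds`` seeds (saturating
        beyond the end of the trajectory)."""
        if n_seeds <= 0 or self.seeds.size == 0:
            return self.initial_spread if n_seeds <= 0 else \
                (int(self.cumulative_spread[-1]) if self.seeds.size else self.initial_spread)
        idx = min(n_seeds, self.seeds.size) - 1
        return int(self.cumulative_spread[idx])

    def p_c(self, s_goal: float) -> float | None:
        """Smallest recorded initiator fraction reaching spread s_goal * N,
        or None if the trajectory never got there."""
        goal = math.ceil(s_goal * self.n_nodes)
        if self.initial_spread >= goal:
            return 0.0
        hits = np.flatnonzero(self.cumulative_spread >= goal)
        return float((hits[0] + 1) / self.n_nodes) if hits.size else None

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "rank": np.arange(1, self.seeds.size + 1),
            "node_id": self.seeds,
            "cumulative_spread": self.cumulative_spread,
            "p": self.p,
            "s_eq": self.s_eq,
        })


def _resolve_weights(strategy: str, weights) -> tuple[float, float, float]:
    if strategy != "bi":
        return 0.0, 0.0, 0.0
    if weights is None:
        raise ValueError("the bi strategy requires weights")
    if not isinstance(weights, BIWeights):
        weights = BIWeights(*weights)
    return weights.a, weights.b, weights.c


def _score(state: CascadeState, nodes: np.ndarray, code: int,
           a: float, b: float, c: float, L: int) -> np.ndarray:
    net = state.net
    scores, state._token = _kernels.score_nodes(
        net.indptr, net.indices, state.active, state.residual, state.inact_deg,
        net.degree, nodes, code, a, b, c, L, state._stamp, state._queue,
        state._token)
    return scores


def node_score(state: CascadeState, node: int, strategy: str, *,
               weights=None, L: int = 6) -> float:
    """Score a single inactive node under one heuristic on the current state."""
    if strategy not in _CODES:
        raise ValueError(f"unknown strategy {strategy!r}")
    if state.active[node]:
        raise ContractViolation("scoring an active node")
    a, b, c = _resolve_weights(strategy, weights)
    nodes = np.array([node], dtype=np.int64)
    return float(_score(state, nodes, _CODES[strategy], a, b, c, L)[0])


def _pick_max(scores: np.ndarray, rng: np.random.Generator) -> int:
    best = scores.max()
    ties = np.flatnonzero(scores == best)
    if ties.size == 1:
        return int(ties[0])
    return int(ties[rng.integers(ties.size)])


def sequential_select(net: Network, resist: np.ndarray, strategy: str, *,
                      weights=None, L: int = 6, budget: int | None = None,
                      s_goal: float | None = None, rng_seed: int = 0,
                      rescore: str = "local") -> SeedTrajectory:
    """Greedily seed the highest-scoring inactive node until the seed budget
    is exhausted or the cumulative spread reaches ``s_goal * N``.

    Ties are broken uniformly at random with the run's seeded RNG.
    ``strategy="random"`` is the uniform baseline.  ``rescore`` selects the
    local (radius-bounded) or full-rescan update; both give identical
    trajectories and the agreement is asserted in the test suite.
    """
    if strategy != "random" and strategy not in _CODES:
        raise ValueError(f"unknown strategy {strategy!r}")
    if budget is None and s_goal is None:
        raise ValueError("provide a seed budget and/or an s_goal")
    if rescore not in ("local", "full"):
        raise ValueError("rescore must be 'local' or 'full'")
    if L < 1:
        raise ValueError("L must be >= 1")
    a, b, c = _resolve_weights(strategy, weights)
    code = _CODES.get(strategy, -1)

    state = CascadeState.fresh(net, resist)
    n = net.n_nodes
    goal = None if s_goal is None else math.ceil(s_goal * n)
    cap = n if budget is None else min(int(budget), n)
    rng = np.random.default_rng(rng_seed)

    scores = np.full(n, -np.inf)
    if code >= 0:
        inact = np.flatnonzero(~state.active)
        if inact.size:
            scores[inact] = _score(state, inact, code, a, b, c, L)

    seeds: list[int] = []
    spreads: list[int] = []
    initial = state.activated_count
    radius = (L + 1) if code == _kernels.CITM else 2
    while len(seeds) < cap and (goal is None or state.activated_count < goal):
        if state.inactive_count == 0:
            break
        if code < 0:
            inact = np.flatnonzero(~state.active)
            node = int(inact[rng.integers(inact.size)])
        else:
            node = _pick_max(scores, rng)
        newly = state.add_seeds(node)
        scores[newly] = -np.inf
        seeds.append(node)
        spreads.append(state.activated_count)
        if code >= 0 and state.inactive_count:
            if rescore == "local":
                upd, state._token = _kernels.k_hop_inactive(
                    net.indptr, net.indices, state.active, newly, radius,
                    state._stamp, state._queue, state._token)
            else:
                upd = np.flatnonzero(~state.active)
            if upd.size:
                scores[upd] = _score(state, upd, code, a, b, c, L)
    name = strategy if strategy != "bi" else f"bi({a:g},{b:g},{c:g})"
    return SeedTrajectory(name, n, np.array(seeds, np.int64),
                          np.array(spreads, np.int64), initial)


def greedy_select(net: Network, resist: np.ndarray, *, budget: int | None = None,
                  s_goal: float | None = None,
                  evaluation_levels: int | None = None,
                  rng_seed: int = 0) -> SeedTrajectory:
    """Exact greedy: at each step seed the inactive node with the largest
    marginal cascade size (optionally evaluated with an L-level truncation;
    the applied cascade is always full).  Ties broken by the seeded RNG."""
    if budget is None and s_goal is None:
        raise ValueError("provide a seed budget and/or an s_goal")
    state = CascadeState.fresh(net, resist)
    n = net.n_nodes
    goal = None if s_goal is None else math.ceil(s_goal * n)
    cap = n if budget is None else min(int(budget), n)
    lim = NO_LIMIT if evaluation_levels is None else evaluation_levels
    rng = np.random.default_rng(rng_seed)
    seeds: list[int] = []
    spreads: list[int] = []
    initial = state.activated_count
    while len(seeds) < cap and (goal is None or state.activated_count < goal):
        candidates = np.flatnonzero(~state.active)
        if candidates.size == 0:
            break
        gains = _kernels.single_seed_gains(net.indptr, net.indices, state.active,
                                           state.residual, state.inact_deg,
                                           candidates, lim)
        node = int(candidates[_pick_max(gains.astype(np.float64), rng)])
        state.add_seeds(node)
        seeds.append(node)
        spreads.append(state.activated_count)
    return SeedTrajectory("greedy", n, np.array(seeds, np.int64),
                          np.array(spreads, np.int64), initial)
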