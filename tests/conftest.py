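"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from ltmax import Network, UNREACHABLE, compute_resistances


def naive_cascade(net: Network, resist, seeds) -> set:
    """Order-free fixed-point oracle for the threshold dynamics.

    Repeatedly sweeps all nodes in index order, activating any inactive node
    whose active-neighbor count meets its resistance, until nothing changes.
    Intentionally ignorant of levels/frontiers so it is independent of the
    BFS engine it checks.
    """
    adj = {i: set() for i in range(net.n_nodes)}
    for a, b in net.edges:
        adj[int(a)].add(int(b))
        adj[int(b)].add(int(a))
    active = set(int(s) for s in seeds)
    changed = True
    while changed:
        changed = False
        for i in range(net.n_nodes):
            if i in active or resist[i] >= UNREACHABLE:
                continue
            if sum(1 for j in adj[i] if j in active) >= resist[i]:
                active.add(i)
                changed = True
    return active


def random_instance(seed: int, n_min: int = 2, n_max: int = 12):
    """A random small graph with random thresholds, for property tests."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(n_min, n_max + 1))
    p = float(rng.uniform(0.1, 0.8))
    mask = rng.random((n, n)) < p
    edges = [(i, j) for i in range(n) for j in range(i + 1, n) if mask[i, j]]
    net = Network(n, np.array(edges, dtype=np.int64).reshape(-1, 2))
    phi = rng.uniform(0.05, 1.0, size=n)  # avoid phi=0 free activations
    return net, compute_resistances(net, phi)


def random_tree_instance(seed: int, n_min: int = 4, n_max: int = 14):
    """A random labeled tree with random thresholds.

    On trees the subcritical neighborhoods of a node are disjoint, which is
    the regime where the indirect-drop score is a true lower bound on the
    total-resistance drop.
    """
    rng = np.random.default_rng(seed)
    n = int(rng.integers(n_min, n_max + 1))
    edges = [(int(rng.integers(0, i)), i) for i in range(1, n)]
    net = Network(n, np.array(edges, dtype=np.int64))
    phi = rng.uniform(0.05, 1.0, size=n)
    return net, compute_resistances(net, phi)


def exhaustive_best_pair(net: Network, resist):
    """Brute-force optimum 2-seed spread (oracle for greedy comparisons)."""
    best = 0
    from ltmax import run_cascade

    for pair in itertools.combinations(range(net.n_nodes), 2):
        best = max(best, run_cascade(net, resist, list(pair)).spread_size)
    return best


@pytest.fixture
def path3():
    """Path A-B-C with phi = 0.5 everywhere (r = 1 each)."""
    net = Network(3, [(0, 1), (1, 2)])
    return net, compute_resistances(net, np.full(3, 0.5))


@pytest.fixture
def star5():
    """Star with 4 leaves, phi = 0.5 (r_center = 2, r_leaf = 1)."""
    net = Network(5, [(0, i) for i in range(1, 5)])
    return net, compute_resistances(net, np.full(5, 0.5))


@pytest.fixture
def k5_r2():
    """Complete graph K5 with resistance 2 everywhere."""
    net = Network(5, list(itertools.combinations(range(5), 2)))
    return net, np.full(5, 2, dtype=np.int64)
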