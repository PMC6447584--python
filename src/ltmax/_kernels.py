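"""Numba inner loops for cascade propagation, node scoring and GPI trials.

All kernels operate on the CSR adjacency of a :class:`~ltmax.network.Network`
(``indptr``/``indices`` int64 arrays) plus flat per-node state arrays:
``active`` (bool), ``residual`` (int64, remaining active-neighbor demand) and
``inact_deg`` (int64, number of currently inactive neighbors, i.e. the dynamic
out-degree).  The Python layer owns all validation; kernels assume clean input.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Resistance sentinel for nodes that can never be activated through spread
# (isolated nodes).  Large enough that decrements can never reach zero, and
# detected with ``residual >= UNREACHABLE`` even after spurious decrements.
UNREACHABLE = np.int64(2**40)

# "Unbounded" level cap for full cascades.
NO_LIMIT = np.int64(2**31)

# Strategy codes shared with ltmax.strategies.
THRES, DEG, RES, DD, ID, BI, CITM = 0, 1, 2, 3, 4, 5, 6


@njit(cache=True)
def propagate(indptr, indices, active, residual, inact_deg, out, m, max_levels):
    """Level-synchronous cascade from the frontier ``out[:m]``.

    Frontier nodes must already be marked active with residual 0; their
    neighbor updates have not yet been applied.  Activated nodes (frontier
    included) are appended to ``out``.  Returns ``(n_activated, n_levels)``
    where ``n_levels`` counts the propagation rounds that activated at least
    one new node.
    """
    total = m
    cur0 = 0
    cur1 = m
    rounds = 0
    levels = 0
    while cur1 > cur0 and rounds < max_levels:
        before = total
        for t in range(cur0, cur1):
            v = out[t]
            for e in range(indptr[v], indptr[v + 1]):
                u = indices[e]
                inact_deg[u] -= 1
                if not active[u]:
                    residual[u] -= 1
                    if residual[u] <= 0:
                        active[u] = True
                        residual[u] = 0
                        out[total] = u
                        total += 1
        rounds += 1
        if total > before:
            levels += 1
        cur0 = cur1
        cur1 = total
    return total, levels


@njit(cache=True)
def add_seeds(indptr, indices, active, residual, inact_deg, seeds, out, max_levels):
    """Activate ``seeds`` (assumed inactive, unique) and propagate."""
    m = 0
    for s in seeds:
        active[s] = True
        residual[s] = 0
        out[m] = s
        m += 1
    return propagate(indptr, indices, active, residual, inact_deg, out, m, max_levels)


@njit(cache=True)
def score_nodes(indptr, indices, active, residual, inact_deg, degree, nodes,
                code, a, b, c, L, stamp, queue, token):
    """Score ``nodes`` (assumed inactive) under one selection heuristic.

    Codes: 0 thres (dynamic resistance over original degree), 1 deg (dynamic
    out-degree), 2 res, 3 DD = r + k_out, 4 ID = DD + sum over subcritical
    neighbors of (k_out - 1), 5 BI with weights (a, b, c), 6 CI-TM-style
    subcritical-chain score up to depth ``L``.

    Isolated (unreachable) nodes score -1 under every heuristic: seeding them
    gains exactly one node, so they are deliberately ranked last.

    ``stamp``/``queue`` are caller-owned int64 work arrays of length n used by
    the CI-TM BFS; ``token`` is the stamp generation counter and the updated
    value is returned alongside the scores.
    """
    out = np.empty(nodes.size, np.float64)
    for t in range(nodes.size):
        i = nodes[t]
        r = residual[i]
        if r >= UNREACHABLE:
            out[t] = -1.0
            continue
        if code == THRES:
            out[t] = r / degree[i]
        elif code == DEG:
            out[t] = inact_deg[i]
        elif code == RES:
            out[t] = r
        elif code == DD:
            out[t] = r + inact_deg[i]
        elif code == ID or code == BI:
            sub = 0.0
            for e in range(indptr[i], indptr[i + 1]):
                j = indices[e]
                if (not active[j]) and residual[j] == 1:
                    sub += inact_deg[j] - 1
            if code == ID:
                out[t] = r + inact_deg[i] + sub
            else:
                out[t] = a * r + b * inact_deg[i] + c * sub
        else:  # CITM: out-degree summed along chains of resistance-1 nodes
            token += 1
            stamp[i] = token
            score = float(inact_deg[i])
            queue[0] = i
            q0 = 0
            q1 = 1
            level = 0
            while q1 > q0 and level < L:
                qn = q1
                for qi in range(q0, q1):
                    v = queue[qi]
                    for e in range(indptr[v], indptr[v + 1]):
                        u = indices[e]
                        if (not active[u]) and residual[u] == 1 and stamp[u] != token:
                            stamp[u] = token
                            score += inact_deg[u] - 1
                            queue[qn] = u
                            qn += 1
                level += 1
                q0 = q1
                q1 = qn
            out[t] = score
    return out, token


@njit(cache=True)
def k_hop_inactive(indptr, indices, active, sources, depth, stamp, queue, token):
    """Inactive nodes within ``depth`` hops of ``sources`` (sources included
    when inactive).  Used to bound the rescoring set after a seeding event."""
    token += 1
    found = np.empty(active.size, np.int64)
    m = 0
    q1 = 0
    for s in sources:
        if stamp[s] != token:
            stamp[s] = token
            queue[q1] = s
            q1 += 1
            if not active[s]:
                found[m] = s
                m += 1
    q0 = 0
    level = 0
    while q1 > q0 and level < depth:
        qn = q1
        for qi in range(q0, q1):
            v = queue[qi]
            for e in range(indptr[v], indptr[v + 1]):
                u = indices[e]
                if stamp[u] != token:
                    stamp[u] = token
                    queue[qn] = u
                    qn += 1
                    if not active[u]:
                        found[m] = u
                        m += 1
        level += 1
        q0 = q1
        q1 = qn
    return found[:m].copy(), token


@njit(cache=True)
def single_seed_gains(indptr, indices, active, residual, inact_deg, candidates, max_levels):
    """Marginal cascade size of seeding each candidate on a disposable copy
    of the current state (the greedy strategy's evaluation step)."""
    n = active.size
    gains = np.empty(candidates.size, np.int64)
    act = np.empty(n, np.bool_)
    res = np.empty(n, np.int64)
    ind = np.empty(n, np.int64)
    out = np.empty(n, np.int64)
    for t in range(candidates.size):
        act[:] = active
        res[:] = residual
        ind[:] = inact_deg
        cand = candidates[t]
        act[cand] = True
        res[cand] = 0
        out[0] = cand
        total, _ = propagate(indptr, indices, act, res, ind, out, 1, max_levels)
        gains[t] = total
    return gains


@njit(cache=True)
def gpi_trials(indptr, indices, active0, residual0, inact0, remaining_goal,
               v, seed_base, max_levels):
    """Run ``v`` random-team trials for the Group Performance Index.

    Each trial works on a disposable copy of the current state, drawing
    uniformly random inactive nodes one at a time (cascading after each) until
    the trial spread reaches ``remaining_goal``.  Per-node membership counts
    and size-weighted sums are accumulated; the per-trial RNG stream is seeded
    with ``seed_base + j`` so earlier trials are unchanged when v grows.
    """
    n = active0.size
    counts = np.zeros(n, np.int64)
    size_sums = np.zeros(n, np.int64)
    trial_sizes = np.empty(v, np.int64)
    members = np.empty(n, np.int64)
    out = np.empty(n, np.int64)
    act = np.empty(n, np.bool_)
    res = np.empty(n, np.int64)
    ind = np.empty(n, np.int64)
    n_inactive0 = 0
    for i in range(n):
        if not active0[i]:
            n_inactive0 += 1
    for j in range(v):
        np.random.seed((seed_base + j) % 2147483647)
        act[:] = active0
        res[:] = residual0
        ind[:] = inact0
        spread = 0
        m = 0
        inactive_left = n_inactive0
        while spread < remaining_goal and inactive_left > 0:
            u = np.random.randint(0, n)
            while act[u]:
                u = np.random.randint(0, n)
            members[m] = u
            m += 1
            act[u] = True
            res[u] = 0
            out[0] = u
            total, _ = propagate(indptr, indices, act, res, ind, out, 1, max_levels)
            spread += total
            inactive_left -= total
        trial_sizes[j] = m
        for t in range(m):
            counts[members[t]] += 1
            size_sums[members[t]] += m
    return counts, size_sums, trial_sizes
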