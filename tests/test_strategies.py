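"""Score formulas, corner equivalences and sequential/greedy selection."""

import numpy as np
import pytest

from ltmax import (BIWeights, CascadeState, ContractViolation, Network,
                   compute_resistances, greedy_select, node_score,
                   run_cascade, sequential_select, total_resistance)
from ltmax.strategies import _CODES, _score
from conftest import exhaustive_best_pair, random_instance, random_tree_instance


def dynamic_state(seed: int):
    """Random instance with a few random seeds already applied, so scores
    are exercised on genuinely dynamic (partially activated) states.
    Thresholds are kept high so the partial cascade leaves inactive nodes."""
    net, _ = random_instance(seed, n_min=6, n_max=12)
    rng = np.random.default_rng(seed)
    resist = compute_resistances(net, rng.uniform(0.45, 1.0, size=net.n_nodes))
    state = CascadeState.fresh(net, resist)
    for s in rng.choice(net.n_nodes, size=2, replace=False):
        if not state.active[s] and state.inactive_count > 3:
            state.add_seed_incremental(int(s))
    return net, resist, state


def all_scores(state, strategy, weights=None, L=6):
    inact = np.flatnonzero(~state.active)
    a, b, c = (weights if weights else (0.0, 0.0, 0.0))
    return inact, _score(state, inact, _CODES[strategy], a, b, c, L)


def test_star_direct_and_indirect_drop_scores(star5):
    net, resist = star5
    state = CascadeState.fresh(net, resist)
    assert node_score(state, 0, "dd") == 6.0  # r=2 + k_out=4
    # every leaf is subcritical with k_out - 1 = 0, so ID adds nothing
    assert node_score(state, 0, "id") == 6.0
    assert node_score(state, 1, "dd") == 2.0


def test_scoring_an_active_node_is_a_contract_violation(star5):
    net, resist = star5
    state = CascadeState.fresh(net, resist)
    state.add_seed_incremental(0)
    with pytest.raises(ContractViolation):
        node_score(state, 1, "deg")


@pytest.mark.parametrize("seed", range(25))
def test_balanced_index_corner_equivalences(seed):
    """BI reduces to res/deg/DD/ID/CI-TM(L=1) at the corner weights."""
    _, _, state = dynamic_state(seed)
    if state.inactive_count == 0:
        pytest.skip("fully active realization")
    _, res = all_scores(state, "res")
    _, deg = all_scores(state, "deg")
    _, dd = all_scores(state, "dd")
    _, idr = all_scores(state, "id")
    _, citm1 = all_scores(state, "citm", L=1)
    _, bi_res = all_scores(state, "bi", weights=(1, 0, 0))
    _, bi_deg = all_scores(state, "bi", weights=(0, 1, 0))
    _, bi_dd = all_scores(state, "bi", weights=(0.5, 0.5, 0))
    _, bi_id = all_scores(state, "bi", weights=(1 / 3, 1 / 3, 1 / 3))
    _, bi_citm = all_scores(state, "bi", weights=(0, 0.5, 0.5))
    reachable = res >= 0  # isolated nodes share the fixed last-place score
    assert np.array_equal(bi_res, res)
    assert np.array_equal(bi_deg, deg)
    assert np.array_equal(2 * bi_dd[reachable], dd[reachable])
    np.testing.assert_allclose(3 * bi_id[reachable], idr[reachable], rtol=1e-12)
    assert np.array_equal(2 * bi_citm[reachable], citm1[reachable])
    # CI-TM at L=1 is exactly ID minus the node's own resistance
    assert np.array_equal(citm1[reachable], (idr - res)[reachable])


@pytest.mark.parametrize("seed", range(15))
def test_citm_score_nondecreasing_in_depth(seed):
    _, _, state = dynamic_state(seed)
    if state.inactive_count == 0:
        pytest.skip("fully active realization")
    prev = None
    for L in (1, 2, 3, 6):
        _, s = all_scores(state, "citm", L=L)
        if prev is not None:
            assert np.all(s >= prev - 1e-12)
        prev = s


@pytest.mark.parametrize("seed", range(20))
def test_indirect_drop_bounds_resistance_drop_on_trees(seed):
    """On trees (disjoint subcritical shells) ID never exceeds the true
    total-resistance drop of seeding the node."""
    net, resist = random_tree_instance(seed)
    state = CascadeState.fresh(net, resist)
    inact, idscores = all_scores(state, "id")
    for node, score in zip(inact, idscores):
        probe = state.copy()
        before = total_resistance(probe)
        probe.add_seed_incremental(int(node))
        drop = before - total_resistance(probe)
        assert score <= drop + 1e-9


@pytest.mark.parametrize("seed", range(20))
def test_direct_drop_bounds_resistance_drop_everywhere(seed):
    """DD = r + k_out is a lower bound on the drop on any graph (every
    neighbor decrement is a real unit of resistance removed)."""
    net, resist, state = dynamic_state(seed)
    inact, ddscores = all_scores(state, "dd")
    for node, score in zip(inact, ddscores):
        if score < 0:  # isolated sentinel
            continue
        probe = state.copy()
        before = total_resistance(probe)
        probe.add_seed_incremental(int(node))
        assert score <= before - total_resistance(probe) + 1e-9


@pytest.mark.parametrize("strategy", ["thres", "deg", "res", "dd", "id", "citm"])
@pytest.mark.parametrize("seed", [3, 17, 41])
def test_local_rescoring_matches_full_rescan(strategy, seed):
    net, resist = random_instance(seed, n_min=8, n_max=12)
    kw = dict(s_goal=1.0, rng_seed=7)
    local = sequential_select(net, resist, strategy, rescore="local", **kw)
    full = sequential_select(net, resist, strategy, rescore="full", **kw)
    assert np.array_equal(local.seeds, full.seeds)
    assert np.array_equal(local.cumulative_spread, full.cumulative_spread)


def test_bi_local_rescoring_matches_full_rescan():
    net, resist = random_instance(23, n_min=8, n_max=12)
    kw = dict(weights=(0.5, 0.25, 0.25), s_goal=1.0, rng_seed=7)
    local = sequential_select(net, resist, "bi", rescore="local", **kw)
    full = sequential_select(net, resist, "bi", rescore="full", **kw)
    assert np.array_equal(local.seeds, full.seeds)


def test_first_selection_is_the_score_argmax(star5):
    net, resist = star5
    traj = sequential_select(net, resist, "dd", budget=1, rng_seed=0)
    assert traj.seeds[0] == 0          # dd(center)=6 beats dd(leaf)=2
    assert traj.cumulative_spread[0] == 5


def test_sequential_goal_stop_and_monotone_spread():
    net, resist = random_instance(5, n_min=10, n_max=12)
    traj = sequential_select(net, resist, "deg", s_goal=0.5, rng_seed=1)
    goal = -(-net.n_nodes // 2)
    assert traj.cumulative_spread[-1] >= goal
    assert np.all(np.diff(traj.cumulative_spread) >= 0)
    # the previous prefix must not have met the goal yet
    if traj.seeds.size > 1:
        assert traj.cumulative_spread[-2] < goal


def test_trajectory_reaches_everything_at_full_budget():
    net, resist = random_instance(9, n_min=6, n_max=10)
    traj = sequential_select(net, resist, "random", budget=net.n_nodes, rng_seed=4)
    assert traj.spread_at(traj.seeds.size) == net.n_nodes


def test_random_strategy_is_seed_deterministic():
    net, resist = random_instance(31, n_min=10, n_max=12)
    a = sequential_select(net, resist, "random", budget=5, rng_seed=8)
    b = sequential_select(net, resist, "random", budget=5, rng_seed=8)
    assert np.array_equal(a.seeds, b.seeds)


def test_bi_weights_validation():
    with pytest.raises(ValueError):
        BIWeights(0.5, 0.6, 0.2)
    with pytest.raises(ValueError):
        BIWeights(-0.1, 0.6, 0.5)
    with pytest.raises(ValueError):
        sequential_select(*random_instance(1), "bi", budget=1)


def test_greedy_first_seed_maximizes_single_seed_spread():
    for seed in (2, 12, 22):
        net, resist = random_instance(seed, n_min=6, n_max=10)
        traj = greedy_select(net, resist, budget=1, rng_seed=0)
        gains = [run_cascade(net, resist, [i]).spread_size
                 for i in range(net.n_nodes)]
        assert traj.cumulative_spread[0] == max(gains)


def test_greedy_on_all_r1_path_floods_from_any_seed():
    net = Network(5, [(i, i + 1) for i in range(4)])
    resist = np.ones(5, dtype=np.int64)
    traj = greedy_select(net, resist, budget=1, rng_seed=0)
    assert traj.cumulative_spread[0] == 5


@pytest.mark.parametrize("seed", range(10))
def test_greedy_two_seeds_vs_exhaustive_pair_optimum(seed):
    """Greedy is sandwiched between the best single seed and the exhaustive
    2-seed optimum (spread is not submodular, so equality can fail)."""
    net, resist = random_instance(seed, n_min=6, n_max=12)
    traj = greedy_select(net, resist, budget=2, rng_seed=0)
    opt2 = exhaustive_best_pair(net, resist)
    best1 = max(run_cascade(net, resist, [i]).spread_size
                for i in range(net.n_nodes))
    two_seed = traj.spread_at(2)
    assert best1 <= two_seed <= opt2
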