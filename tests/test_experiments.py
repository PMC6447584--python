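"""Ensemble harness: critical fractions, weight scans, win probabilities."""

import numpy as np
import pandas as pd
import pytest

from ltmax import (EnsembleResult, ExperimentConfig, Network, StrategySpec,
                   best_strategy_probability, ensemble_experiment,
                   find_critical_fraction, sequential_select, weight_scan)
from conftest import random_instance


def test_critical_fraction_single_seed_flood():
    net = Network(8, [(i, i + 1) for i in range(7)])
    resist = np.ones(8, dtype=np.int64)
    for strategy in ("deg", "res", "greedy"):
        assert find_critical_fraction(net, resist, strategy, 1.0) == 1 / 8


def test_critical_fraction_k5_needs_two_fifths(k5_r2):
    net, resist = k5_r2
    assert find_critical_fraction(net, resist, "deg", 1.0) == 2 / 5


def test_ensemble_single_realization_has_undefined_se():
    cfg = ExperimentConfig(n_nodes=120, mean_degree=6, sigma=0.2,
                           strategies=["deg"], n_realizations=1, base_seed=3)
    res = ensemble_experiment(cfg)
    assert len(res.data) == 1
    assert np.isnan(res.summary.loc["deg", "se"])
    assert res.summary.loc["deg", "mean"] == res.data["p_c"].iloc[0]


def test_ensemble_is_bit_reproducible():
    cfg = ExperimentConfig(n_nodes=150, mean_degree=6, sigma=0.25,
                           strategies=["deg", "res"], n_realizations=4,
                           base_seed=11)
    a = ensemble_experiment(cfg)
    b = ensemble_experiment(cfg)
    pd.testing.assert_frame_equal(a.data, b.data)


def test_fixed_graph_mode_reuses_one_network():
    # with sigma=0 the thresholds are degenerate too, so every realization
    # of a fixed-graph ensemble must give the same p_c
    cfg = ExperimentConfig(n_nodes=200, mean_degree=6, sigma=0.0,
                           strategies=["deg"], n_realizations=3, base_seed=5,
                           fixed_graph=True)
    res = ensemble_experiment(cfg)
    assert res.data["p_c"].nunique() == 1


def test_ensemble_roundtrip_serialization(tmp_path):
    cfg = ExperimentConfig(n_nodes=120, mean_degree=6, sigma=0.2,
                           strategies=["deg"], n_realizations=3, base_seed=7)
    res = ensemble_experiment(cfg)
    res.save(tmp_path / "out")
    back = EnsembleResult.load(tmp_path / "out")
    pd.testing.assert_frame_equal(back.summary, res.summary)


def test_config_yaml_roundtrip(tmp_path):
    cfg = ExperimentConfig(n_nodes=321, sigma=0.15, strategies=["id"],
                           base_seed=9)
    cfg.to_yaml(tmp_path / "c.yaml")
    assert ExperimentConfig.from_yaml(tmp_path / "c.yaml") == cfg


def test_weight_scan_corners_match_named_strategies():
    """The (a,b) = (0,1) and (1,0) corners of the scan reproduce the deg and
    res ensembles exactly under common random numbers."""
    cfg = ExperimentConfig(n_nodes=300, mean_degree=8, sigma=0.25,
                           strategies=["deg", "res"], n_realizations=4,
                           base_seed=21)
    _, surface = weight_scan(cfg, grid_resolution=0.5)
    named = ensemble_experiment(cfg)
    corner_deg = surface.set_index(["a", "b"]).loc[(0.0, 1.0), "mean_p_c"]
    corner_res = surface.set_index(["a", "b"]).loc[(1.0, 0.0), "mean_p_c"]
    assert corner_deg == pytest.approx(named.summary.loc["deg", "mean"])
    assert corner_res == pytest.approx(named.summary.loc["res", "mean"])


def test_weight_scan_rejects_uneven_resolution():
    with pytest.raises(ValueError):
        weight_scan(ExperimentConfig(n_realizations=1), grid_resolution=0.3)


def _budget_trajectories(seeds, strategies, n=60):
    trajs = {s: [] for s in strategies}
    for seed in seeds:
        net, resist = random_instance(seed, n_min=n, n_max=n)
        for s in strategies:
            trajs[s].append(sequential_select(net, resist, s, budget=n,
                                              rng_seed=seed))
    return trajs


def test_single_strategy_always_wins():
    trajs = _budget_trajectories(range(40, 43), ["deg"], n=12)
    table = best_strategy_probability(trajs, p_values=[0.25, 0.5, 1.0])
    assert np.all(table["deg"].to_numpy() == 1.0)


def test_identical_strategies_split_ties_evenly():
    trajs = _budget_trajectories(range(40, 43), ["deg"], n=12)
    trajs["deg-clone"] = trajs["deg"]
    table = best_strategy_probability(trajs, p_values=[0.25, 0.5, 1.0])
    assert np.allclose(table.to_numpy(), 0.5)


def test_mismatched_realization_sets_rejected():
    trajs = _budget_trajectories(range(40, 43), ["deg"], n=12)
    trajs["res"] = trajs["deg"][:-1]
    with pytest.raises(ValueError):
        best_strategy_probability(trajs, p_values=[0.5])


def test_greedy_wins_most_often_at_small_initiator_fractions():
    """Fixed-graph protocol with repeated threshold generations: exact
    greedy has the top win probability at the smallest initiator fraction."""
    from ltmax import (SIGMA_UNIFORM, ThresholdSpec, compute_resistances,
                       generate_er, greedy_select, sample_thresholds)

    n = 500
    net = generate_er(n, 10.0, 77)
    trajs = {s: [] for s in ("greedy", "id", "deg", "res")}
    for r in range(10):
        phi = sample_thresholds(ThresholdSpec(0.5, SIGMA_UNIFORM), n, 300 + r)
        resist = compute_resistances(net, phi)
        for s in trajs:
            if s == "greedy":
                trajs[s].append(greedy_select(net, resist, budget=15, rng_seed=r))
            else:
                trajs[s].append(sequential_select(net, resist, s, budget=15,
                                                  rng_seed=r))
    table = best_strategy_probability(trajs, p_values=[2 / n, 5 / n, 10 / n])
    first_row = table.iloc[0]
    assert first_row["greedy"] == first_row.max()
    assert first_row["greedy"] > 0.5


def test_full_budget_activates_everything_for_every_strategy():
    net, resist = random_instance(61, n_min=15, n_max=15)
    for strategy in ("deg", "res", "id", "random"):
        traj = sequential_select(net, resist, strategy, budget=net.n_nodes,
                                 rng_seed=2)
        assert traj.spread_at(net.n_nodes) == net.n_nodes
        assert np.all(np.diff(traj.cumulative_spread) >= 0)


def test_strategy_spec_parsing():
    assert StrategySpec.parse("id").name == "id"
    spec = StrategySpec.parse({"name": "bi", "weights": [0.5, 0.3, 0.2]})
    assert spec.weights == (0.5, 0.3, 0.2)
    assert spec.label == "bi(0.5,0.3,0.2)"
    with pytest.raises(TypeError):
        StrategySpec.parse(42)
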