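"""Ensemble harness: critical initiator fractions, weight scans, win rates.

Every comparison uses common random numbers: all strategies evaluated within
one realization see the same graph and the same thresholds, and realization
seeds are derived deterministically from the base seed.  Trajectories are
exact at every initiator fraction p = m/N (seeds enter one at a time), so no
interpolation is involved anywhere.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .gpi import GPIConfig, gpi_select
from .netgen import AssortativityTarget, generate_er, rewire_to_assortativity
from .network import Network
from .strategies import BIWeights, SeedTrajectory, greedy_select, sequential_select
from .thresholds import ThresholdSpec, compute_resistances, sample_thresholds


@dataclass(frozen=True)
class StrategySpec:
    """A named selection strategy plus its parameters (BI weights, CI-TM
    depth L, GPI control parameters, greedy evaluation truncation)."""

    name: str
    weights: tuple | None = None
    L: int = 6
    v: int = 100_000
    s: float = 1e-3
    evaluation_levels: int | None = None

    @classmethod
    def parse(cls, obj) -> "StrategySpec":
        if isinstance(obj, StrategySpec):
            return obj
        if isinstance(obj, str):
            return cls(name=obj)
        if isinstance(obj, dict):
            d = dict(obj)
            if "weights" in d and d["weights"] is not None:
                d["weights"] = tuple(d["weights"])
            return cls(**d)
        raise TypeError(f"cannot parse strategy spec from {obj!r}")

    @property
    def label(self) -> str:
        if self.name == "bi" and self.weights is not None:
            a, b, c = self.weights
            return f"bi({a:g},{b:g},{c:g})"
        return self.name


def run_selection(net: Network, resist: np.ndarray, spec: StrategySpec, *,
                  budget: int | None = None, s_goal: float | None = None,
                  rng_seed: int = 0) -> SeedTrajectory:
    """Dispatch one selection run (sequential heuristic, greedy, or GPI)."""
    spec = StrategySpec.parse(spec)
    if spec.name == "greedy":
        return greedy_select(net, resist, budget=budget, s_goal=s_goal,
                             evaluation_levels=spec.evaluation_levels,
                             rng_seed=rng_seed)
    if spec.name == "gpi":
        cfg = GPIConfig(s=spec.s, v=spec.v,
                        s_goal=1.0 if s_goal is None else s_goal)
        return gpi_select(net, resist, cfg, rng_seed=rng_seed, budget=budget)
    return sequential_select(net, resist, spec.name, weights=spec.weights,
                             L=spec.L, budget=budget, s_goal=s_goal,
                             rng_seed=rng_seed)


def find_critical_fraction(net: Network, resist: np.ndarray, spec, s_goal: float,
                           rng_seed: int = 0) -> float:
    """Smallest initiator fraction |Y|/N at which the strategy's cumulative
    spread reaches s_goal * N (0.0 if free r=0 spread already suffices)."""
    if not 0.0 < s_goal <= 1.0:
        raise ValueError("s_goal must lie in (0, 1]")
    traj = run_selection(net, resist, StrategySpec.parse(spec),
                         s_goal=s_goal, rng_seed=rng_seed)
    pc = traj.p_c(s_goal)
    assert pc is not None  # seeding all nodes always reaches any goal
    return pc


@dataclass
class ExperimentConfig:
    """Ensemble study conditions.  Reference conditions are N=10,000,
    <k>=10, mean threshold 0.5 and 500 realizations (20 for GPI); the
    defaults here are the desk-scale variants used by the bundled analyses,
    with the full scale available by overriding fields."""

    n_nodes: int = 1000
    mean_degree: float = 10.0
    rho_target: float = 0.0
    rho_tolerance: float = 0.02
    sigma: float = 1.0 / math.sqrt(12.0)
    mean_phi: float = 0.5
    strategies: list = field(default_factory=lambda: ["id", "deg", "res"])
    s_goal: float = 0.5
    n_realizations: int = 20
    base_seed: int = 0
    fixed_graph: bool = False

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))


def _child_seeds(base_seed: int, n: int, salt: int = 0) -> np.ndarray:
    """Deterministic per-realization seeds (kept below 2**31)."""
    ss = np.random.SeedSequence([int(base_seed), salt])
    return ss.generate_state(n, dtype=np.uint32).astype(np.int64) % (2**31)


def make_instance(config: ExperimentConfig, graph_seed: int, thr_seed: int):
    """One realization: graph (rewired if a target rho is set) + resistances."""
    net = generate_er(config.n_nodes, config.mean_degree, graph_seed)
    if config.rho_target != 0.0:
        target = AssortativityTarget(config.rho_target, config.rho_tolerance)
        net = rewire_to_assortativity(net, target, graph_seed + 1).network
    phi = sample_thresholds(ThresholdSpec(config.mean_phi, config.sigma),
                            config.n_nodes, thr_seed)
    return net, compute_resistances(net, phi)


@dataclass
class EnsembleResult:
    """Per-realization measurements plus their aggregate.

    ``data`` holds one row per realization and strategy; ``summary`` the
    mean and standard error (sd / sqrt(n); NaN for a single realization).
    The aggregates are always recomputable from ``data``.
    """

    data: pd.DataFrame
    summary: pd.DataFrame
    config: dict

    def save(self, prefix) -> None:
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        self.data.to_csv(prefix.with_suffix(".csv"), index=False)
        payload = {"config": self.config,
                   "summary": self.summary.reset_index().to_dict(orient="records")}
        prefix.with_suffix(".json").write_text(json.dumps(payload, indent=2))

    @classmethod
    def load(cls, prefix) -> "EnsembleResult":
        prefix = Path(prefix)
        data = pd.read_csv(prefix.with_suffix(".csv"))
        payload = json.loads(prefix.with_suffix(".json").read_text())
        return cls(data=data, summary=_summarize(data), config=payload["config"])


def _summarize(data: pd.DataFrame) -> pd.DataFrame:
    grp = data.groupby("strategy")["p_c"]
    out = grp.agg(mean="mean", sd="std", n="count")
    out["se"] = out["sd"] / np.sqrt(out["n"])
    return out[["mean", "se", "n"]]


def ensemble_experiment(config: ExperimentConfig) -> EnsembleResult:
    """Measure p_c for every configured strategy over an ensemble.

    Fresh-graph mode regenerates graph and thresholds per realization;
    fixed-graph mode reuses one graph and regenerates only the thresholds.
    Failed realizations are recorded (column ``failed``) and excluded from
    the aggregate rather than aborting the ensemble.
    """
    specs = [StrategySpec.parse(s) for s in config.strategies]
    gseeds = _child_seeds(config.base_seed, config.n_realizations, salt=1)
    tseeds = _child_seeds(config.base_seed, config.n_realizations, salt=2)
    rseeds = _child_seeds(config.base_seed, config.n_realizations, salt=3)
    if config.fixed_graph:
        gseeds = np.full(config.n_realizations, gseeds[0])
    rows = []
    for r in range(config.n_realizations):
        try:
            net, resist = make_instance(config, int(gseeds[r]), int(tseeds[r]))
            for spec in specs:
                pc = find_critical_fraction(net, resist, spec, config.s_goal,
                                            rng_seed=int(rseeds[r]))
                rows.append({"realization": r, "strategy": spec.label,
                             "p_c": pc, "failed": False})
        except Exception as exc:  # pragma: no cover - defensive
            rows.append({"realization": r, "strategy": "-", "p_c": np.nan,
                         "failed": True, "error": str(exc)})
    data = pd.DataFrame(rows)
    ok = data[~data["failed"]]
    return EnsembleResult(data=data, summary=_summarize(ok),
                          config=dataclasses.asdict(config))


def weight_scan(config: ExperimentConfig, grid_resolution: float = 0.05):
    """Scan the BI weight simplex on a shared realization set.

    Evaluates the ensemble-mean p_c for every grid point (a, b) with
    a + b <= 1 and c = 1 - a - b, using identical graphs, thresholds and run
    seeds at every point (common random numbers).  Returns the argmin
    weights and the full surface as a DataFrame.
    """
    steps = round(1.0 / grid_resolution)
    if abs(steps * grid_resolution - 1.0) > 1e-9:
        raise ValueError("grid_resolution must divide 1 evenly")
    gseeds = _child_seeds(config.base_seed, config.n_realizations, salt=1)
    tseeds = _child_seeds(config.base_seed, config.n_realizations, salt=2)
    rseeds = _child_seeds(config.base_seed, config.n_realizations, salt=3)
    if config.fixed_graph:
        gseeds = np.full(config.n_realizations, gseeds[0])
    instances = [make_instance(config, int(gseeds[r]), int(tseeds[r]))
                 for r in range(config.n_realizations)]
    rows = []
    for ia in range(steps + 1):
        for ib in range(steps + 1 - ia):
            a = round(ia * grid_resolution, 12)
            b = round(ib * grid_resolution, 12)
            c = max(0.0, round(1.0 - a - b, 12))
            pcs = [find_critical_fraction(net, resist,
                                          StrategySpec("bi", weights=(a, b, c)),
                                          config.s_goal, rng_seed=int(rseeds[r]))
                   for r, (net, resist) in enumerate(instances)]
            pcs = np.asarray(pcs)
            rows.append({"a": a, "b": b, "c": c, "mean_p_c": pcs.mean(),
                         "se_p_c": pcs.std(ddof=1) / np.sqrt(len(pcs))
                         if len(pcs) > 1 else np.nan})
    surface = pd.DataFrame(rows)
    best = surface.iloc[int(surface["mean_p_c"].to_numpy().argmin())]
    return BIWeights(best["a"], best["b"], best["c"]), surface


def best_strategy_probability(trajectories: dict[str, list[SeedTrajectory]],
                              p_values) -> pd.DataFrame:
    """Probability of each strategy attaining the largest spread at each p.

    All strategies must supply one trajectory per shared realization; at each
    initiator fraction the win is split equally among tied leaders.
    """
    names = list(trajectories)
    lengths = {len(trajectories[k]) for k in names}
    if len(lengths) != 1:
        raise ValueError("all strategies must cover the same realizations")
    n_real = lengths.pop()
    n_nodes = {t.n_nodes for ts in trajectories.values() for t in ts}
    if len(n_nodes) != 1:
        raise ValueError("trajectories must share one network size")
    n = n_nodes.pop()
    p_values = np.asarray(p_values, dtype=np.float64)
    wins = np.zeros((p_values.size, len(names)))
    for r in range(n_real):
        for ip, p in enumerate(p_values):
            m = int(round(p * n))
            spreads = np.array([trajectories[k][r].spread_at(m) for k in names])
            leaders = np.flatnonzero(spreads == spreads.max())
            wins[ip, leaders] += 1.0 / leaders.size
    return pd.DataFrame(wins / n_real, index=pd.Index(p_values, name="p"),
                        columns=names)
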