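"""Truncated-normal threshold sampling and integer resistances.

Thresholds phi are fractions in [0, 1]; the sampling family is the normal
distribution N(mu, tau) truncated to [0, 1] with mu fixed at the target mean
(0.5 by default).  The family is parameterized by the standard deviation
``sigma`` of the *truncated* distribution, which runs from 0 (all mass at the
mean) to 1/sqrt(12) ~= 0.28868, the uniform limit reached as tau -> inf.  The
underlying scale tau matching a requested sigma is solved numerically.

A node of degree k and threshold phi needs ``r = ceil(phi * k)`` active
neighbors (the minimal integer m with m >= phi * k, the ">=" activation rule;
integral products give exactly phi * k, e.g. phi=0.5, k=10 -> r=5).  Isolated
nodes (k = 0) receive the ``UNREACHABLE`` sentinel: they can only enter a
cascade as seeds.  A supplied phi of 0 on a connected node yields r = 0 and
the node activates as soon as the dynamics first evaluate it, even with no
active neighbor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from ._kernels import UNREACHABLE
from .network import Network

#: Standard deviation of the uniform distribution on [0, 1] (sigma upper limit).
SIGMA_UNIFORM = 1.0 / math.sqrt(12.0)

#: Sentinel tau values: delta distribution at the mean / uniform limit.
TAU_DELTA = 0.0
TAU_UNIFORM = math.inf

_SIGMA_SLACK = 1e-3       # accept printed roundings like 0.2887 just above the limit
_UNIFORM_CUTOFF = 1e-6    # sigma within this of the limit is treated as uniform


@dataclass(frozen=True)
class ThresholdSpec:
    """Threshold distribution: truncated-normal mean and target sd."""

    mean: float = 0.5
    sigma: float = SIGMA_UNIFORM

    def __post_init__(self) -> None:
        if not 0.0 < self.mean < 1.0:
            raise ValueError("mean must lie in (0, 1)")
        if not 0.0 <= self.sigma <= SIGMA_UNIFORM + _SIGMA_SLACK:
            raise ValueError(f"sigma must lie in [0, 1/sqrt(12)] (got {self.sigma})")


@dataclass(frozen=True)
class ThresholdAssignment:
    """Per-node fractional thresholds and derived integer resistances."""

    phi: np.ndarray
    resistance: np.ndarray


def _truncated_sd(tau: float, mean: float) -> float:
    a, b = (0.0 - mean) / tau, (1.0 - mean) / tau
    return float(stats.truncnorm.std(a, b, loc=mean, scale=tau))


def solve_truncnorm_tau(sigma_target: float, mean: float = 0.5) -> float:
    """Underlying scale tau whose [0,1]-truncated sd equals ``sigma_target``.

    Returns ``TAU_DELTA`` (0.0) for sigma 0 and ``TAU_UNIFORM`` (inf) for the
    uniform limit 1/sqrt(12); otherwise the solution is accurate to 1e-6 in
    the resulting sd.  The uniform sentinel is only meaningful for mean 0.5.
    """
    if not 0.0 <= sigma_target <= SIGMA_UNIFORM + _SIGMA_SLACK:
        raise ValueError(f"sigma_target outside [0, 1/sqrt(12)]: {sigma_target}")
    if sigma_target < 1e-9:
        return TAU_DELTA
    if sigma_target >= SIGMA_UNIFORM - _UNIFORM_CUTOFF:
        if abs(mean - 0.5) > 1e-12:
            raise ValueError("uniform limit requires mean = 0.5")
        return TAU_UNIFORM
    # sd(tau) is increasing with sd(tau) < tau, so tau = sigma brackets below.
    lo = sigma_target
    hi = 2.0 * sigma_target
    while _truncated_sd(hi, mean) < sigma_target:
        hi *= 2.0
        if hi > 1e8:  # pragma: no cover - unreachable below the cutoff
            return TAU_UNIFORM
    tau = optimize.brentq(lambda t: _truncated_sd(t, mean) - sigma_target,
                          lo, hi, xtol=1e-12, rtol=1e-14)
    assert abs(_truncated_sd(tau, mean) - sigma_target) < 1e-6
    return float(tau)


def sample_thresholds(spec: ThresholdSpec, n_nodes: int, rng_seed: int) -> np.ndarray:
    """Draw i.i.d. thresholds by inverse-CDF (one uniform per node, so the
    draw count per seed is deterministic).  Values are in [0, 1]."""
    tau = solve_truncnorm_tau(spec.sigma, spec.mean)
    rng = np.random.default_rng(rng_seed)
    u = rng.random(n_nodes)
    if tau == TAU_DELTA:
        return np.full(n_nodes, spec.mean)
    if tau == TAU_UNIFORM:
        return u
    a, b = (0.0 - spec.mean) / tau, (1.0 - spec.mean) / tau
    phi = stats.truncnorm.ppf(u, a, b, loc=spec.mean, scale=tau)
    return np.clip(phi, 0.0, 1.0)


def compute_resistances(net: Network, phi: np.ndarray) -> np.ndarray:
    """Integer resistances r_i = ceil(phi_i * k_i); UNREACHABLE for k_i = 0.

    A 1e-9 guard absorbs float noise in the product so that exactly integral
    phi * k maps to that integer (the ">=" rule), never one above.
    """
    phi = np.asarray(phi, dtype=np.float64)
    if phi.shape != (net.n_nodes,):
        raise ValueError("phi length must equal the number of nodes")
    if np.any(phi < 0.0) or np.any(phi > 1.0) or not np.all(np.isfinite(phi)):
        raise ValueError("thresholds must lie in [0, 1]")
    r = np.ceil(phi * net.degree - 1e-9).astype(np.int64)
    np.maximum(r, 0, out=r)
    r[net.degree == 0] = UNREACHABLE
    return r


def assign(net: Network, spec: ThresholdSpec, rng_seed: int) -> ThresholdAssignment:
    """Sample thresholds for a network and derive resistances in one step."""
    phi = sample_thresholds(spec, net.n_nodes, rng_seed)
    return ThresholdAssignment(phi=phi, resistance=compute_resistances(net, phi))


# -- plain-text I/O --------------------------------------------------------

def write_thresholds(path, phi: np.ndarray) -> None:
    """Write a ``node_id,phi`` CSV."""
    with open(path, "w") as fh:
        fh.write("node_id,phi\n")
        for i, p in enumerate(phi):
            fh.write(f"{i},{float(p)!r}\n")


def read_thresholds(path, net: Network) -> np.ndarray:
    """Read a ``node_id,phi`` CSV, validating range and completeness against
    the network's node set."""
    import pandas as pd

    df = pd.read_csv(path)
    if list(df.columns) != ["node_id", "phi"]:
        raise ValueError("threshold CSV must have header 'node_id,phi'")
    phi = np.full(net.n_nodes, np.nan)
    ids = df["node_id"].to_numpy(dtype=np.int64)
    if ids.min() < 0 or ids.max() >= net.n_nodes or np.unique(ids).size != ids.size:
        raise ValueError("threshold CSV node ids must be unique and in range")
    phi[ids] = df["phi"].to_numpy(dtype=np.float64)
    if np.any(np.isnan(phi)):
        raise ValueError("threshold CSV does not cover every node")
    if np.any(phi < 0.0) or np.any(phi > 1.0):
        raise ValueError("thresholds must lie in [0, 1]")
    return phi
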