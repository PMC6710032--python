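"""Seeded, parallel Monte Carlo replication of swarm optimizer runs.

Repeatedly minimizes a registered benchmark objective with independent
random streams and collects the cloud of best positions/values — the
standard way to probe whether the optimizer reliably reaches the global
basins of a multimodal surface. Replicates are embarrassingly parallel;
sub-seeds are derived deterministically from the master seed via
``numpy.random.SeedSequence.spawn``, so the result multiset is identical
for any worker count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from joblib import Parallel, delayed

from .benchmarks import get_benchmark
from .pso import PSOConfig, pso

__all__ = ["MCConfig", "MCResult", "simulation_mc", "assign_basins"]


@dataclass
class MCConfig:
    """Replication settings; swarm settings default to S=150, e=1e-4,
    N=50, prop=0.1 — light enough that thousands of replicates are
    feasible while still locating global basins on 2-D benchmarks."""

    replicates: int = 200
    objective_name: str = "rastrigin"
    seed: Optional[int] = 1
    swarm_size: int = 150
    stop_variance: float = 1e-4
    min_iterations: int = 50
    stop_proportion: float = 0.1
    workers: int = 1

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        get_benchmark(self.objective_name)  # raises on unknown name


@dataclass
class MCResult:
    positions: np.ndarray  # (replicates, n)
    values: np.ndarray  # (replicates,)
    objective_name: str
    config: MCConfig = field(repr=False, default=None)


def _one_replicate(name: str, pso_cfg_kwargs: dict, child_seed) -> tuple:
    bench = get_benchmark(name)
    rng = np.random.default_rng(child_seed)
    config = PSOConfig(**pso_cfg_kwargs)
    result = pso(
        bench.objective, bench.default_bounds, config, rng=rng, vectorized=True
    )
    return result.best_position, result.best_value


def simulation_mc(config: MCConfig) -> MCResult:
    """Run ``config.replicates`` independent swarm minimizations.

    Returns the per-replicate best positions and values, ordered by
    replicate index (hence independent of parallel degree).
    """
    pso_kwargs = dict(
        swarm_size=config.swarm_size,
        stop_variance=config.stop_variance,
        min_iterations=config.min_iterations,
        stop_proportion=config.stop_proportion,
    )
    children = np.random.SeedSequence(config.seed).spawn(config.replicates)
    out = Parallel(n_jobs=config.workers)(
        delayed(_one_replicate)(config.objective_name, pso_kwargs, child)
        for child in children
    )
    positions = np.array([p for p, _ in out])
    values = np.array([v for _, v in out])
    return MCResult(
        positions=positions,
        values=values,
        objective_name=config.objective_name,
        config=config,
    )


def assign_basins(result: MCResult) -> np.ndarray:
    """Index of the nearest known global minimizer for each replicate."""
    bench = get_benchmark(result.objective_name)
    minima = np.array([pos for pos, _ in bench.known_minima])
    d = np.linalg.norm(
        result.positions[:, None, :] - minima[None, :, :], axis=2
    )
    return np.argmin(d, axis=1)


def plot_optima_cloud(result: MCResult, ax=None, grid_size: int = 300):
    """Level curves of the objective with the replicate optima overlaid."""
    import matplotlib.pyplot as plt

    bench = get_benchmark(result.objective_name)
    if bench.arity != 2:
        raise ValueError("level-curve plot requires a 2-D objective")
    if ax is None:
        _, ax = plt.subplots()
    lo, hi = bench.default_bounds.lower, bench.default_bounds.upper
    xs = np.linspace(lo[0], hi[0], grid_size)
    ys = np.linspace(lo[1], hi[1], grid_size)
    X, Y = np.meshgrid(xs, ys)
    Z = bench.evaluate(np.stack([X, Y], axis=-1))
    ax.contourf(X, Y, Z, levels=30)
    ax.contour(X, Y, Z, levels=30, colors="k", linewidths=0.3)
    ax.scatter(
        result.positions[:, 0], result.positions[:, 1],
        s=8, color="white", edgecolor="none",
    )
    ax.set_xlabel("x1")
    ax.set_ylabel("x2")
    ax.set_title(f"{bench.name} (replicates = {result.values.size})")
    return ax
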