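"""Box-constrained particle swarm optimization with out-of-bounds resampling.

The optimizer minimizes an objective over a rectangular search region
``R = prod_d [lower_d, upper_d]``. It follows the canonical global-best PSO
update

    v_i <- w * v_i + phi_p * r_p * (p_i - x_i) + phi_g * r_g * (g - x_i)
    x_i <- x_i + v_i

with one modification: a particle whose updated position leaves the box is
eliminated and replaced by a fresh uniform draw inside the region (its
velocity is kept). This keeps every evaluation feasible and prevents the
whole swarm from collapsing into a single local basin.

Termination couples a minimum iteration count N with a variance criterion:
once at least N iterations have run, the search stops when the sample
variance of the last ``ceil(prop * iterations)`` global-best values falls at
or below the threshold ``e``. A hard iteration cap guards against
non-convergent runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = [
    "Bounds",
    "PSOConfig",
    "SwarmState",
    "OptimizationTrace",
    "PSOResult",
    "initialize_swarm",
    "step",
    "should_stop",
    "pso",
]

_RESAMPLE_LIMIT = 100


@dataclass(frozen=True)
class Bounds:
    """Rectangular search region defined by component-wise lower/upper limits."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        lower = np.atleast_1d(np.asarray(self.lower, dtype=float))
        upper = np.atleast_1d(np.asarray(self.upper, dtype=float))
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)
        if lower.shape != upper.shape or lower.ndim != 1 or lower.size < 1:
            raise ValueError("lower and upper must be 1-D vectors of equal length")
        if not (np.all(np.isfinite(lower)) and np.all(np.isfinite(upper))):
            raise ValueError("bounds must be finite")
        if not np.all(lower < upper):
            raise ValueError("every lower bound must be strictly below its upper bound")

    @property
    def n(self) -> int:
        return self.lower.size

    @property
    def width(self) -> np.ndarray:
        return self.upper - self.lower

    def contains(self, x: np.ndarray) -> np.ndarray:
        """Row-wise membership test for an (S, n) array of positions."""
        x = np.atleast_2d(x)
        return np.all((x >= self.lower) & (x <= self.upper), axis=1)


@dataclass
class PSOConfig:
    """Swarm hyperparameters and stop-rule settings.

    ``swarm_size`` (S), ``stop_variance`` (e), ``min_iterations`` (N) and
    ``stop_proportion`` (prop) follow the package defaults S=150, N=500,
    prop=0.2. Inertia and acceleration coefficients default to
    omega=0.5, phi_p=phi_g=1.5, inside the standard convergence region.
    """

    swarm_size: int = 150
    stop_variance: float = 1e-4
    min_iterations: int = 500
    stop_proportion: float = 0.2
    inertia: float = 0.5
    cognitive_accel: float = 1.5
    social_accel: float = 1.5
    max_iterations: Optional[int] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.swarm_size < 2:
            raise ValueError("swarm_size must be at least 2")
        if self.stop_variance <= 0:
            raise ValueError("stop_variance must be positive")
        if not 0 < self.stop_proportion <= 1:
            raise ValueError("stop_proportion must be in (0, 1]")
        if self.min_iterations < 1:
            raise ValueError("min_iterations must be positive")
        if self.max_iterations is None:
            self.max_iterations = 50 * self.min_iterations
        if self.max_iterations < self.min_iterations:
            raise ValueError("max_iterations must be >= min_iterations")


@dataclass
class OptimizationTrace:
    """Per-iteration history of the global best value and position."""

    best_values: list = field(default_factory=list)
    best_positions: list = field(default_factory=list)

    def append(self, value: float, position: np.ndarray) -> None:
        self.best_values.append(float(value))
        self.best_positions.append(np.array(position, copy=True))

    def __len__(self) -> int:
        return len(self.best_values)


@dataclass
class SwarmState:
    positions: np.ndarray  # (S, n)
    velocities: np.ndarray  # (S, n)
    personal_bests: np.ndarray  # (S, n)
    personal_best_values: np.ndarray  # (S,)
    global_best: np.ndarray  # (n,)
    global_best_value: float
    iteration: int = 0


@dataclass
class PSOResult:
    best_position: np.ndarray
    best_value: float
    trace: OptimizationTrace
    iterations: int
    converged: bool


def _evaluate(
    objective: Callable,
    positions: np.ndarray,
    data,
    vectorized: bool,
) -> np.ndarray:
    if vectorized:
        vals = objective(positions, data)
        return np.asarray(vals, dtype=float).reshape(positions.shape[0])
    return np.array([float(objective(x, data)) for x in positions])


def _resample_nonfinite(
    objective, positions, values, bounds, rng, data, vectorized
) -> None:
    """Redraw particles whose objective is non-finite, in place."""
    for _ in range(_RESAMPLE_LIMIT):
        bad = ~np.isfinite(values)
        if not np.any(bad):
            return
        k = int(bad.sum())
        positions[bad] = rng.uniform(bounds.lower, bounds.upper, size=(k, bounds.n))
        values[bad] = _evaluate(objective, positions[bad], data, vectorized)
    if not np.all(np.isfinite(values)):
        raise RuntimeError("objective not finite on search region")


def initialize_swarm(
    objective: Callable,
    bounds: Bounds,
    config: PSOConfig,
    rng: np.random.Generator,
    data=None,
    vectorized: bool = False,
) -> SwarmState:
    """Draw initial positions and velocities uniformly over the region.

    Positions are U(lower, upper) per component; velocities are
    U(-|width|, |width|). Each particle's personal best starts at its initial
    position and the global best is the smallest personal best.
    """
    S, n = config.swarm_size, bounds.n
    positions = rng.uniform(bounds.lower, bounds.upper, size=(S, n))
    velocities = rng.uniform(-bounds.width, bounds.width, size=(S, n))
    values = _evaluate(objective, positions, data, vectorized)
    _resample_nonfinite(objective, positions, values, bounds, rng, data, vectorized)
    best = int(np.argmin(values))
    return SwarmState(
        positions=positions,
        velocities=velocities,
        personal_bests=positions.copy(),
        personal_best_values=values.copy(),
        global_best=positions[best].copy(),
        global_best_value=float(values[best]),
        iteration=0,
    )


def step(
    state: SwarmState,
    objective: Callable,
    bounds: Bounds,
    config: PSOConfig,
    rng: np.random.Generator,
    data=None,
    vectorized: bool = False,
    trace: Optional[OptimizationTrace] = None,
) -> SwarmState:
    """Advance the swarm by one iteration (in place) and append to the trace.

    One scalar pair (r_p, r_g) is drawn per particle per iteration and shared
    across dimensions. Out-of-box positions are replaced by fresh uniform
    draws; velocities are left untouched on replacement.
    """
    S, n = state.positions.shape
    r = rng.uniform(size=(S, 2))
    r_p, r_g = r[:, :1], r[:, 1:]
    state.velocities = (
        config.inertia * state.velocities
        + config.cognitive_accel * r_p * (state.personal_bests - state.positions)
        + config.social_accel * r_g * (state.global_best - state.positions)
    )
    state.positions = state.positions + state.velocities

    escaped = ~bounds.contains(state.positions)
    if np.any(escaped):
        k = int(escaped.sum())
        state.positions[escaped] = rng.uniform(
            bounds.lower, bounds.upper, size=(k, n)
        )

    values = _evaluate(objective, state.positions, data, vectorized)
    _resample_nonfinite(
        objective, state.positions, values, bounds, rng, data, vectorized
    )

    improved = values < state.personal_best_values
    state.personal_bests[improved] = state.positions[improved]
    state.personal_best_values[improved] = values[improved]

    best = int(np.argmin(state.personal_best_values))
    if state.personal_best_values[best] < state.global_best_value:
        state.global_best = state.personal_bests[best].copy()
        state.global_best_value = float(state.personal_best_values[best])

    state.iteration += 1
    if trace is not None:
        trace.append(state.global_best_value, state.global_best)
    return state


def should_stop(trace: OptimizationTrace, config: PSOConfig) -> bool:
    """Variance stop rule over the trailing window of global-best values.

    True once at least ``min_iterations`` have run and the sample variance
    (n-1 denominator) of the last ``ceil(prop * iterations)`` best values is
    at or below ``stop_variance``; also true unconditionally at the
    ``max_iterations`` cap.
    """
    iters = len(trace)
    if iters == 0:
        raise ValueError("trace must be non-empty")
    if iters >= config.max_iterations:
        return True
    if iters < config.min_iterations:
        return False
    window = math.ceil(config.stop_proportion * iters)
    tail = np.asarray(trace.best_values[-window:])
    var = float(np.var(tail, ddof=1)) if tail.size > 1 else 0.0
    return var <= config.stop_variance


def pso(
    objective: Callable,
    bounds: Bounds | Sequence,
    config: Optional[PSOConfig] = None,
    data=None,
    rng: Optional[np.random.Generator] = None,
    vectorized: bool = False,
) -> PSOResult:
    """Minimize ``objective(params, data)`` over a box.

    Parameters
    ----------
    objective
        Callable ``f(params, data) -> float``; when fitting by maximum
        likelihood this is the negative log-likelihood and ``data`` the
        sample. With ``vectorized=True`` it must accept an (S, n) array of
        row-wise parameter vectors and return S values.
    bounds
        A :class:`Bounds` or an ``(lower, upper)`` pair.
    config
        Swarm settings; defaults to :class:`PSOConfig()`.
    rng
        Optional generator; otherwise built from ``config.seed``.

    Returns
    -------
    PSOResult with the best position/value, full best-value trace, iteration
    count and a convergence flag (False only when the iteration cap fired).
    """
    if not isinstance(bounds, Bounds):
        bounds = Bounds(*bounds)
    if config is None:
        config = PSOConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)

    trace = OptimizationTrace()
    state = initialize_swarm(objective, bounds, config, rng, data, vectorized)

    converged = True
    while True:
        step(state, objective, bounds, config, rng, data, vectorized, trace)
        if should_stop(trace, config):
            break
    if len(trace) >= config.max_iterations:
        window = math.ceil(config.stop_proportion * len(trace))
        tail = np.asarray(trace.best_values[-window:])
        var = float(np.var(tail, ddof=1)) if tail.size > 1 else 0.0
        converged = var <= config.stop_variance

    return PSOResult(
        best_position=state.global_best.copy(),
        best_value=state.global_best_value,
        trace=trace,
        iterations=len(trace),
        converged=converged,
    )
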