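"""Multimodal benchmark objectives with known global minima.

Six classic test functions used to validate the swarm optimizer: a
univariate trigonometric objective, Easom, Cross-in-tray, Hoelder table,
Rastrigin and Himmelblau. Each is registered with its conventional search
box and the list of known global minimizers, so tests and the CLI can check
any optimizer run against ground truth. All evaluators are vectorized over
the last axis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, List, Tuple

import numpy as np

from .pso import Bounds

__all__ = [
    "BenchmarkFunction",
    "REGISTRY",
    "get_benchmark",
    "evaluate_trig",
    "evaluate_easom",
    "evaluate_cross_in_tray",
    "evaluate_holder",
    "evaluate_rastrigin",
    "evaluate_himmelblau",
]


def evaluate_trig(theta):
    """-(6 + theta^2 sin(14 theta)); global minimum -11.5618 at theta=2.3605."""
    theta = np.asarray(theta, dtype=float)
    return -(6.0 + theta**2 * np.sin(14.0 * theta))


def evaluate_easom(x, y):
    """Easom needle function, minimized at (pi, pi) with value -1."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return -np.cos(x) * np.cos(y) * np.exp(-((x - np.pi) ** 2 + (y - np.pi) ** 2))


def evaluate_cross_in_tray(x, y):
    """Cross-in-tray function; four symmetric minima of value -2.06261.

    The inner exponent |100 - sqrt(x^2+y^2)/pi| stays near 100 on the usual
    box, so the exponential is large (~e^100) but well inside float64 range;
    the magnitude is damped by the outer 0.1 power before any further
    arithmetic.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    expo = np.abs(100.0 - np.sqrt(x**2 + y**2) / np.pi)
    inner = np.abs(np.sin(x) * np.sin(y)) * np.exp(expo)
    return -0.0001 * (inner + 1.0) ** 0.1


def evaluate_holder(x, y):
    """Hoelder table function; four symmetric minima of value -19.2085."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    expo = np.abs(1.0 - np.sqrt(x**2 + y**2) / np.pi)
    return -np.abs(np.sin(x) * np.cos(y) * np.exp(expo))


def evaluate_rastrigin(x, A: float = 10.0):
    """Rastrigin function A*n + sum(x_i^2 - A cos(2 pi x_i)) over the last axis."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    return A * x.shape[-1] + np.sum(x**2 - A * np.cos(2.0 * np.pi * x), axis=-1)


def evaluate_himmelblau(x, y):
    """Himmelblau function (x^2+y-11)^2 + (x+y^2-7)^2; four zero-valued minima."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return (x**2 + y - 11.0) ** 2 + (x + y**2 - 7.0) ** 2


@dataclass(frozen=True)
class BenchmarkFunction:
    """A named objective with its search box and known global minima."""

    name: str
    arity: int
    default_bounds: Bounds
    known_minima: List[Tuple[Tuple[float, ...], float]]
    _func: Callable[[np.ndarray], np.ndarray]

    def evaluate(self, point) -> np.ndarray:
        """Evaluate at a point (length-arity vector) or (..., arity) array."""
        point = np.atleast_1d(np.asarray(point, dtype=float))
        if point.shape[-1] != self.arity:
            raise ValueError(
                f"{self.name} expects points of dimension {self.arity}"
            )
        return self._func(point)

    def objective(self, params, data=None) -> np.ndarray:
        """PSO-compatible signature; ``data`` is ignored."""
        return self.evaluate(params)

    @property
    def minimum_value(self) -> float:
        return self.known_minima[0][1]


def _box(lo: float, hi: float, n: int) -> Bounds:
    return Bounds(np.full(n, lo), np.full(n, hi))


REGISTRY: Dict[str, BenchmarkFunction] = {}


def _register(name, arity, bounds, minima, func):
    REGISTRY[name] = BenchmarkFunction(name, arity, bounds, minima, func)


_register(
    "trig",
    1,
    _box(-2.5, 2.5, 1),
    [((2.3605,), -11.5618)],
    lambda p: evaluate_trig(p[..., 0]),
)
_register(
    "easom",
    2,
    _box(-10.0, 10.0, 2),
    [((np.pi, np.pi), -1.0)],
    lambda p: evaluate_easom(p[..., 0], p[..., 1]),
)
_register(
    "cross_in_tray",
    2,
    _box(-10.0, 10.0, 2),
    [
        ((1.34941, 1.34941), -2.06261),
        ((1.34941, -1.34941), -2.06261),
        ((-1.34941, 1.34941), -2.06261),
        ((-1.34941, -1.34941), -2.06261),
    ],
    lambda p: evaluate_cross_in_tray(p[..., 0], p[..., 1]),
)
_register(
    "holder",
    2,
    _box(-10.0, 10.0, 2),
    [
        ((8.05502, 9.66459), -19.2085),
        ((-8.05502, 9.66459), -19.2085),
        ((8.05502, -9.66459), -19.2085),
        ((-8.05502, -9.66459), -19.2085),
    ],
    lambda p: evaluate_holder(p[..., 0], p[..., 1]),
)
_register(
    "rastrigin",
    2,
    _box(-5.12, 5.12, 2),
    [((0.0, 0.0), 0.0)],
    evaluate_rastrigin,
)
_register(
    "himmelblau",
    2,
    _box(-5.0, 5.0, 2),
    [
        ((3.0, 2.0), 0.0),
        ((-2.805118, 3.131312), 0.0),
        ((-3.779310, -3.283186), 0.0),
        ((3.584428, -1.848126), 0.0),
    ],
    lambda p: evaluate_himmelblau(p[..., 0], p[..., 1]),
)


def get_benchmark(name: str) -> BenchmarkFunction:
    try:
        return REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown benchmark {name!r}; choose from {sorted(REGISTRY)}"
        ) from None
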