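"""Empirical scaled total-time-on-test (TTT) transform.

For a positive sample with order statistics X_(1) <= ... <= X_(n), the
empirical scaled TTT transform is

    T(i/n) = [sum_{k<=i} X_(k) + (n - i) X_(i)] / sum_k X_(k),

plotted against i/n. Its shape diagnoses the hazard rate: the curve hugs
the diagonal for a constant hazard, is concave for an increasing hazard,
convex for a decreasing one, and changes curvature once for bathtub or
upside-down-bathtub hazards. The curve is scale invariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["TTTCurve", "ttt_curve"]


@dataclass(frozen=True)
class TTTCurve:
    """Ordered (i/n, T(i/n)) pairs, including the origin (0, 0)."""

    abscissae: np.ndarray
    ordinates: np.ndarray

    @property
    def n(self) -> int:
        return self.abscissae.size - 1

    def concavity_summary(self) -> np.ndarray:
        """Heuristic sign pattern of second differences of the curve.

        +1 where locally convex, -1 where concave, 0 where flat. Only a
        rough visual aid — hazard-shape classification is a judgement call,
        not a decision rule.
        """
        d2 = np.diff(self.ordinates, n=2)
        return np.sign(np.where(np.abs(d2) < 1e-12, 0.0, d2))

    def plot(self, ax=None, **kwargs):
        """TTT plot with the diagonal reference line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.abscissae, self.ordinates, **kwargs)
        ax.plot([0, 1], [0, 1], linestyle="--", color="grey", linewidth=1)
        ax.set_xlabel("i/n")
        ax.set_ylabel("T(i/n)")
        ax.set_xlim(0, 1)
        ax.set_ylim(0, 1.02)
        return ax


def ttt_curve(data) -> TTTCurve:
    """Compute the empirical scaled TTT curve of a positive sample.

    Requires n >= 2 strictly positive values (lifetimes); ties are allowed.
    """
    x = np.sort(np.asarray(data, dtype=float))
    n = x.size
    if n < 2:
        raise ValueError("at least two observations are required")
    if np.any(x <= 0) or not np.all(np.isfinite(x)):
        raise ValueError("TTT transform requires strictly positive lifetimes")
    total = float(x.sum())
    i = np.arange(1, n + 1)
    T = (np.cumsum(x) + (n - i) * x) / total
    return TTTCurve(
        abscissae=np.concatenate(([0.0], i / n)),
        ordinates=np.concatenate(([0.0], T)),
    )
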