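"""Plain-text data reading and result serialization.

Input samples are one value per row, optionally a single-column CSV with a
header. Fit and optimizer results serialize to JSON, Monte Carlo clouds and
TTT curves to CSV. Numbers are written at 12 significant digits so written
reports are byte-stable.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .fitting import LifetimeFitResults
from .mc import MCResult
from .pso import PSOResult
from .ttt import TTTCurve

__all__ = ["read_data", "write_report", "trace_to_csv"]


def read_data(path) -> np.ndarray:
    """Read a univariate sample: one numeric value per row.

    A single non-numeric first row is treated as a header and skipped.
    Any other non-numeric row is an error reported with its line number.
    """
    lines = Path(path).read_text().splitlines()
    rows = [(i + 1, ln.strip().rstrip(",")) for i, ln in enumerate(lines)]
    rows = [(no, ln) for no, ln in rows if ln]
    if not rows:
        raise ValueError(f"{path}: file contains no data")
    start = 0
    try:
        float(rows[0][1])
    except ValueError:
        start = 1  # header row
    values = []
    for no, ln in rows[start:]:
        try:
            values.append(float(ln))
        except ValueError:
            raise ValueError(f"{path}: non-numeric value {ln!r} on line {no}")
    if not values:
        raise ValueError(f"{path}: file contains no numeric data")
    return np.asarray(values, dtype=float)


def _round12(obj):
    if isinstance(obj, dict):
        return {k: _round12(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round12(v) for v in obj]
    if isinstance(obj, (float, np.floating)):
        return float(f"{float(obj):.12g}")
    if isinstance(obj, (int, np.integer, bool)):
        return int(obj) if not isinstance(obj, bool) else obj
    if isinstance(obj, np.ndarray):
        return _round12(obj.tolist())
    return obj


def write_report(result, path) -> None:
    """Write a result to disk: JSON for fits and optimizer runs, CSV for
    Monte Carlo clouds and TTT curves."""
    path = Path(path)
    if isinstance(result, LifetimeFitResults):
        path.write_text(json.dumps(_round12(result.to_dict()), indent=2) + "\n")
    elif isinstance(result, PSOResult):
        payload = {
            "best_position": result.best_position,
            "best_value": result.best_value,
            "iterations": result.iterations,
            "converged": result.converged,
        }
        path.write_text(json.dumps(_round12(payload), indent=2) + "\n")
    elif isinstance(result, MCResult):
        frame = pd.DataFrame(
            result.positions,
            columns=[f"x{j + 1}" for j in range(result.positions.shape[1])],
        )
        frame["value"] = result.values
        frame.to_csv(path, index=False, float_format="%.12g")
    elif isinstance(result, TTTCurve):
        pd.DataFrame(
            {"i_over_n": result.abscissae, "T": result.ordinates}
        ).to_csv(path, index=False, float_format="%.12g")
    else:
        raise TypeError(f"cannot serialize {type(result).__name__}")


def trace_to_csv(result: PSOResult, path) -> None:
    """Dump the per-iteration global-best history."""
    pd.DataFrame(
        {
            "iteration": np.arange(1, result.iterations + 1),
            "best_value": result.trace.best_values,
        }
    ).to_csv(path, index=False, float_format="%.12g")
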