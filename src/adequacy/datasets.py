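"""Packaged example data."""

from __future__ import annotations

from importlib import resources

import numpy as np

__all__ = ["load_flood"]


def load_flood() -> np.ndarray:
    """Twenty maximum flood levels of the Susquehanna River at Harrisburg.

    Annual maxima in millions of cubic feet per second, a classic unit-
    interval sample commonly fitted with Kumaraswamy-type distributions.
    """
    text = resources.files("adequacy.data").joinpath("flood.txt").read_text()
    return np.array([float(line) for line in text.split()])
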