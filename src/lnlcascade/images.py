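"""PNG input/output with luminance calibration.

Displays map digital values to luminance; the calibration scalar (cd/m² per
digital unit at full scale) is a configuration value with no canonical
default, so it is always explicit here.  8- and 16-bit grayscale (or RGB)
PNGs are supported.
"""

from __future__ import annotations

import numpy as np
import imageio.v3 as iio

from .core import Stimulus, vectorize

__all__ = ["read_png", "write_png"]


def read_png(path: str, calibration: float = 1.0) -> Stimulus:
    """Read a PNG and scale digital values by ``calibration`` to cd/m²."""
    arr = np.asarray(iio.imread(path), dtype=float) * calibration
    return vectorize(arr)


def write_png(
    stim: Stimulus | np.ndarray,
    path: str,
    calibration: float = 1.0,
    peak: float | None = None,
    bit_depth: int = 16,
) -> None:
    """Write a stimulus as PNG, dividing by ``calibration`` back to digital
    values; ``peak`` (default: the data maximum) maps to full scale."""
    arr = stim.image() if isinstance(stim, Stimulus) else np.asarray(stim, dtype=float)
    arr = arr / calibration
    top = float(np.max(arr)) if peak is None else peak / calibration
    top = top if top > 0 else 1.0
    full = 2**bit_depth - 1
    digital = np.clip(arr / top, 0.0, 1.0) * full
    dtype = np.uint16 if bit_depth == 16 else np.uint8
    iio.imwrite(path, np.squeeze(digital).astype(dtype))
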