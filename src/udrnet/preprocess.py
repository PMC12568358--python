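"""CT preprocessing chain: Hounsfield windowing, min-max normalization, and
depth cropping.

The chain mirrors routine radiological preparation of lung CT for learning:
a window (width WW, level WL) maps the Hounsfield range of interest linearly
onto [0, 255] and saturates outside it; min-max normalization then rescales
each volume to [0, 1]; finally, slices at the start and end of the axial
sequence that carry no lung are cropped (e.g. 192x192x208 -> 192x192x192).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core_io import IntensityDomain, Volume

__all__ = ["WindowSpec", "window", "normalize", "crop_depth"]

log = logging.getLogger(__name__)

#: Conventional lung window; the width/level are configurable everywhere.
DEFAULT_LUNG_WINDOW_WL = -600.0
DEFAULT_LUNG_WINDOW_WW = 1500.0


@dataclass(frozen=True)
class WindowSpec:
    """A Hounsfield display window: width ``ww`` (> 0) and level ``wl``."""

    ww: float = DEFAULT_LUNG_WINDOW_WW
    wl: float = DEFAULT_LUNG_WINDOW_WL

    def __post_init__(self):
        if self.ww <= 0:
            raise ValueError(f"window width must be positive, got {self.ww}")


def window(v: Volume, spec: WindowSpec = WindowSpec()) -> Volume:
    """Map Hounsfield intensities through the (WW, WL) window onto [0, 255].

    Values at or below ``WL - WW/2`` map to 0, values at or above
    ``WL + WW/2`` map to 255, and the interior maps linearly:
    ``255 * (I - (WL - WW/2)) / WW``.  The map is monotone non-decreasing.
    """
    if v.intensity_domain is not IntensityDomain.HOUNSFIELD:
        raise ValueError(
            f"window() expects a hounsfield volume, got {v.intensity_domain.value}"
        )
    lo = spec.wl - spec.ww / 2.0
    data = np.asarray(v.data, dtype=np.float64)
    out = np.clip(255.0 * (data - lo) / spec.ww, 0.0, 255.0)
    return v.with_data(out.astype(np.float32), IntensityDomain.WINDOWED_0_255)


def normalize(v: Volume) -> Volume:
    """Min-max normalize to [0, 1]: ``(I - min I) / (max I - min I)``.

    A constant volume has no contrast to rescale; it is returned as all
    zeros with a warning rather than raising, so batch pipelines survive
    degenerate inputs.
    """
    data = np.asarray(v.data, dtype=np.float64)
    lo, hi = float(data.min()), float(data.max())
    if hi == lo:
        log.warning("normalize(): constant volume (value %g); returning zeros", lo)
        out = np.zeros_like(data)
    else:
        out = (data - lo) / (hi - lo)
    return v.with_data(out.astype(np.float32), IntensityDomain.NORMALIZED_0_1)


def crop_depth(v: Volume, target_depth: int) -> Volume:
    """Crop the last array axis to ``target_depth`` slices.

    The removed slices are split as evenly as possible between the start and
    the end of the axis (the initial and final images of the CT sequence);
    an odd remainder removes the extra slice from the end.  Retained voxels
    are preserved bitwise.
    """
    current = v.data.shape[-1]
    if target_depth > current:
        raise ValueError(
            f"target depth {target_depth} exceeds current depth {current}"
        )
    if target_depth < 1:
        raise ValueError(f"target depth must be >= 1, got {target_depth}")
    remove = current - target_depth
    front = remove // 2
    return v.with_data(v.data[..., front:front + target_depth])
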