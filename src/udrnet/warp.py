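"""Spatial-transformer resampling: apply a displacement field to an image.

The warp follows the pull (backward) convention: the output value at voxel
``i`` is the moving image sampled at ``i + DVF(i)``, with trilinear
interpolation at non-integer positions (nearest-neighbour for masks) and
edge clamping for sample positions outside the volume.  This module is the
NumPy/SciPy inference path; training uses the differentiable twin
:func:`udrnet._autodiff.grid_sample_trilinear`, which implements the same
map (the test suite asserts the two agree).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .core_io import DisplacementField, Mask, Volume

__all__ = ["compose_identity_grid", "warp_image", "warp_mask"]


def compose_identity_grid(shape: tuple[int, int, int]) -> np.ndarray:
    """The identity coordinate grid: value at voxel ``i`` is ``i`` itself,
    shape ``(3, D, H, W)``, in voxel units."""
    if len(shape) != 3 or any(int(s) < 1 for s in shape):
        raise ValueError(f"shape must be 3 positive dims, got {shape}")
    return np.indices(shape, dtype=np.float32)


def _sample_coords(shape, dvf: DisplacementField) -> np.ndarray:
    if dvf.spatial_shape != tuple(shape):
        raise ValueError(
            f"image shape {tuple(shape)} != DVF spatial shape {dvf.spatial_shape}"
        )
    return compose_identity_grid(shape).astype(np.float64) + dvf.data.astype(np.float64)


def warp_image(moving: Volume, dvf: DisplacementField, mode: str = "trilinear") -> Volume:
    """Resample ``moving`` at ``i + DVF(i)`` for every output voxel ``i``.

    ``mode`` is ``"trilinear"`` (images) or ``"nearest"`` (labels).  Sample
    positions outside the volume clamp to the nearest edge voxel, so no
    synthetic zeros leak into the similarity loss at boundaries.
    """
    if mode not in ("trilinear", "nearest"):
        raise ValueError(f"unknown interpolation mode {mode!r}")
    coords = _sample_coords(moving.shape, dvf)
    order = 1 if mode == "trilinear" else 0
    # scipy's mode="nearest" replicates the border voxel == coordinate clamping
    out = ndimage.map_coordinates(
        np.asarray(moving.data, dtype=np.float64), coords, order=order, mode="nearest"
    )
    return moving.with_data(out.astype(np.float32))


def warp_mask(mask: Mask, dvf: DisplacementField) -> Mask:
    """Warp a binary mask with nearest-neighbour sampling (stays binary)."""
    coords = _sample_coords(mask.shape, dvf)
    out = ndimage.map_coordinates(mask.data, coords, order=0, mode="nearest")
    return Mask(out.astype(np.uint8))
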