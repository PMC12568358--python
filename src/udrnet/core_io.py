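"""Domain containers and NIfTI I/O for volumes, masks and displacement fields.

Conventions fixed here and used everywhere else in the package:

* array axis order is ``(D, H, W)``, 0-based voxel indices;
* a displacement field (DVF) is stored in memory as ``(3, D, H, W)`` with
  component order matching the array axes, in **voxels of the fixed grid**
  (not millimetres), and on disk as a 4D NIfTI with the vector dimension
  last (``D x H x W x 3``);
* the warp convention is "pull": the value of the warped image at voxel
  ``i`` is the moving image sampled at ``i + DVF(i)``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "IntensityDomain",
    "Volume",
    "Mask",
    "DisplacementField",
    "ImagePair",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "read_dvf",
    "write_dvf",
]


class IntensityDomain(enum.Enum):
    HOUNSFIELD = "hounsfield"
    WINDOWED_0_255 = "windowed_0_255"
    NORMALIZED_0_1 = "normalized_0_1"


@dataclass
class Volume:
    """A 3D scalar image with voxel spacing and origin metadata."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    intensity_domain: IntensityDomain = IntensityDomain.HOUNSFIELD

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(
                f"Volume data must have rank 3, got rank {self.data.ndim}"
            )
        if any(s < 1 for s in self.data.shape):
            raise ValueError(f"Volume axes must have length >= 1, got {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if self.intensity_domain is IntensityDomain.NORMALIZED_0_1:
            lo, hi = float(self.data.min()), float(self.data.max())
            if lo < -1e-6 or hi > 1 + 1e-6:
                raise ValueError(
                    f"normalized_0_1 volume has values outside [0,1]: [{lo}, {hi}]"
                )
        elif self.intensity_domain is IntensityDomain.WINDOWED_0_255:
            lo, hi = float(self.data.min()), float(self.data.max())
            if lo < -1e-4 or hi > 255 + 1e-4:
                raise ValueError(
                    f"windowed_0_255 volume has values outside [0,255]: [{lo}, {hi}]"
                )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def with_data(self, data: np.ndarray, domain: IntensityDomain | None = None) -> "Volume":
        return Volume(data, self.spacing, self.origin,
                      domain if domain is not None else self.intensity_domain)


@dataclass
class Mask:
    """A binary region, same grid as its companion volume."""

    data: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Mask data must have rank 3, got rank {self.data.ndim}")
        vals = np.unique(self.data)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError(f"Mask values must be 0/1, found {vals[:10]}")
        self.data = self.data.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def volume_fraction(self) -> float:
        return float(self.data.mean())


class Interp(enum.Enum):
    TRILINEAR = "trilinear"
    NEAREST = "nearest"


@dataclass
class DisplacementField:
    """Per-voxel 3-vector field, ``(3, D, H, W)``, in voxels of the fixed grid."""

    data: np.ndarray
    interp: Interp = Interp.TRILINEAR

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 4 or self.data.shape[0] != 3:
            raise ValueError(
                f"DVF must have shape (3, D, H, W), got {self.data.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("DVF contains non-finite components")

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    def magnitude(self) -> np.ndarray:
        """Per-voxel Euclidean displacement length, in voxels."""
        return np.sqrt((self.data.astype(np.float64) ** 2).sum(axis=0))


@dataclass
class ImagePair:
    """A fixed/moving pair, optionally with masks and a known true DVF."""

    fixed: Volume
    moving: Volume
    fixed_mask: Mask | None = None
    moving_mask: Mask | None = None
    true_dvf: DisplacementField | None = None
    name: str = field(default="pair")

    def __post_init__(self):
        if self.fixed.shape != self.moving.shape:
            raise ValueError(
                f"fixed shape {self.fixed.shape} != moving shape {self.moving.shape}"
            )
        for m, label in ((self.fixed_mask, "fixed_mask"), (self.moving_mask, "moving_mask")):
            if m is not None and m.shape != self.fixed.shape:
                raise ValueError(f"{label} shape {m.shape} != image shape {self.fixed.shape}")
        if self.true_dvf is not None and self.true_dvf.spatial_shape != self.fixed.shape:
            raise ValueError(
                f"true_dvf spatial shape {self.true_dvf.spatial_shape} != "
                f"fixed shape {self.fixed.shape}"
            )


# -- NIfTI I/O ----------------------------------------------------------------

def _affine(spacing, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    aff[:3, 3] = origin
    return aff


def _load(path) -> nib.Nifti1Image:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such NIfTI file: {path}")
    return nib.load(str(path))


def read_volume(path) -> Volume:
    """Read a 3D NIfTI scalar image.

    The intensity domain is inferred: values already inside [0, 1] are tagged
    ``normalized_0_1``, values inside [0, 255] ``windowed_0_255``, anything
    else (e.g. air at -1000) ``hounsfield``.
    """
    img = _load(path)
    data = np.asarray(img.dataobj, dtype=np.float32)
    if data.ndim != 3:
        raise ValueError(
            f"expected a rank-3 image, got rank {data.ndim} in {path}"
        )
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(o) for o in img.affine[:3, 3])
    lo, hi = float(data.min()), float(data.max())
    if 0 <= lo and hi <= 1:
        domain = IntensityDomain.NORMALIZED_0_1
    elif 0 <= lo and hi <= 255:
        domain = IntensityDomain.WINDOWED_0_255
    else:
        domain = IntensityDomain.HOUNSFIELD
    return Volume(data, spacing, origin, domain)


def write_volume(v: Volume, path) -> None:
    img = nib.Nifti1Image(np.asarray(v.data, dtype=np.float32), _affine(v.spacing, v.origin))
    img.header.set_zooms(v.spacing)
    nib.save(img, str(path))


def read_mask(path) -> Mask:
    img = _load(path)
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a rank-3 mask, got rank {data.ndim} in {path}")
    return Mask((data > 0.5).astype(np.uint8))


def write_mask(m: Mask, path) -> None:
    nib.save(nib.Nifti1Image(m.data.astype(np.uint8), np.eye(4)), str(path))


def read_dvf(path) -> DisplacementField:
    """Read a displacement field stored as a 4D NIfTI (D, H, W, 3)."""
    img = _load(path)
    data = np.asarray(img.dataobj, dtype=np.float32)
    if data.ndim != 4 or data.shape[-1] != 3:
        raise ValueError(
            f"expected a (D,H,W,3) displacement NIfTI, got shape {data.shape} in {path}"
        )
    return DisplacementField(np.ascontiguousarray(np.moveaxis(data, -1, 0)))


def write_dvf(dvf: DisplacementField, path) -> None:
    data = np.ascontiguousarray(np.moveaxis(dvf.data.astype(np.float32), 0, -1))
    nib.save(nib.Nifti1Image(data, np.eye(4)), str(path))
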