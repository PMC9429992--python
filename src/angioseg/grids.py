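"""Volumetric containers and NIfTI I/O.

Conventions used throughout the package: 0-based voxel indices, axis order
(X, Y, Z), channels last for one-hot maps. Voxel spacing is in millimetres
and is taken from / written to the NIfTI header, which is authoritative.
Inputs are assumed brain-extracted and affinely co-registered; this package
performs neither step (see :func:`assert_preregistered`).
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "Volume", "LabelMap", "OneHotMap", "read_volume", "write_volume",
    "read_label_map", "write_label_map", "preprocess_intensity",
    "to_one_hot", "one_hot_argmax", "assert_preregistered",
]


@dataclasses.dataclass
class Volume:
    """A 3D scalar grid with per-axis voxel spacing in mm."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Volume data must be 3D, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")

    @property
    def shape(self):
        return self.data.shape


@dataclasses.dataclass
class LabelMap:
    """A binary vessel map on the same grid as its paired Volume."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"LabelMap data must be 3D, got ndim={self.data.ndim}")
        vals = np.unique(self.data)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"LabelMap must be binary, found values {vals[:10]}")
        self.data = self.data.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")

    @property
    def shape(self):
        return self.data.shape


@dataclasses.dataclass
class OneHotMap:
    """(X, Y, Z, 2) map; channel 0 = background, channel 1 = vessel."""

    data: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 4 or self.data.shape[-1] != 2:
            raise ValueError(
                f"OneHotMap must be (X,Y,Z,2), got shape {self.data.shape}")

    @property
    def shape(self):
        return self.data.shape

    @property
    def vessel(self) -> np.ndarray:
        return self.data[..., 1]

    @property
    def background(self) -> np.ndarray:
        return self.data[..., 0]


def _load(path) -> nib.Nifti1Image:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such NIfTI file: {path}")
    return nib.load(str(path))


def read_volume(path) -> Volume:
    """Read a 3D NIfTI scan; spacing comes from the header zooms."""
    img = _load(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(
            f"{path}: expected a 3D image, got shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    if any(s <= 0 for s in spacing):
        raise ValueError(f"{path}: non-positive voxel spacing {spacing}")
    return Volume(data=data, spacing=spacing, affine=img.affine)


def read_label_map(path) -> LabelMap:
    v = read_volume(path)
    return LabelMap(data=v.data, spacing=v.spacing, affine=v.affine)


def _affine_for(vol) -> np.ndarray:
    if vol.affine is not None:
        return vol.affine
    aff = np.diag(list(vol.spacing) + [1.0])
    return aff


def write_volume(vol: Volume | LabelMap, path) -> None:
    img = nib.Nifti1Image(np.asarray(vol.data), _affine_for(vol))
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


write_label_map = write_volume


def preprocess_intensity(v: Volume, clip_lo: float = 0.0,
                         clip_hi: float = 350.0,
                         brain_mask: np.ndarray | None = None) -> Volume:
    """Clip and contrast-normalize a TOF-MRA scan into [0, 1].

    Pipeline: clip to [clip_lo, clip_hi]; linearly rescale between the 10th
    and 99th intensity percentiles of the (masked) scan; clip the rescaled
    values to [0, 1]; divide by the resulting maximum so the output maximum
    is exactly 1. The fixed default window [0, 350] suppresses the bright
    noise tail typical of TOF-MRA.
    """
    if not clip_lo < clip_hi:
        raise ValueError(f"clip_lo must be < clip_hi, got ({clip_lo}, {clip_hi})")
    x = np.clip(np.asarray(v.data, dtype=np.float64), clip_lo, clip_hi)
    sample = x[np.asarray(brain_mask, bool)] if brain_mask is not None else x
    p10, p99 = np.percentile(sample, [10, 99])
    if p99 == p10:
        raise ValueError(
            f"degenerate intensity percentiles: p10 == p99 == {p10}; "
            "cannot rescale a constant-intensity volume")
    x = (x - p10) / (p99 - p10)
    np.clip(x, 0.0, 1.0, out=x)
    m = x.max()
    if m > 0:
        x /= m
    return Volume(data=x.astype(np.float32), spacing=v.spacing, affine=v.affine)


def to_one_hot(m: LabelMap | np.ndarray) -> OneHotMap:
    """One-hot encode a binary map: channel 0 background, channel 1 vessel."""
    data = m.data if isinstance(m, LabelMap) else np.asarray(m)
    vals = np.unique(data)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError(f"one-hot encoding requires a binary map, got {vals[:10]}")
    vessel = data.astype(np.float32)
    return OneHotMap(data=np.stack([1.0 - vessel, vessel], axis=-1))


def one_hot_argmax(m: OneHotMap, spacing=(1.0, 1.0, 1.0)) -> LabelMap:
    """Binarize a (possibly soft) one-hot map by channel argmax."""
    return LabelMap(data=(m.data[..., 1] > m.data[..., 0]).astype(np.uint8),
                    spacing=spacing)


def assert_preregistered(pre_registered: bool) -> None:
    """Documented hook: upstream brain extraction and affine registration are
    external; callers acknowledge it with ``pre_registered=True``."""
    if not pre_registered:
        raise ValueError(
            "inputs must be brain-extracted and affinely co-registered "
            "upstream; pass pre_registered=True to acknowledge")
    warnings.warn("assuming inputs are brain-extracted and co-registered",
                  stacklevel=2)
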