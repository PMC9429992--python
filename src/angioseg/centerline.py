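"""Rendering centerline + radius annotations into dense tubular label maps.

Vessel annotations arrive as ordered (x, y, z, r) records: voxel coordinates
(possibly fractional) and a radius. Because such annotations carry no local
vessel direction, each point is rendered as an isotropic sphere in physical
(mm) space; a chain of overlapping spheres along a sampled centerline then
approximates a tube. The raw union of spheres is scalloped, so a refinement
pass (Gaussian smoothing, re-thresholding and ellipsoidal erosion) restores
tubular morphology.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import LabelMap

logger = logging.getLogger(__name__)

__all__ = [
    "CenterlineAnnotation", "read_centerlines", "write_centerlines",
    "render_spheres", "refine_tubular", "ellipsoid_element",
]


@dataclasses.dataclass
class CenterlineAnnotation:
    """Ordered (x, y, z, r) records; radii in mm, coordinates in voxels.

    ``vessel_id`` groups points belonging to one vessel when available.
    """

    points: np.ndarray                      # (N, 4) float: x, y, z, r
    vessel_id: np.ndarray | None = None     # (N,) int, optional

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=np.float64))
        if self.points.size == 0:
            self.points = self.points.reshape(0, 4)
        if self.points.shape[1] != 4:
            raise ValueError(
                f"points must be (N, 4) [x, y, z, r], got {self.points.shape}")
        if (self.points[:, 3] < 0).any():
            raise ValueError("negative radius in centerline annotation")
        if self.vessel_id is not None:
            self.vessel_id = np.asarray(self.vessel_id, dtype=np.int64)
            if self.vessel_id.shape[0] != self.points.shape[0]:
                raise ValueError("vessel_id length mismatch")

    def __len__(self):
        return self.points.shape[0]


def read_centerlines(path, radius_unit: str,
                     spacing: tuple[float, float, float] | None = None
                     ) -> CenterlineAnnotation:
    """Read a CSV/TSV table with columns x, y, z, r (optional vessel_id).

    ``radius_unit`` must be explicitly "mm" or "voxel"; stored annotations do
    not declare it. Radii given in voxels are converted to mm using the mean
    of the supplied per-axis spacing.
    """
    if radius_unit not in ("mm", "voxel"):
        raise ValueError(f"radius_unit must be 'mm' or 'voxel', got {radius_unit!r}")
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    missing = {"x", "y", "z", "r"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing centerline columns {sorted(missing)}")
    pts = df[["x", "y", "z", "r"]].to_numpy(dtype=np.float64)
    if radius_unit == "voxel":
        if spacing is None:
            raise ValueError("spacing required to convert voxel radii to mm")
        pts[:, 3] *= float(np.mean(spacing))
    vid = df["vessel_id"].to_numpy() if "vessel_id" in df.columns else None
    return CenterlineAnnotation(points=pts, vessel_id=vid)


def write_centerlines(ann: CenterlineAnnotation, path) -> None:
    df = pd.DataFrame(ann.points, columns=["x", "y", "z", "r"])
    if ann.vessel_id is not None:
        df["vessel_id"] = ann.vessel_id
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=sep, index=False)


def render_spheres(ann: CenterlineAnnotation,
                   shape: tuple[int, int, int],
                   spacing: tuple[float, float, float]) -> LabelMap:
    """Render each record as a sphere of radius r (mm) about its point.

    A voxel is set when its center lies within Euclidean distance r of the
    point, measured in mm; anisotropic grids therefore produce per-axis
    scaled (ellipsoidal) voxel footprints. The voxel containing the point is
    always set, so degenerate radii below the voxel size still leave a mark.
    Points whose spheres extend beyond the grid are clipped with a warning.
    """
    shape = tuple(int(s) for s in shape)
    sp = np.asarray(spacing, dtype=np.float64)
    out = np.zeros(shape, dtype=np.uint8)
    clipped = 0
    for x, y, z, r in ann.points:
        c = np.array([x, y, z])
        # half-extent of the sphere in voxels per axis
        ext = np.maximum(np.ceil(r / sp).astype(int), 0)
        lo = np.floor(c).astype(int) - ext
        hi = np.floor(c).astype(int) + ext + 1
        if (lo < 0).any() or (hi > shape).any():
            clipped += 1
        lo_c = np.clip(lo, 0, shape)
        hi_c = np.clip(hi, 0, shape)
        if (hi_c <= lo_c).any():
            continue
        ix = np.arange(lo_c[0], hi_c[0])
        iy = np.arange(lo_c[1], hi_c[1])
        iz = np.arange(lo_c[2], hi_c[2])
        dx = (ix - c[0]) * sp[0]
        dy = (iy - c[1]) * sp[1]
        dz = (iz - c[2]) * sp[2]
        d2 = (dx[:, None, None] ** 2 + dy[None, :, None] ** 2
              + dz[None, None, :] ** 2)
        out[lo_c[0]:hi_c[0], lo_c[1]:hi_c[1], lo_c[2]:hi_c[2]] |= (
            d2 <= r * r).astype(np.uint8)
        # the voxel that contains the point is always part of the vessel
        home = np.round(c).astype(int)
        if (home >= 0).all() and (home < shape).all():
            out[tuple(home)] = 1
    if clipped:
        logger.warning("%d centerline sphere(s) clipped at the grid boundary",
                       clipped)
    return LabelMap(data=out, spacing=tuple(sp))


def ellipsoid_element(radii: tuple[int, int, int] = (1, 1, 1)) -> np.ndarray:
    """Ellipsoidal structuring element with integer semi-axes in voxels.

    Semi-axes (1, 1, 1) give the 3x3x3 discrete unit ball (6-connected
    cross), the smallest erosion kernel that removes sphere-chain scallops
    without destroying radius-1 vessels.
    """
    rx, ry, rz = (max(int(r), 0) for r in radii)
    ix = np.arange(-rx, rx + 1)
    iy = np.arange(-ry, ry + 1)
    iz = np.arange(-rz, rz + 1)
    d = ((ix[:, None, None] / max(rx, 1)) ** 2
         + (iy[None, :, None] / max(ry, 1)) ** 2
         + (iz[None, None, :] / max(rz, 1)) ** 2)
    return d <= 1.0


def refine_tubular(raw: LabelMap, smooth_sigma: float = 1.0,
                   erosion_element: np.ndarray | None = None) -> LabelMap:
    """Smooth a sphere-union rendering into tubular morphology.

    Gaussian smoothing of the binary map followed by re-thresholding at 0.5
    fuses the scallops between consecutive spheres; a morphological erosion
    with an ellipsoidal element then counteracts the dilation introduced by
    sphere overlap. The output never grows beyond the smoothing support of
    the input.
    """
    if erosion_element is None:
        erosion_element = ellipsoid_element((1, 1, 1))
    if any(k > s for k, s in zip(erosion_element.shape, raw.shape)):
        raise ValueError(
            f"erosion element {erosion_element.shape} larger than map "
            f"{raw.shape}")
    smoothed = ndimage.gaussian_filter(raw.data.astype(np.float64),
                                       sigma=smooth_sigma)
    binary = smoothed >= 0.5
    eroded = ndimage.binary_erosion(binary, structure=erosion_element)
    return LabelMap(data=eroded.astype(np.uint8), spacing=raw.spacing,
                    affine=raw.affine)
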