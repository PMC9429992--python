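"""Random 3D patch sampling, joint augmentation, and sliding-window tiling.

Full scans (e.g. 448x448x128) exceed practical memory for dense 3D networks,
so training draws random fixed-size patches (default 80^3) from the brain's
tight bounding box, and inference tiles the zero-padded scan with
non-overlapping windows of the same size and reassembles the outputs.

Morphological augmentations (flip, rotation, zoom) are applied with
identical parameters to scan, ground truth and prior so voxel-level pairing
is preserved; intensity augmentation (multiplicative gamma noise) touches
the scan only.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy import ndimage

from .grids import LabelMap, OneHotMap, Volume, to_one_hot
from .prior import PriorAtlas, prior_patch

logger = logging.getLogger(__name__)

__all__ = [
    "PatchSpec", "TrainingSample", "AugmentConfig", "brain_bbox",
    "sample_patch", "augment", "sliding_windows", "assemble", "extract_patch",
]

DEFAULT_PATCH = (80, 80, 80)


@dataclasses.dataclass(frozen=True)
class PatchSpec:
    """Half-open sub-grid [origin, origin + size)."""

    origin: tuple[int, int, int]
    size: tuple[int, int, int] = DEFAULT_PATCH

    def __post_init__(self):
        if any(o < 0 for o in self.origin):
            raise ValueError(f"negative patch origin {self.origin}")
        if any(s <= 0 for s in self.size):
            raise ValueError(f"non-positive patch size {self.size}")

    @property
    def slices(self):
        return tuple(slice(o, o + s) for o, s in zip(self.origin, self.size))


@dataclasses.dataclass
class TrainingSample:
    scan_patch: Volume
    gt_patch: OneHotMap
    prior_patch: OneHotMap
    spec: PatchSpec
    seed: int


def brain_bbox(scan: Volume) -> tuple[np.ndarray, np.ndarray]:
    """Tight bounding box (lo, hi exclusive) of nonzero scan voxels."""
    nz = np.nonzero(scan.data)
    if len(nz[0]) == 0:
        return np.zeros(3, dtype=int), np.asarray(scan.shape, dtype=int)
    lo = np.array([a.min() for a in nz])
    hi = np.array([a.max() + 1 for a in nz])
    return lo, hi


def sample_patch(scan: Volume, gt: LabelMap, prior: PriorAtlas,
                 rng_seed: int, size: tuple[int, int, int] = DEFAULT_PATCH
                 ) -> TrainingSample:
    """Draw one training patch with origin uniform inside the brain bbox.

    If the bounding box is smaller than the patch along an axis, all three
    volumes are padded symmetrically with zeros (with a warning) so at least
    one valid origin exists. Reproducible given ``rng_seed``.
    """
    if scan.shape != gt.shape or scan.shape != prior.shape:
        raise ValueError(
            f"grid mismatch: scan {scan.shape}, gt {gt.shape}, "
            f"prior {prior.shape}")
    size = np.asarray(size, dtype=int)
    lo, hi = brain_bbox(scan)
    scan_data, gt_data, counts = scan.data, gt.data, prior.counts
    need = np.maximum(size - (hi - lo), 0)
    if need.any():
        logger.warning("brain bbox %s smaller than patch %s; zero-padding",
                       tuple(hi - lo), tuple(size))
        before = need // 2
        after = need - before
        padspec = tuple((int(b), int(a)) for b, a in zip(before, after))
        scan_data = np.pad(scan_data, padspec)
        gt_data = np.pad(gt_data, padspec)
        counts = np.pad(counts, padspec)
        hi = hi + before + after
        # origins are expressed on the padded grid
    rng = np.random.default_rng(rng_seed)
    max_origin = hi - size
    origin = tuple(int(rng.integers(l, m + 1)) for l, m in zip(lo, max_origin))
    spec = PatchSpec(origin=origin, size=tuple(int(s) for s in size))
    sl = spec.slices
    padded_prior = PriorAtlas(counts=counts, n_subjects=prior.n_subjects,
                              min_fraction=prior.min_fraction,
                              spacing=prior.spacing)
    return TrainingSample(
        scan_patch=Volume(data=scan_data[sl], spacing=scan.spacing),
        gt_patch=to_one_hot(gt_data[sl]),
        prior_patch=prior_patch(padded_prior, spec),
        spec=spec, seed=rng_seed)


@dataclasses.dataclass
class AugmentConfig:
    """Probabilities and ranges of the joint augmentations.

    The system is not very sensitive to these values; defaults below are the
    package's standing choices.
    """

    p_flip: float = 0.5
    p_rotate: float = 0.5
    max_angle_deg: float = 15.0
    p_zoom: float = 0.3
    zoom_range: tuple[float, float] = (0.9, 1.1)
    p_gamma: float = 0.3
    gamma_concentration: float = 50.0   # multiplicative noise ~ Gamma(a, 1/a)

    def __post_init__(self):
        for p in (self.p_flip, self.p_rotate, self.p_zoom, self.p_gamma):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"augmentation probability {p} outside [0, 1]")


def _zoom_to_shape(arr, factor, order, target_shape, fill=0.0):
    z = ndimage.zoom(arr, factor, order=order, mode="constant", cval=fill,
                     grid_mode=False)
    out = np.full(target_shape, fill, dtype=arr.dtype if order == 0 else np.float32)
    # center crop / center place
    src_lo, dst_lo, ext = [], [], []
    for s, t in zip(z.shape, target_shape):
        if s >= t:
            off = (s - t) // 2
            src_lo.append(off); dst_lo.append(0); ext.append(t)
        else:
            off = (t - s) // 2
            src_lo.append(0); dst_lo.append(off); ext.append(s)
    src = tuple(slice(a, a + e) for a, e in zip(src_lo, ext))
    dst = tuple(slice(a, a + e) for a, e in zip(dst_lo, ext))
    out[dst] = z[src]
    return out


def augment(sample: TrainingSample, cfg: AugmentConfig, rng_seed: int
            ) -> TrainingSample:
    """Apply one random augmentation draw jointly to scan/GT/prior.

    Interpolation is linear for all channels; the ground truth is
    re-binarized at 0.5 afterwards so the binary one-hot invariant survives
    resampling without the aliasing of nearest-neighbour lookup.
    """
    rng = np.random.default_rng(rng_seed)
    scan = np.asarray(sample.scan_patch.data)
    gt_v = sample.gt_patch.vessel.copy()
    pri_v = sample.prior_patch.vessel.copy()
    shape = scan.shape

    if rng.random() < cfg.p_flip:                       # left-right flip
        scan = scan[::-1]; gt_v = gt_v[::-1]; pri_v = pri_v[::-1]

    if rng.random() < cfg.p_rotate:
        angle = rng.uniform(-cfg.max_angle_deg, cfg.max_angle_deg)
        axes = [(0, 1), (0, 2), (1, 2)][rng.integers(0, 3)]
        scan = ndimage.rotate(scan, angle, axes=axes, reshape=False, order=1,
                              mode="constant")
        pri_v = ndimage.rotate(pri_v, angle, axes=axes, reshape=False, order=1,
                               mode="constant")
        gt_v = ndimage.rotate(gt_v, angle, axes=axes, reshape=False, order=1,
                              mode="constant")

    if rng.random() < cfg.p_zoom:
        factor = rng.uniform(*cfg.zoom_range)
        if not cfg.zoom_range[0] <= factor <= cfg.zoom_range[1]:
            raise ValueError(f"zoom factor {factor} outside {cfg.zoom_range}")
        scan = _zoom_to_shape(scan, factor, 1, shape)
        pri_v = _zoom_to_shape(pri_v, factor, 1, shape)
        gt_v = _zoom_to_shape(gt_v, factor, 1, shape)

    if rng.random() < cfg.p_gamma:                      # scan only
        a = cfg.gamma_concentration
        noise = rng.gamma(a, 1.0 / a, size=shape).astype(np.float32)
        scan = scan * noise

    gt_bin = (gt_v >= 0.5).astype(np.float32)
    pri_v = np.clip(pri_v, 0.0, 1.0)
    return TrainingSample(
        scan_patch=Volume(data=np.ascontiguousarray(scan),
                          spacing=sample.scan_patch.spacing),
        gt_patch=OneHotMap(np.stack([1.0 - gt_bin, gt_bin], axis=-1)),
        prior_patch=OneHotMap(np.stack([1.0 - pri_v, pri_v], axis=-1)),
        spec=sample.spec, seed=rng_seed)


def sliding_windows(shape: tuple[int, int, int],
                    size: tuple[int, int, int] = DEFAULT_PATCH
                    ) -> list[PatchSpec]:
    """Non-overlapping tiling of the zero-padded volume.

    The volume is conceptually padded up to the next multiple of ``size``
    per axis; windows are pairwise disjoint and their union covers the
    padded grid exactly.
    """
    if any(s <= 0 for s in shape):
        raise ValueError(f"non-positive shape {shape}")
    counts = [int(np.ceil(s / w)) for s, w in zip(shape, size)]
    specs = []
    for i in range(counts[0]):
        for j in range(counts[1]):
            for k in range(counts[2]):
                specs.append(PatchSpec(
                    origin=(i * size[0], j * size[1], k * size[2]),
                    size=tuple(size)))
    return specs


def extract_patch(data: np.ndarray, spec: PatchSpec, fill=0.0) -> np.ndarray:
    """Extract a patch, zero-filling where the window exceeds the volume."""
    out_shape = spec.size + data.shape[3:]
    out = np.full(out_shape, fill, dtype=data.dtype)
    src, dst = [], []
    for o, s, n in zip(spec.origin, spec.size, data.shape[:3]):
        ext = max(min(o + s, n) - o, 0)
        src.append(slice(o, o + ext))
        dst.append(slice(0, ext))
    if all(s.stop > s.start for s in src):
        out[tuple(dst)] = data[tuple(src)]
    return out


def assemble(patch_outputs: list[tuple[PatchSpec, OneHotMap]],
             shape: tuple[int, int, int]) -> OneHotMap:
    """Reassemble sliding-window outputs into a full map, cropping padding.

    Every window from ``sliding_windows(shape)`` must appear exactly once.
    """
    expected = {(s.origin, s.size) for s in sliding_windows(
        shape, patch_outputs[0][0].size)} if patch_outputs else set()
    seen = set()
    size = patch_outputs[0][0].size
    padded = tuple(int(np.ceil(s / w)) * w for s, w in zip(shape, size))
    full = np.zeros(padded + (2,), dtype=np.float32)
    for spec, out in patch_outputs:
        key = (spec.origin, spec.size)
        if key in seen:
            raise ValueError(f"duplicate window {key}")
        if key not in expected:
            raise ValueError(f"window {key} not part of the tiling of {shape}")
        seen.add(key)
        full[spec.slices] = out.data
    if seen != expected:
        raise ValueError(f"missing windows: {sorted(expected - seen)[:5]} ...")
    crop = tuple(slice(0, s) for s in shape)
    return OneHotMap(data=full[crop])
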