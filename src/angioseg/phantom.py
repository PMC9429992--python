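"""Synthetic TOF-MRA-like tubular phantoms.

The generator emulates the data regime the segmentation method assumes:
bright, sparse, branching tubular trees (vessels occupy well under 5% of
the volume) on a darker tissue background, with paired centerline + radius
annotations and a dense ground truth rendered by the same sphere renderer
used for real annotations — so every module in the package is exercisable
without any external dataset.

Geometry is a tapering random walk with stochastic branching; intensity is
a two-level model (background / vessel on the pre-clip scanner scale, so
the default [0, 350] clip window is meaningful) with partial-volume
Gaussian blur and multiplicative gamma-distributed noise.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy import ndimage

from .centerline import CenterlineAnnotation, render_spheres
from .grids import LabelMap, Volume

logger = logging.getLogger(__name__)

__all__ = ["PhantomSpec", "generate_phantom", "generate_cohort"]


@dataclasses.dataclass
class PhantomSpec:
    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (0.5, 0.5, 0.5)
    n_trees: int = 3
    branching: float = 0.05          # branch probability per step
    radius_range: tuple[float, float] = (1.0, 4.0)   # voxels
    tortuosity: float = 0.25         # std of per-step direction jitter
    vessel_fraction_cap: float = 0.05
    background_level: float = 80.0   # pre-clip scanner units
    vessel_level: float = 300.0
    noise_shape: float = 100.0       # gamma concentration; std ~ 1/sqrt(a)
    blur_sigma: float = 0.7          # partial-volume blur, voxels
    max_steps: int = 400
    seed: int = 0

    def __post_init__(self):
        if any(s < 32 for s in self.shape):
            raise ValueError(f"phantom shape must be >= 32 per axis, "
                             f"got {self.shape}")
        if not 0.0 < self.vessel_fraction_cap <= 1.0:
            raise ValueError("vessel_fraction_cap must be in (0, 1]")


def _unit(v):
    n = np.linalg.norm(v)
    return v / n if n > 0 else np.array([1.0, 0.0, 0.0])


def _grow_tree(rng: np.random.Generator, spec: PhantomSpec,
               root=None, direction=None, r0=None, step=0.5):
    """Random-walk branching centerline; returns (points, r_mm) arrays.

    Radii taper multiplicatively along each branch, so they are monotone
    non-increasing from root to tip; children start at 0.8 of the parent
    radius.
    """
    shape = np.asarray(spec.shape, dtype=float)
    mm = float(np.mean(spec.spacing))
    margin = 4.0
    if root is None:
        root = rng.uniform(margin, shape - margin)
    if direction is None:
        direction = _unit(rng.normal(size=3))
    if r0 is None:
        r0 = rng.uniform(*spec.radius_range)
    points = []
    stack = [(np.asarray(root, float), np.asarray(direction, float),
              float(r0), 0)]
    taper = 0.995
    min_r = 0.8
    while stack:
        pos, d, r, depth = stack.pop()
        for _ in range(spec.max_steps):
            points.append((pos[0], pos[1], pos[2], r * mm))
            d = _unit(d + rng.normal(scale=spec.tortuosity, size=3))
            pos = pos + d * step
            r *= taper
            if ((pos < margin).any() or (pos > shape - margin).any()
                    or r < min_r):
                break
            if depth < 3 and rng.random() < spec.branching:
                child_dir = _unit(d + rng.normal(scale=0.8, size=3))
                stack.append((pos.copy(), child_dir, r * 0.8, depth + 1))
    return np.asarray(points, dtype=np.float64)


def _render_trees(trees, spec: PhantomSpec):
    pts = np.concatenate([t for t in trees if len(t)], axis=0) if trees else \
        np.zeros((0, 4))
    vid = np.concatenate([np.full(len(t), i, dtype=np.int64)
                          for i, t in enumerate(trees) if len(t)]) if trees \
        else None
    ann = CenterlineAnnotation(points=pts, vessel_id=vid)
    gt = render_spheres(ann, spec.shape, spec.spacing)
    return ann, gt


def _grow_capped(rng, spec: PhantomSpec, seeds_trees):
    """Grow trees one by one; stop adding once the vessel cap would be hit."""
    cap_voxels = spec.vessel_fraction_cap * np.prod(spec.shape)
    kept = []
    occupied = np.zeros(spec.shape, dtype=np.uint8)
    for tree in seeds_trees:
        _, gt_one = _render_trees([tree], spec)
        new_occ = occupied | gt_one.data
        if new_occ.sum() > cap_voxels and kept:
            logger.warning(
                "vessel fraction cap %.3f reached; generated %d of %d trees",
                spec.vessel_fraction_cap, len(kept), len(seeds_trees))
            break
        if new_occ.sum() > cap_voxels:
            logger.warning("single tree exceeds the vessel cap; kept anyway")
        occupied = new_occ
        kept.append(tree)
    return kept


def _scan_from_gt(rng, gt: LabelMap, spec: PhantomSpec) -> Volume:
    ideal = np.where(gt.data > 0, spec.vessel_level,
                     spec.background_level).astype(np.float64)
    blurred = ndimage.gaussian_filter(ideal, sigma=spec.blur_sigma)
    noise = rng.gamma(spec.noise_shape, 1.0 / spec.noise_shape,
                      size=gt.shape)
    return Volume(data=(blurred * noise).astype(np.float32),
                  spacing=spec.spacing)


def generate_phantom(spec: PhantomSpec
                     ) -> tuple[Volume, LabelMap, CenterlineAnnotation]:
    """One phantom: (scan, dense GT, centerline annotation). Seeded."""
    rng = np.random.default_rng(spec.seed)
    trees = [_grow_tree(rng, spec) for _ in range(spec.n_trees)]
    trees = _grow_capped(rng, spec, trees)
    ann, gt = _render_trees(trees, spec)
    scan = _scan_from_gt(rng, gt, spec)
    return scan, gt, ann


def generate_cohort(n: int, spec: PhantomSpec, shared_geometry: float = 0.5
                    ) -> list[tuple[Volume, LabelMap, CenterlineAnnotation]]:
    """A registered cohort sharing a common trunk.

    ``shared_geometry`` is the fraction of each member's trees that come
    from a cohort-wide trunk grown from ``spec.seed``; the remainder are
    member-specific. At 1.0 all members are identical; at 0.0 they are
    independent. The shared trunk makes the occupancy prior informative:
    trunk voxels reach count n while member-unique branches stay at count 1.
    """
    if n < 2:
        raise ValueError("a cohort needs n >= 2 members")
    if not 0.0 <= shared_geometry <= 1.0:
        raise ValueError("shared_geometry must be in [0, 1]")
    n_shared = int(round(shared_geometry * spec.n_trees))
    trunk_rng = np.random.default_rng(spec.seed)
    trunk = [_grow_tree(trunk_rng, spec) for _ in range(n_shared)]
    cohort = []
    for member in range(n):
        m_rng = np.random.default_rng(
            np.random.SeedSequence([spec.seed, member + 1]))
        own = [_grow_tree(m_rng, spec)
               for _ in range(spec.n_trees - n_shared)]
        trees = _grow_capped(m_rng, spec, trunk + own)
        ann, gt = _render_trees(trees, spec)
        scan = _scan_from_gt(m_rng, gt, spec)
        cohort.append((scan, gt, ann))
    return cohort
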