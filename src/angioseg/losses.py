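"""Segmentation and adversarial losses.

Three terms drive training:

* **Generalized Dice loss** — Dice overlap with per-class weights
  ``w_l = 1 / (sum_n R_ln)^2``, inversely proportional to squared class
  prevalence so the scarce vessel class dominates the gradient.
* **Centerline Dice loss** — one minus the harmonic mean of topology
  precision ``|S_P ∩ R| / |S_P|`` and topology sensitivity
  ``|S_R ∩ P| / |S_R|``, where skeletons are extracted by iterative soft
  morphological thinning (min/max pooling with a 3x3x3 cube); on the binary
  ground truth the same iteration is exactly hard thinning. Preserves
  centerlines and bifurcations that plain overlap losses ignore.
* **Feature-matching adversarial loss** — the mean absolute difference
  between discriminator features of the prediction-masked and GT-masked
  scan, averaged over the discriminator's L scales. The generator minimizes
  it, the discriminator maximizes it; there is no real/fake logit.

The combined objective is the unweighted sum of the three, each averaged
over the batch. All functions build autodiff graphs; the ``*_value``
wrappers evaluate them on plain numpy inputs in float64.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import nn
from .nn import Tensor

__all__ = [
    "LossValues", "SoftSkeleton", "gdl", "gdl_value", "soft_skeletonize",
    "soft_skeleton_array", "cld_loss", "cld_loss_value", "masked_input",
    "feature_loss", "combined_loss",
]

_SPATIAL = (2, 3, 4)


@dataclasses.dataclass
class LossValues:
    """Scalar loss components of one batch (total = gdl + cld + mae)."""

    gdl: float
    cld: float
    mae: float
    t_prec: float = float("nan")
    t_sens: float = float("nan")

    @property
    def total(self) -> float:
        return self.gdl + self.cld + self.mae


@dataclasses.dataclass
class SoftSkeleton:
    data: np.ndarray
    iterations: int


def _as_tensor(x, channels_last=False) -> Tensor:
    if isinstance(x, Tensor):
        return x
    arr = np.asarray(getattr(x, "data", x), dtype=np.float64)
    if channels_last:
        if arr.ndim == 4:          # (X,Y,Z,2) -> (1,2,X,Y,Z)
            arr = np.moveaxis(arr, -1, 0)[None]
        elif arr.ndim == 5:        # (N,X,Y,Z,2) -> (N,2,X,Y,Z)
            arr = np.moveaxis(arr, -1, 1)
    else:
        if arr.ndim == 3:          # (X,Y,Z) -> (1,1,X,Y,Z)
            arr = arr[None, None]
        elif arr.ndim == 4:        # (N,X,Y,Z) -> (N,1,X,Y,Z)
            arr = arr[:, None]
    return nn.constant(arr)


def gdl(R: Tensor, P: Tensor, eps: float = 1e-5) -> Tensor:
    """Generalized Dice loss on (N, 2, X, Y, Z) one-hot tensors.

    The per-class weight is 1 / (class volume)^2; a class absent from the
    reference would make the weight infinite, so the squared volume is
    replaced by ``eps`` for empty classes only — non-degenerate inputs are
    evaluated exactly.
    """
    if R.shape != P.shape:
        raise ValueError(f"shape mismatch: R {R.shape} vs P {P.shape}")
    r_vol = nn.tsum(R, axis=_SPATIAL)                       # (N, 2), constant
    w_val = r_vol.value ** 2
    w = nn.constant(1.0 / np.where(w_val > 0, w_val, eps))
    inter = nn.tsum(R * P, axis=_SPATIAL)
    total = nn.tsum(R + P, axis=_SPATIAL)
    num = nn.tsum(w * inter, axis=1)                        # (N,)
    den = nn.tsum(w * total, axis=1)
    per_sample = nn.constant(np.ones(R.shape[0])) - nn.scale(num / den, 2.0)
    return nn.tmean(per_sample)


def gdl_value(R, P, eps: float = 1e-5) -> float:
    """Evaluate the generalized Dice loss on channels-last numpy one-hots."""
    return float(gdl(_as_tensor(R, channels_last=True),
                     _as_tensor(P, channels_last=True), eps=eps).value)


def _soft_erode(t: Tensor) -> Tensor:
    """Grey erosion with the 6-neighbour cross: the minimum over the three
    axis-aligned length-3 max-pools of the negated map."""
    e = [nn.neg(nn.max_pool_axis(nn.neg(t), ax)) for ax in range(3)]
    return nn.minimum(nn.minimum(e[0], e[1]), e[2])


def _soft_open(t: Tensor) -> Tensor:
    return nn.max_pool3_same(_soft_erode(t))


def soft_skeletonize(m: Tensor, k: int) -> Tensor:
    """Iterative soft thinning (k rounds of erode/open/residual-accumulate).

    Erosion uses the 6-neighbour cross while dilation uses the full 3x3x3
    cube — the asymmetric pair that keeps the fixed points of the iteration
    thin one-voxel structures. On values in [0, 1] the skeleton is voxelwise
    <= the input; on binary input with k at least the maximal tube radius
    the result is a thin medial structure. Differentiable everywhere min/max
    pooling is.
    """
    if k < 1:
        raise ValueError(f"skeleton iterations must be >= 1, got {k}")
    img = m
    skel = nn.relu(img - _soft_open(img))
    for _ in range(k):
        img = _soft_erode(img)
        delta = nn.relu(img - _soft_open(img))
        skel = skel + nn.relu(delta - skel * delta)
    return skel


def soft_skeleton_array(m: np.ndarray, k: int = 10) -> SoftSkeleton:
    """Numpy-facing soft skeleton of a 3D map in [0, 1]."""
    t = soft_skeletonize(_as_tensor(np.asarray(getattr(m, "data", m))), k)
    return SoftSkeleton(data=t.value[0, 0], iterations=k)


def cld_loss(Rv: Tensor, Pv: Tensor, k: int = 10, eps: float = 1e-8) -> Tensor:
    """Centerline Dice loss, 1 - clDice, on (N, 1, X, Y, Z) vessel maps.

    The prediction's skeleton is computed softly; the ground truth is
    binary, for which the same iteration reduces to hard thinning.
    Intersections are voxelwise product sums; 0/0 cases degrade to loss 1
    through the eps guards.
    """
    if Rv.shape != Pv.shape:
        raise ValueError(f"shape mismatch: Rv {Rv.shape} vs Pv {Pv.shape}")
    s_p = soft_skeletonize(Pv, k)
    s_r = soft_skeletonize(Rv, k)
    eps_t = nn.constant(np.full(Rv.shape[0], eps, dtype=Rv.value.dtype))
    tp_num = nn.tsum(s_p * Rv, axis=(1, 2, 3, 4))
    tp_den = nn.tsum(s_p, axis=(1, 2, 3, 4)) + eps_t
    ts_num = nn.tsum(s_r * Pv, axis=(1, 2, 3, 4))
    ts_den = nn.tsum(s_r, axis=(1, 2, 3, 4)) + eps_t
    t_prec = tp_num / tp_den
    t_sens = ts_num / ts_den
    cl = nn.scale(t_prec * t_sens, 2.0) / (t_prec + t_sens + eps_t)
    loss = nn.constant(np.ones(Rv.shape[0])) - cl
    return nn.tmean(loss)


def cld_loss_value(Rv, Pv, k: int = 10) -> float:
    """Evaluate 1 - clDice on numpy vessel maps, with exact 0/0 -> 1 guard."""
    R = _as_tensor(Rv)
    P = _as_tensor(Pv)
    s_p = soft_skeletonize(P, k).value
    s_r = soft_skeletonize(R, k).value
    sp_sum, sr_sum = s_p.sum(), s_r.sum()
    if sp_sum == 0 or sr_sum == 0:
        return 1.0
    t_prec = (s_p * R.value).sum() / sp_sum
    t_sens = (s_r * P.value).sum() / sr_sum
    if t_prec + t_sens == 0:
        return 1.0
    return float(1.0 - 2.0 * t_prec * t_sens / (t_prec + t_sens))


def masked_input(x: Tensor, M: Tensor) -> Tensor:
    """Voxelwise product of the scan with a (soft) vessel mask."""
    if x.shape != M.shape:
        raise ValueError(f"shape mismatch: x {x.shape} vs mask {M.shape}")
    return x * M


def feature_loss(x: Tensor, Pv: Tensor, Rv: Tensor, discriminator) -> Tensor:
    """Multiscale L1 feature-matching loss.

    Per discriminator scale, the mean absolute difference between feature
    grids of the prediction-masked and GT-masked scan; averaged over the L
    scales. The mean (not sum) keeps the loss scale independent of feature
    map size.
    """
    feats_p = discriminator(masked_input(x, Pv))
    feats_r = discriminator(masked_input(x, Rv))
    if len(feats_p) != len(feats_r):
        raise ValueError("discriminator returned differing feature lists")
    terms = []
    for fp, fr in zip(feats_p, feats_r):
        if fp.shape != fr.shape:
            raise ValueError(
                f"feature shape mismatch between passes: {fp.shape} vs {fr.shape}")
        terms.append(nn.tmean(nn.tabs(fp - fr)))
    total = terms[0]
    for t in terms[1:]:
        total = total + t
    return nn.scale(total, 1.0 / len(terms))


def combined_loss(gdl_term: Tensor, cld_term: Tensor,
                  mae_term: Tensor | None = None) -> Tensor:
    """Unweighted sum of the loss terms (equal contributions)."""
    total = gdl_term + cld_term
    if mae_term is not None:
        total = total + mae_term
    return total
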