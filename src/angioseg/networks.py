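"""Segmentation generator and multiscale feature-extractor discriminator.

The generator is a four-level 3D U-Net over the scan patch with a parallel
U-Net over the anatomical prior patch; anatomical attention gates combine
the two feature streams at five sites (three encoder skips, the bottleneck,
and the final decoder scale), amplifying scan features at locations the
prior marks as vessel-likely. The output is a per-voxel two-channel softmax
(background / vessel).

The discriminator is a purely convolutional hierarchy of five stride-2
scales with leaky-rectified activations and no real/fake head: its feature
maps, tapped once per scale, feed the feature-matching adversarial loss, so
it is a learned multiscale statistic of vessel-masked scan appearance.

Both networks are built on the package's own autodiff engine (``.nn``).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from . import nn
from .grids import OneHotMap, Volume
from .nn import Tensor

__all__ = [
    "GeneratorConfig", "DiscriminatorConfig", "AttentionGate", "Generator",
    "Discriminator", "generator_forward", "discriminator_features",
    "save_checkpoint", "load_generator", "load_discriminator",
]


@dataclasses.dataclass
class GeneratorConfig:
    levels: int = 4
    base_channels: int = 16
    use_prior: bool = True
    use_gates: bool = True
    prior_encoder_only: bool = False
    norm: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.levels < 2:
            raise ValueError("generator needs at least 2 levels")

    @property
    def n_gates(self) -> int:
        # (levels - 1) encoder skips + bottleneck + final decoder scale
        return self.levels + 1 if (self.use_prior and self.use_gates) else 0


@dataclasses.dataclass
class DiscriminatorConfig:
    scales: int = 5
    base_channels: int = 16
    seed: int = 0

    def __post_init__(self):
        if self.scales < 1:
            raise ValueError("discriminator needs at least 1 scale")


class AttentionGate(nn.Module):
    """Anatomical attention gate combining scan and prior feature streams.

    Each branch passes through a 1x1x1 convolution into a joint width; their
    placewise sum and product are concatenated with both projections and
    mixed by a joint 1x1x1 convolution whose sigmoid output is the per-voxel
    weight map in [0, 1] multiplied into the scan features. The most recent
    weight map is kept on ``last_weights`` for inspection.
    """

    def __init__(self, c_scan: int, c_prior: int, c_joint: int,
                 rng: np.random.Generator):
        self.proj_scan = nn.Conv3d(c_scan, c_joint, 1, rng)
        self.proj_prior = nn.Conv3d(c_prior, c_joint, 1, rng)
        self.joint = nn.Conv3d(4 * c_joint, 1, 1, rng)
        # neutral gate at initialization (alpha = 0.5 everywhere): the gate
        # learns to open/close instead of starting saturated
        self.joint.w.value[:] = 0.0
        self.last_weights: np.ndarray | None = None

    def __call__(self, scan_feats: Tensor, prior_feats: Tensor,
                 force_weights: float | None = None) -> Tensor:
        if scan_feats.shape[2:] != prior_feats.shape[2:]:
            raise ValueError(
                f"gate extent mismatch: scan {scan_feats.shape[2:]} vs "
                f"prior {prior_feats.shape[2:]}")
        q = self.proj_scan(scan_feats)
        p = self.proj_prior(prior_feats)
        combined = nn.concat_channels([q + p, q * p, q, p])
        alpha = nn.sigmoid(self.joint(combined))
        if force_weights is not None:
            alpha = nn.constant(np.full_like(alpha.value, force_weights))
        self.last_weights = alpha.value[:, 0]
        return scan_feats * alpha


class _UNetStream(nn.Module):
    """Encoder(+decoder) stack shared by the scan and prior branches."""

    def __init__(self, cin: int, cfg: GeneratorConfig,
                 rng: np.random.Generator, with_decoder: bool = True):
        b = cfg.base_channels
        self.widths = [b * 2 ** i for i in range(cfg.levels)]
        self.enc = []
        c = cin
        for w in self.widths:
            self.enc.append(nn.ConvBlock(c, w, rng, norm=cfg.norm))
            c = w
        self.dec = []
        if with_decoder:
            for i in range(cfg.levels - 2, -1, -1):
                self.dec.append(nn.ConvBlock(
                    self.widths[i + 1] + self.widths[i], self.widths[i], rng,
                    norm=cfg.norm))
        self.with_decoder = with_decoder

    def encode(self, x: Tensor):
        skips = []
        h = x
        for i, block in enumerate(self.enc):
            h = block(h)
            skips.append(h)
            if i < len(self.enc) - 1:
                h = nn.avg_pool2(h)
        return skips  # skips[-1] is the bottleneck

    def decode(self, skips):
        h = skips[-1]
        outs = []
        for i, block in enumerate(self.dec):
            skip = skips[len(skips) - 2 - i]
            h = block(nn.concat_channels([nn.upsample2(h), skip]))
            outs.append(h)
        return outs  # finest scale last


class Generator(nn.Module):
    """Attention-gated 3D U-Net over (scan, prior) patch pairs."""

    def __init__(self, cfg: GeneratorConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.scan_net = _UNetStream(1, cfg, rng, with_decoder=True)
        self.prior_net = None
        self.gates = []
        if cfg.use_prior:
            self.prior_net = _UNetStream(
                2, cfg, rng, with_decoder=not cfg.prior_encoder_only)
            if cfg.use_gates:
                w = self.scan_net.widths
                # gates 1..levels-1 on encoder skips, one on the bottleneck,
                # one on the final decoder scale
                self.gates = [AttentionGate(w[i], w[i], max(w[i] // 2, 1), rng)
                              for i in range(cfg.levels - 1)]
                self.gates.append(AttentionGate(w[-1], w[-1],
                                                max(w[-1] // 2, 1), rng))
                self.gates.append(AttentionGate(w[0], w[0],
                                                max(w[0] // 2, 1), rng))
        self.head = nn.Conv3d(cfg.base_channels, 2, 1, rng)

    def __call__(self, scan: Tensor, prior: Tensor | None = None) -> Tensor:
        cfg = self.cfg
        ext = scan.shape[2:]
        if any(e % 2 ** (cfg.levels - 1) for e in ext):
            raise ValueError(
                f"patch extent {ext} must be divisible by "
                f"{2 ** (cfg.levels - 1)} for {cfg.levels} levels")
        gated = cfg.use_prior and cfg.use_gates
        if cfg.use_prior:
            if prior is None:
                raise ValueError("this generator config requires a prior patch")
            if prior.shape[2:] != ext:
                raise ValueError(
                    f"scan {ext} and prior {prior.shape[2:]} extents differ")
            p_skips = self.prior_net.encode(prior)
            if self.prior_net.with_decoder:
                p_dec = self.prior_net.decode(p_skips)
                p_final = p_dec[-1]
            else:
                p_final = p_skips[0]
        skips = self.scan_net.encode(scan)
        if gated:
            skips = [self.gates[i](skips[i], p_skips[i])
                     for i in range(cfg.levels - 1)] + [
                self.gates[cfg.levels - 1](skips[-1], p_skips[-1])]
        dec = self.scan_net.decode(skips)
        h = dec[-1]
        if gated:
            h = self.gates[-1](h, p_final)
        return nn.softmax_channel(self.head(h))

    def gate_weight_maps(self):
        """Weight maps of the most recent forward pass, one per gate."""
        return [g.last_weights for g in self.gates]


class Discriminator(nn.Module):
    """Five-scale strided convolutional feature extractor (no logit head)."""

    def __init__(self, cfg: DiscriminatorConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        widths = [min(cfg.base_channels * 2 ** i, 8 * cfg.base_channels)
                  for i in range(cfg.scales)]
        self.convs = []
        c = 1
        for w in widths:
            self.convs.append(nn.Conv3d(c, w, 3, rng, stride=2))
            c = w

    def __call__(self, x: Tensor) -> list[Tensor]:
        feats = []
        h = x
        for conv in self.convs:
            h = nn.leaky_relu(conv(h))
            feats.append(h)
        return feats


def generator_forward(scan_patch: Volume, prior_patch: OneHotMap | None,
                      gen: Generator) -> OneHotMap:
    """Run the generator on one patch pair; returns the soft one-hot map."""
    x = nn.constant(scan_patch.data[None, None].astype(np.float32))
    p = None
    if gen.cfg.use_prior:
        if prior_patch is None:
            raise ValueError("generator config requires a prior patch")
        p = nn.constant(np.moveaxis(prior_patch.data, -1, 0)[None]
                        .astype(np.float32))
    out = gen(x, p)
    return OneHotMap(data=np.moveaxis(out.value[0], 0, -1))


def discriminator_features(masked_patch: Volume | np.ndarray,
                           disc: Discriminator) -> list[np.ndarray]:
    """Feature grids (numpy) of a masked scan patch, one per scale."""
    data = masked_patch.data if isinstance(masked_patch, Volume) else masked_patch
    feats = disc(nn.constant(np.asarray(data, dtype=np.float32)[None, None]))
    return [f.value[0] for f in feats]


def save_checkpoint(model: nn.Module, path, manifest: dict | None = None
                    ) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **model.state_dict())
    if manifest is not None:
        Path(str(path) + ".json").write_text(json.dumps(manifest, indent=2,
                                                        default=str))


def load_generator(path, cfg: GeneratorConfig) -> Generator:
    gen = Generator(cfg)
    with np.load(path) as state:
        gen.load_state_dict(state)
    return gen


def load_discriminator(path, cfg: DiscriminatorConfig) -> Discriminator:
    disc = Discriminator(cfg)
    with np.load(path) as state:
        disc.load_state_dict(state)
    return disc
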