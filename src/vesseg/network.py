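"""Improved 3-D V-Net for vessel segmentation.

A four-level encoder–decoder built from 3x3x3 convolutions with PReLU
activations and residual stages, modified in three ways relative to the
original five-level V-Net:

* the deepest (fifth) encoder level is removed; instead the fourth level
  applies three dilated 3x3x3 convolutions with rates 3, 4 and 5, growing
  the receptive field (effective kernel ``kd = k + (k-1)(r-1)`` = 7, 9, 11)
  without a further loss of spatial resolution;
* every skip connection passes through a pyramid-convolution block:
  parallel 3x3x3 / 5x5x5 / 7x7x7 branches summed, an identity shortcut,
  and a trailing 1x1x1 convolution — mixing local and global context
  before the decoder consumes the skip;
* each decoder level owns a 1x1x1 reduction head used for
  multi-resolution deep supervision (see :mod:`vesseg.supervision`).

Downsampling is a 2x2x2 stride-2 convolution (3 of them), upsampling a
2x2x2 stride-2 transposed convolution (3 of them), channels doubling on
the way down from ``base_channels`` as base*(1, 2, 4, 8) and halving on
the way up.  Dropout (p = 0.5) closes every residual stage.  Input
spatial extents must be divisible by 8.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np

from .nn import (
    Adam,  # noqa: F401  (re-exported for pipeline convenience)
    Conv3d,
    ConvTranspose3d2x,
    Dropout,
    Module,
    PReLU,
    Tensor,
    add,
    concat_channels,
    pad_kernel,
)
from .nn import functional as F

__all__ = [
    "NetworkConfig",
    "PyramidBlock",
    "SegmentationModel",
    "effective_kernel_size",
    "build_model",
    "model_forward",
    "receptive_field_probe",
]

DIVISOR = 8  # three stride-2 stages


@dataclass(frozen=True)
class NetworkConfig:
    in_channels: int = 1
    n_classes: int = 2
    base_channels: int = 16
    n_levels: int = 4
    conv_kernel: int = 3
    dilation_rates: tuple = (3, 4, 5)
    pyramid_kernels: tuple = (3, 5, 7)
    dropout_p: float = 0.5
    dilated_arrangement: str = "series"  # or "parallel"
    pyramid_blocks: bool = True

    def __post_init__(self) -> None:
        if self.n_levels != 4:
            raise ValueError("the architecture is fixed at 4 levels")
        for k in (self.conv_kernel, *self.pyramid_kernels):
            if k % 2 == 0:
                raise ValueError(f"kernels must be odd, got {k}")
        if any(r < 1 for r in self.dilation_rates):
            raise ValueError("dilation rates must be >= 1")
        if self.dilated_arrangement not in ("series", "parallel"):
            raise ValueError("dilated_arrangement must be 'series' or 'parallel'")


def effective_kernel_size(k: int, r: int) -> int:
    """Effective extent of a k-tap convolution dilated by rate r:
    ``kd = k + (k - 1)(r - 1)``."""
    if k % 2 == 0 or k < 1:
        raise ValueError(f"kernel size must be odd and positive, got {k}")
    if r < 1:
        raise ValueError(f"dilation rate must be >= 1, got {r}")
    return k + (k - 1) * (r - 1)


class ResidualStage(Module):
    """n_convs 3x3x3 conv+PReLU, identity shortcut, dropout at the end."""

    def __init__(self, channels: int, n_convs: int, dropout_p: float,
                 rng: np.random.Generator):
        super().__init__()
        self.convs = [Conv3d(channels, channels, 3, rng) for _ in range(n_convs)]
        self.acts = [PReLU(channels) for _ in range(n_convs)]
        self.dropout = Dropout(dropout_p)

    def __call__(self, x: Tensor) -> Tensor:
        h = x
        for conv, act in zip(self.convs, self.acts):
            h = act(conv(h))
        return self.dropout(add(h, x))


class DilatedStage(Module):
    """Encoder level 4: three dilated 3x3x3 convolutions (rates 3, 4, 5).

    Arranged in series by default (receptive fields compose to
    7+9+11-2 = 25 voxels per axis); a parallel arrangement summing the
    three branches is available via the config switch.
    """

    def __init__(self, channels: int, rates: tuple, dropout_p: float,
                 rng: np.random.Generator, arrangement: str = "series"):
        super().__init__()
        self.arrangement = arrangement
        self.rates = tuple(rates)
        self.convs = [Conv3d(channels, channels, 3, rng, dilation=r) for r in rates]
        self.acts = [PReLU(channels) for _ in rates]
        self.dropout = Dropout(dropout_p)

    def __call__(self, x: Tensor) -> Tensor:
        if self.arrangement == "series":
            h = x
            for conv, act in zip(self.convs, self.acts):
                h = act(conv(h))
        else:
            h = self.convs[0](x)
            for conv in self.convs[1:]:
                h = add(h, conv(x))
            h = self.acts[0](h)
        return self.dropout(add(h, x))


class PyramidBlock(Module):
    """Skip-connection block: parallel 3/5/7 branches + shortcut + 1x1x1.

    The three branch kernels are kept as separate parameters but evaluated
    as one 7x7x7 convolution whose kernel is the zero-padded sum of the
    branches — identical arithmetic (the merge is a sum) at one im2col
    instead of three.  With all branch and post weights zero and the post
    convolution set to identity, the block is the identity map.
    """

    def __init__(self, channels: int, kernels: tuple, rng: np.random.Generator):
        super().__init__()
        self.channels = channels
        self.kernels = tuple(sorted(kernels))
        self.branch_weights = []
        self.branch_biases = []
        for k in self.kernels:
            std = np.sqrt(2.0 / (channels * k**3)) / len(self.kernels)
            self.branch_weights.append(
                Tensor(rng.normal(0.0, std, (channels, channels, k, k, k)),
                       requires_grad=True)
            )
            self.branch_biases.append(
                Tensor(np.zeros(channels), requires_grad=True)
            )
        self.post = Conv3d(channels, channels, 1, rng)

    def __call__(self, x: Tensor) -> Tensor:
        if x.data.shape[0] != self.channels:
            raise ValueError(
                f"pyramid block expects {self.channels} channels, got {x.data.shape[0]}"
            )
        kmax = self.kernels[-1]
        w_eff = pad_kernel(self.branch_weights[0], kmax)
        b_eff = self.branch_biases[0]
        for w, b in zip(self.branch_weights[1:], self.branch_biases[1:]):
            w_eff = add(w_eff, pad_kernel(w, kmax))
            b_eff = add(b_eff, b)
        y = F.conv3d(x, w_eff, b_eff)
        return self.post(add(y, x))


class SegmentationModel(Module):
    """The full improved V-Net; forward returns fused + per-path logits."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        c = config.base_channels
        p = config.dropout_p
        self.stem = Conv3d(config.in_channels, c, 3, rng)
        self.stem_act = PReLU(c)
        self.stage1 = ResidualStage(c, 1, p, rng)
        self.down1 = Conv3d(c, 2 * c, 2, rng, stride=2, padding=0)
        self.down1_act = PReLU(2 * c)
        self.stage2 = ResidualStage(2 * c, 2, p, rng)
        self.down2 = Conv3d(2 * c, 4 * c, 2, rng, stride=2, padding=0)
        self.down2_act = PReLU(4 * c)
        self.stage3 = ResidualStage(4 * c, 3, p, rng)
        self.down3 = Conv3d(4 * c, 8 * c, 2, rng, stride=2, padding=0)
        self.down3_act = PReLU(8 * c)
        self.stage4 = DilatedStage(8 * c, config.dilation_rates, p, rng,
                                   config.dilated_arrangement)
        if config.pyramid_blocks:
            self.pyramid1 = PyramidBlock(c, config.pyramid_kernels, rng)
            self.pyramid2 = PyramidBlock(2 * c, config.pyramid_kernels, rng)
            self.pyramid3 = PyramidBlock(4 * c, config.pyramid_kernels, rng)
        else:
            self.pyramid1 = self.pyramid2 = self.pyramid3 = None
        self.up3 = ConvTranspose3d2x(8 * c, 4 * c, rng)
        self.up3_act = PReLU(4 * c)
        self.dec3 = DecoderStage(4 * c, 3, p, rng)
        self.up2 = ConvTranspose3d2x(4 * c, 2 * c, rng)
        self.up2_act = PReLU(2 * c)
        self.dec2 = DecoderStage(2 * c, 2, p, rng)
        self.up1 = ConvTranspose3d2x(2 * c, c, rng)
        self.up1_act = PReLU(c)
        self.dec1 = DecoderStage(c, 1, p, rng)
        # 1x1x1 reduction heads; one per supervised decoder resolution,
        # none on the deepest (1/8) level, each independently initialised
        self.head_full = Conv3d(c, config.n_classes, 1, rng)
        self.head_half = Conv3d(2 * c, config.n_classes, 1, rng)
        self.head_quarter = Conv3d(4 * c, config.n_classes, 1, rng)
        self._dropout_base_seed = seed

    # -- introspection -------------------------------------------------
    def dilated_convs(self) -> list:
        return [m for m in self.modules()
                if isinstance(m, Conv3d) and m.dilation > 1]

    def downsample_ops(self) -> list:
        return [m for m in self.modules()
                if isinstance(m, Conv3d) and m.stride > 1]

    def upsample_ops(self) -> list:
        return [m for m in self.modules() if isinstance(m, ConvTranspose3d2x)]

    def pyramid_parameter_count(self) -> int:
        total = 0
        for blk in (self.pyramid1, self.pyramid2, self.pyramid3):
            if blk is not None:
                total += sum(p.data.size for _, p in blk.named_parameters())
        return total

    def channel_schedule(self) -> list:
        c = self.config.base_channels
        return [c, 2 * c, 4 * c, 8 * c]

    def reseed_dropout(self, seed: int) -> None:
        for i, m in enumerate(m for m in self.modules() if isinstance(m, Dropout)):
            m.reseed(seed + i)

    def summary(self) -> str:
        c = self.config.base_channels
        lines = [
            f"SegmentationModel: {self.n_parameters()} parameters",
            f"  encoder channels: {self.channel_schedule()} at resolutions 1, 1/2, 1/4, 1/8",
            f"  level 4: dilated 3x3x3 convs, rates {self.config.dilation_rates} "
            f"({self.config.dilated_arrangement})",
            f"  skip blocks: pyramid kernels {self.config.pyramid_kernels}"
            if self.config.pyramid_blocks else "  skip blocks: identity (ablated)",
            f"  decoder channels: {[4 * c, 2 * c, c]} with 2x2x2 stride-2 transposed convs",
            f"  supervision heads: 1x1x1 -> {self.config.n_classes} at full, 1/2, 1/4",
            f"  dropout p={self.config.dropout_p} at the end of each residual stage",
        ]
        return "\n".join(lines)

    # -- forward -------------------------------------------------------
    def __call__(self, x) -> tuple:
        if not isinstance(x, Tensor):
            x = Tensor(x)
        if x.data.ndim == 3:
            x = Tensor(x.data[None], requires_grad=x.requires_grad)
        spatial = x.data.shape[1:]
        if any(s % DIVISOR for s in spatial):
            raise ValueError(
                f"spatial extents {spatial} must be divisible by {DIVISOR}"
            )
        e1 = self.stage1(self.stem_act(self.stem(x)))
        e2 = self.stage2(self.down1_act(self.down1(e1)))
        e3 = self.stage3(self.down2_act(self.down2(e2)))
        e4 = self.stage4(self.down3_act(self.down3(e3)))
        s1 = self.pyramid1(e1) if self.pyramid1 else e1
        s2 = self.pyramid2(e2) if self.pyramid2 else e2
        s3 = self.pyramid3(e3) if self.pyramid3 else e3
        f3 = self.dec3(self.up3_act(self.up3(e4)), s3)
        f2 = self.dec2(self.up2_act(self.up2(f3)), s2)
        f1 = self.dec1(self.up1_act(self.up1(f2)), s1)
        logits_full = self.head_full(f1)
        logits_half = self.head_half(f2)
        logits_quarter = self.head_quarter(f3)
        from .supervision import fuse_pyramid

        fused = fuse_pyramid([logits_full, logits_half, logits_quarter])
        return fused, [logits_full, logits_half, logits_quarter]


class DecoderStage(Module):
    """Concat(upsampled, skip) -> convs back to level width -> residual."""

    def __init__(self, channels: int, n_convs: int, dropout_p: float,
                 rng: np.random.Generator):
        super().__init__()
        self.convs = [Conv3d(2 * channels if i == 0 else channels, channels, 3, rng)
                      for i in range(n_convs)]
        self.acts = [PReLU(channels) for _ in range(n_convs)]
        self.dropout = Dropout(dropout_p)

    def __call__(self, up: Tensor, skip: Tensor) -> Tensor:
        h = concat_channels(up, skip)
        for conv, act in zip(self.convs, self.acts):
            h = act(conv(h))
        return self.dropout(add(h, up))


def build_model(config: NetworkConfig = NetworkConfig(), seed: int = 0) -> SegmentationModel:
    """Construct the model; bit-identical across builds with the same seed."""
    return SegmentationModel(config, seed)


def model_forward(model: SegmentationModel, image):
    """Run the model on one volume or a batch.

    ``image`` may be (D,H,W), (C,D,H,W) or a batch (N,C,D,H,W); batches are
    processed volume by volume (training batch size is 1 throughout).
    Returns (fused logits, [full, 1/2, 1/4 path logits]); softmax of the
    fused logits is normalised per voxel.
    """
    arr = image.data if isinstance(image, Tensor) else np.asarray(image)
    if arr.ndim == 5:
        outs = [model(v) for v in arr]
        return [o[0] for o in outs], [o[1] for o in outs]
    return model(image)


def _linearize(module: Module) -> Module:
    lin = copy.deepcopy(module)
    for m in lin.modules():
        if isinstance(m, (Conv3d, ConvTranspose3d2x)) and m.bias is not None:
            m.bias.data[:] = 0.0
        if isinstance(m, PReLU):
            m.slope.data[:] = 1.0  # identity activation
    lin.eval()
    return lin


def receptive_field_probe(stage, in_channels: int = 1, input_extent: int = 33,
                          tol: float = 1e-9):
    """Impulse-response extent (voxels per axis) of a linearized stage.

    ``stage`` is a Module or a sequence of Modules applied in order; a
    linearized copy (identity activations, zero biases, dropout off) is fed
    a centred unit impulse and the bounding box of the non-negligible
    response is measured.
    """
    stages = list(stage) if isinstance(stage, (list, tuple)) else [stage]
    stages = [_linearize(s) for s in stages]
    n = input_extent
    x = np.zeros((in_channels, n, n, n), dtype=np.float32)
    x[:, n // 2, n // 2, n // 2] = 1.0
    h = Tensor(x)
    for s in stages:
        h = s(h)
    resp = np.abs(h.data).max(axis=0)
    thr = max(resp.max() * 1e-6, tol)
    nz = np.nonzero(resp > thr)
    return tuple(int(idx.max() - idx.min()) + 1 for idx in nz)
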