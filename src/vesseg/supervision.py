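"""Multi-resolution deep supervision.

Each of the three upper decoder levels (full, 1/2 and 1/4 resolution)
carries its own independently initialised 1x1x1 reduction head; the
deepest (1/8) level has none.  The per-path logits are fused stepwise —
upsample the 1/4 map trilinearly to 1/2, merge with the 1/2 map, upsample
again and merge with the full map — giving the final prediction, and each
path is additionally supervised against a label downsampled to its own
resolution.  The total objective is the plain unweighted sum

    L_total = L_all + sum_{d=1..3} L_d

with L_all on the fused map; equal weights make the three paths equally
important pieces of one multi-task problem.

The default merge is element-wise addition, which keeps fusion linear;
labels are downsampled by trilinear interpolation (with the half-voxel
centre convention a factor-2 step is exactly 2x2x2 block averaging) and
re-binarised at 0.5, ties counting as foreground to protect thin vessels.
"""

from __future__ import annotations

import numpy as np

from .nn import Tensor, add
from .nn import functional as F
from .volumes import MaskVolume

__all__ = [
    "reduce_head",
    "fuse_pyramid",
    "downsample_labels",
    "total_loss",
    "SupervisionOutputs",
]

N_PATHS = 3


class SupervisionOutputs:
    """Fused logits + the three per-path logits (full, 1/2, 1/4)."""

    def __init__(self, fused: Tensor, path_logits: list):
        if len(path_logits) != N_PATHS:
            raise ValueError(f"expected {N_PATHS} supervised paths, got {len(path_logits)}")
        self.fused = fused
        self.path_logits = list(path_logits)
        full = fused.data.shape[1:]
        for d, lg in enumerate(self.path_logits):
            expect = tuple(s // 2**d for s in full)
            if lg.data.shape[1:] != expect:
                raise ValueError(
                    f"path {d} logits at {lg.data.shape[1:]}, expected {expect}"
                )


def reduce_head(features: Tensor, head) -> Tensor:
    """Apply a 1x1x1 reduction head to decoder features (shape-preserving)."""
    return head(features)


def fuse_pyramid(path_logits: list, merge: str = "add") -> Tensor:
    """Fuse per-path logits coarse-to-fine with trilinear upsampling.

    ``path_logits`` is ordered [full, 1/2, 1/4].  The 1/4 map is upsampled
    to 1/2 and merged, the result upsampled to full and merged again.
    """
    if merge != "add":
        raise NotImplementedError("only additive fusion is implemented")
    if len(path_logits) != N_PATHS:
        raise ValueError(f"expected {N_PATHS} paths, got {len(path_logits)}")
    full, half, quarter = path_logits
    for a, b in ((half, quarter), (full, half)):
        if tuple(a.data.shape[1:]) != tuple(2 * s for s in b.data.shape[1:]):
            raise ValueError("path resolutions must halve stepwise")
    h = add(F.upsample_trilinear_2x(quarter), half)
    return add(F.upsample_trilinear_2x(h), full)


def downsample_labels(mask, factor: int):
    """Downsample a binary mask by trilinear interpolation + 0.5 threshold.

    ``factor`` must be 2 or 4; shape must divide evenly.  With half-voxel
    centre alignment the interpolation reduces to block averaging, and the
    average is thresholded at 0.5 with ties going to foreground.
    Returns the same type that was passed (MaskVolume or array).
    """
    if factor not in (2, 4):
        raise ValueError(f"factor must be 2 or 4, got {factor}")
    is_vol = isinstance(mask, MaskVolume)
    arr = mask.voxels if is_vol else np.asarray(mask)
    if any(s % factor for s in arr.shape):
        raise ValueError(f"shape {arr.shape} not divisible by factor {factor}")
    d, h, w = (s // factor for s in arr.shape)
    blocks = arr.reshape(d, factor, h, factor, w, factor).astype(np.float32)
    avg = blocks.mean(axis=(1, 3, 5))
    out = (avg >= 0.5).astype(np.uint8)
    if is_vol:
        return MaskVolume(out, tuple(s * factor for s in mask.spacing))
    return out


def total_loss(outputs: SupervisionOutputs, mask, loss_fn):
    """Equal-weight deep-supervision objective.

    Returns ``(total, breakdown)`` where ``total`` is a scalar Tensor
    (graph-connected for backprop) and ``breakdown`` maps term names to
    float values: the fused-map loss ``all`` plus one term per supervised
    path at its own label resolution.
    """
    g_full = np.asarray(getattr(mask, "voxels", mask), dtype=np.float64)
    if g_full.shape != outputs.fused.data.shape[1:]:
        raise ValueError(
            f"mask shape {g_full.shape} != fused logits {outputs.fused.data.shape[1:]}"
        )
    targets = [g_full, downsample_labels(g_full.astype(np.uint8), 2).astype(np.float64),
               downsample_labels(g_full.astype(np.uint8), 4).astype(np.float64)]
    total = F.loss_bridge(outputs.fused, g_full, loss_fn)
    breakdown = {"all": total.item()}
    for d, (lg, tgt) in enumerate(zip(outputs.path_logits, targets), start=1):
        term = F.loss_bridge(lg, tgt, loss_fn)
        breakdown[f"path{d}"] = term.item()
        total = add(total, term)
    breakdown["total"] = total.item()
    return total, breakdown
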