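"""Training, inference and evaluation orchestration.

Training follows the published recipe: Adam at learning rate 1e-4, batch
size 1, dropout 0.5, the deep-supervision objective of
:mod:`vesseg.supervision` with a selectable loss family, and k-fold
cross-validation utilities for evaluation.  Every random choice (model
init, dropout, patch sampling, fold assignment) derives from explicit
seeds, so a config + seed pair reproduces a run bit for bit in
single-threaded deterministic mode.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from .losses import get_loss
from .metrics import MetricsReport, aggregate_folds, evaluate_masks
from .network import (
    DIVISOR,
    NetworkConfig,
    SegmentationModel,
    build_model,
)
from .nn import Adam
from .nn.functional import softmax_channels
from .postprocess import filter_small_components
from .supervision import SupervisionOutputs, total_loss
from .volumes import CTVolume, MaskVolume, ProbabilityVolume

__all__ = [
    "TrainConfig",
    "RunManifest",
    "kfold_split",
    "train",
    "predict",
    "compare_losses",
    "cross_validate",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class TrainConfig:
    optimizer: str = "adam"
    learning_rate: float = 1e-4
    batch_size: int = 1
    dropout: float = 0.5
    max_steps: int = 300
    patch_size: tuple = (48, 48, 48)
    rng_seed: int = 0
    loss: str = "tversky"
    loss_params: dict = field(default_factory=lambda: {"alpha": 0.3, "beta": 0.7})
    k_folds: int = 10
    val_volumes: int = 1
    eval_every: int = 50
    postprocess_min_volume: float | None = 180.0

    def __post_init__(self) -> None:
        if self.optimizer != "adam":
            raise ValueError("only the Adam optimizer is supported")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if any(s % DIVISOR for s in self.patch_size):
            raise ValueError(f"patch_size must be divisible by {DIVISOR}")
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")


@dataclass
class RunManifest:
    """Everything needed to re-run and audit an experiment."""

    train_config: dict
    network_config: dict
    seed: int
    train_ids: list
    val_ids: list
    loss_curve: list = field(default_factory=list)  # per-step term breakdowns
    val_history: list = field(default_factory=list)  # (step, mean val dice)
    best_step: int = -1
    final_metrics: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.as_dict(), fh, indent=2)


def kfold_split(ids: list, k: int, seed: int = 0) -> list:
    """Disjoint folds with sizes differing by at most 1; seeded shuffle."""
    ids = list(ids)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(ids):
        raise ValueError(f"k={k} exceeds number of ids ({len(ids)})")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    return [[ids[j] for j in order[i::k]] for i in range(k)]


def _patch_corner(shape, patch, rng):
    return tuple(int(rng.integers(0, s - p + 1)) if s > p else 0
                 for s, p in zip(shape, patch))


def _extract(arr, corner, patch):
    sl = tuple(slice(c, c + p) for c, p in zip(corner, patch))
    return arr[sl]


def train(dataset: list, train_cfg: TrainConfig,
          network_cfg: NetworkConfig | None = None,
          progress: bool = False):
    """Train on (CTVolume, MaskVolume) pairs; returns (model, RunManifest).

    The last ``val_volumes`` volumes of a seeded shuffle are held out for
    validation; the checkpoint with the best validation Dice is restored
    before returning.  A NaN in any loss term aborts with a diagnostic
    naming the offending term.
    """
    if not dataset:
        raise ValueError("empty dataset")
    network_cfg = network_cfg or NetworkConfig()
    if network_cfg.dropout_p != train_cfg.dropout:
        network_cfg = replace(network_cfg, dropout_p=train_cfg.dropout)
    rng = np.random.default_rng(train_cfg.rng_seed)
    order = list(rng.permutation(len(dataset)))
    n_val = min(train_cfg.val_volumes, len(dataset) - 1)
    val_ids = order[len(dataset) - n_val:]
    train_ids = order[: len(dataset) - n_val]
    model = build_model(network_cfg, seed=train_cfg.rng_seed)
    model.reseed_dropout(train_cfg.rng_seed + 10_000)
    model.train()
    loss_fn = get_loss(train_cfg.loss, **train_cfg.loss_params)
    opt = Adam(model.parameters(), lr=train_cfg.learning_rate)
    manifest = RunManifest(
        train_config=asdict(train_cfg),
        network_config=asdict(network_cfg),
        seed=train_cfg.rng_seed,
        train_ids=[int(i) for i in train_ids],
        val_ids=[int(i) for i in val_ids],
    )
    patch = tuple(train_cfg.patch_size)
    best_dice = -math.inf
    best_state = None

    def validate(step: int) -> None:
        nonlocal best_dice, best_state
        if not val_ids:
            return
        model.eval()
        dices = []
        for vid in val_ids:
            image, mask = dataset[vid]
            _, pred = predict(model, image, postprocess_min_volume=None)
            d = evaluate_masks(pred, mask).dice
            if not math.isnan(d):
                dices.append(d)
        model.train()
        mean_d = float(np.mean(dices)) if dices else math.nan
        manifest.val_history.append((step, mean_d))
        if dices and mean_d > best_dice:
            best_dice = mean_d
            best_state = model.state_dict()
            manifest.best_step = step

    for step in range(1, train_cfg.max_steps + 1):
        for _ in range(train_cfg.batch_size):
            vid = train_ids[int(rng.integers(len(train_ids)))]
            image, mask = dataset[vid]
            corner = _patch_corner(image.shape, patch, rng)
            img = _extract(image.voxels, corner, patch).astype(np.float32)[None]
            lab = _extract(mask.voxels, corner, patch)
            fused, paths = model(img)
            loss, breakdown = total_loss(SupervisionOutputs(fused, paths), lab, loss_fn)
            for term, val in breakdown.items():
                if not math.isfinite(val):
                    raise RuntimeError(
                        f"non-finite loss at step {step}: term {term!r} = {val}"
                    )
            manifest.loss_curve.append(breakdown)
            loss.backward()
        opt.step()
        opt.zero_grad()
        if progress and step % 10 == 0:
            print(f"step {step:4d}  L_total {breakdown['total']:.4f}")
        if train_cfg.eval_every and step % train_cfg.eval_every == 0:
            validate(step)
    if not train_cfg.eval_every or train_cfg.max_steps % max(train_cfg.eval_every, 1):
        validate(train_cfg.max_steps)
    if best_state is not None:
        model.load_state_dict(best_state)
    model.eval()
    return model, manifest


def _pad_to_divisor(arr: np.ndarray, divisor: int = DIVISOR):
    pads = []
    for s in arr.shape:
        rem = (-s) % divisor
        pads.append((rem // 2, rem - rem // 2))
    if any(p != (0, 0) for p in pads):
        arr = np.pad(arr, pads, mode="edge")
    return arr, pads


def predict(model: SegmentationModel, volume: CTVolume,
            postprocess_min_volume: float | None = 180.0,
            connectivity: int = 26):
    """Segment one preprocessed volume.

    Volumes whose extents are not divisible by 8 are padded symmetrically
    (edge mode) and the padding removed afterwards, so the output grid
    always equals the input grid.  Returns (ProbabilityVolume, MaskVolume);
    the mask is the per-voxel argmax, optionally post-filtered by minimum
    component volume.
    """
    was_training = model.training
    model.eval()
    arr, pads = _pad_to_divisor(np.asarray(volume.voxels, dtype=np.float32))
    fused, _ = model(arr[None])
    p = softmax_channels(fused.data)
    crop = tuple(slice(lo, s - hi if hi else None)
                 for (lo, hi), s in zip(pads, arr.shape))
    p0 = p[0][crop]
    p1 = p[1][crop]
    prob = ProbabilityVolume(p0, p1, volume.spacing)
    mask = prob.argmax_mask()
    if postprocess_min_volume is not None and postprocess_min_volume > 0:
        mask, _ = filter_small_components(mask, postprocess_min_volume, connectivity)
    if was_training:
        model.train()
    return prob, mask


def compare_losses(dataset: list, train_cfg: TrainConfig,
                   network_cfg: NetworkConfig | None = None,
                   losses: list = ("dice", "gdl", "bce", "focal", "tversky")):
    """Train one model per loss (identical seed/config otherwise) and
    evaluate each on the held-out volumes; returns one metrics row per loss.
    """
    rows = []
    for entry in losses:
        name, params = entry if isinstance(entry, tuple) else (entry, None)
        if params is None:
            params = {"alpha": 0.3, "beta": 0.7} if name == "tversky" else {}
        get_loss(name, **params)  # validate early
        cfg = replace(train_cfg, loss=name, loss_params=params)
        model, manifest = train(dataset, cfg, network_cfg)
        reports = []
        for vid in manifest.val_ids:
            image, mask = dataset[vid]
            _, pred = predict(model, image,
                              postprocess_min_volume=cfg.postprocess_min_volume)
            reports.append(evaluate_masks(pred, mask))
        mean = {
            k: float(np.nanmean([getattr(r, k) for r in reports]))
            for k in ("dice", "accuracy", "sensitivity", "specificity")
        }
        rows.append({"loss": name, "params": params, **mean})
    return rows


def cross_validate(dataset: list, train_cfg: TrainConfig,
                   network_cfg: NetworkConfig | None = None,
                   k: int | None = None):
    """k-fold cross-validation; each fold is the test set exactly once.

    Returns (per-fold MetricsReport list, mean ± std aggregate).
    """
    k = k or train_cfg.k_folds
    folds = kfold_split(list(range(len(dataset))), k, train_cfg.rng_seed)
    per_fold = []
    for i, test_ids in enumerate(folds):
        train_set = [dataset[j] for j in range(len(dataset))
                     if j not in set(test_ids)]
        cfg = replace(train_cfg, rng_seed=train_cfg.rng_seed + i)
        model, _ = train(train_set, cfg, network_cfg)
        reports = []
        for j in test_ids:
            image, mask = dataset[j]
            _, pred = predict(model, image,
                              postprocess_min_volume=cfg.postprocess_min_volume)
            reports.append(evaluate_masks(pred, mask))
        fold_mean = MetricsReport(
            **{k_: float(np.nanmean([getattr(r, k_) for r in reports]))
               for k_ in ("dice", "accuracy", "sensitivity", "specificity")}
        )
        per_fold.append(fold_mean)
    return per_fold, aggregate_folds(per_fold)


def save_checkpoint(model: SegmentationModel, path: str,
                    train_config: TrainConfig | None = None) -> None:
    """Parameters + embedded config in one .npz; loadable without context."""
    payload = {f"param/{k}": v for k, v in model.state_dict().items()}
    payload["config_json"] = np.array(
        json.dumps(
            {
                "network": asdict(model.config),
                "train": asdict(train_config) if train_config else None,
                "seed": model._dropout_base_seed,
            }
        )
    )
    np.savez(path, **payload)


def load_checkpoint(path: str):
    """Rebuild the model from a checkpoint; returns (model, config dict)."""
    data = np.load(path, allow_pickle=False)
    cfg = json.loads(str(data["config_json"]))
    net_kwargs = dict(cfg["network"])
    for key in ("dilation_rates", "pyramid_kernels"):
        net_kwargs[key] = tuple(net_kwargs[key])
    model = build_model(NetworkConfig(**net_kwargs), seed=cfg.get("seed", 0))
    state = {k[len("param/"):]: data[k] for k in data.files if k.startswith("param/")}
    model.load_state_dict(state)
    model.eval()
    return model, cfg
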