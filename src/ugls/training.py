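"""Two-stage training orchestration.

The pipeline trains a coarse network on raw images, converts every image's
own binarized coarse prediction into an uncertainty bundle (no ground truth
ever enters bundle construction), then trains a fine network on the selected
channel combination (``bum``, ``ori+bum`` or ``bei+bum``) using the same
cost function, optimizer and batch size as the coarse stage.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from . import metrics
from .backbone import BackboneConfig, RMSprop, UNet, binarize, build_backbone
from .imaging import BinaryMask, Image, build_uncertainty_bundle

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "AugmentationSpec",
    "INPUT_MODES",
    "LeakageError",
    "augment",
    "train_stage",
    "rotate_subsets",
    "build_fine_input",
    "fine_channel_count",
    "run_ugls",
    "UglsResult",
    "scale_radius",
]

INPUT_MODES = ("bum", "ori+bum", "bei+bum")


class LeakageError(RuntimeError):
    """A ground-truth mask reached bundle construction."""


@dataclass(frozen=True)
class AugmentationSpec:
    """Joint image/mask augmentation ranges.

    Flips are Bernoulli(0.5) when enabled; scale, translation (fraction of
    each axis), rotation and shear are sampled uniformly from their ranges.
    The same sampled transform is applied to the image (bilinear) and every
    mask (nearest-neighbor).
    """

    flip_horizontal: bool = True
    flip_vertical: bool = True
    scale_range: tuple[float, float] = (0.9, 1.1)
    translate_frac: tuple[float, float] = (-0.1, 0.1)
    rotate_deg: tuple[float, float] = (-180.0, 180.0)
    shear_deg: tuple[float, float] = (-5.0, 5.0)

    @classmethod
    def identity(cls) -> "AugmentationSpec":
        return cls(
            flip_horizontal=False,
            flip_vertical=False,
            scale_range=(1.0, 1.0),
            translate_frac=(0.0, 0.0),
            rotate_deg=(0.0, 0.0),
            shear_deg=(0.0, 0.0),
        )


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-3
    batch_size: int = 8
    max_epochs: int = 100
    patience: int = 20
    r_m: int = 9
    r_g: int | None = None  # None -> shared with r_m
    input_mode: str = "bei+bum"
    threshold: float = 0.5
    seed: int = 0
    augment: bool = True
    augmentation: AugmentationSpec = field(default_factory=AugmentationSpec)
    base_filters: int = 8
    depth: int = 3

    def __post_init__(self) -> None:
        if self.patience > self.max_epochs:
            raise ValueError("patience must not exceed max_epochs")
        if self.input_mode not in INPUT_MODES:
            raise ValueError(f"input_mode must be one of {INPUT_MODES}")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")
        if self.r_m < 1 or (self.r_g is not None and self.r_g < 1):
            raise ValueError("r_m and r_g must be >= 1")

    @property
    def effective_r_g(self) -> int:
        return self.r_m if self.r_g is None else self.r_g


def scale_radius(r_at_256: int, size: int) -> int:
    """Scale a radius quoted at 256x256 evaluation resolution to another
    image size, preserving the band-width-to-object proportion."""
    return max(1, round(r_at_256 * size / 256))


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------


def _sample_transform(spec: AugmentationSpec, shape: tuple[int, int], rng):
    flip_h = spec.flip_horizontal and rng.random() < 0.5
    flip_v = spec.flip_vertical and rng.random() < 0.5
    scale = rng.uniform(*spec.scale_range)
    ty = rng.uniform(*spec.translate_frac) * shape[0]
    tx = rng.uniform(*spec.translate_frac) * shape[1]
    theta = np.deg2rad(rng.uniform(*spec.rotate_deg))
    shear = np.deg2rad(rng.uniform(*spec.shear_deg))
    return flip_h, flip_v, scale, (ty, tx), theta, shear


def _affine_channel(chan: np.ndarray, params, order: int) -> np.ndarray:
    _, _, scale, (ty, tx), theta, shear = params
    h, w = chan.shape
    c = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    shr = np.array([[1.0, np.tan(shear)], [0.0, 1.0]])
    fwd = rot @ shr * scale
    inv = np.linalg.inv(fwd)
    offset = c - inv @ (c + np.array([ty, tx]))
    return ndimage.affine_transform(
        chan, inv, offset=offset, order=order, mode="constant", cval=0.0,
        prefilter=(order > 1),
    )


def _apply_transform(stack: np.ndarray, params, orders: Sequence[int]) -> np.ndarray:
    """Transform a (C, H, W) stack channel by channel with per-channel
    interpolation order."""
    flip_h, flip_v, *_ = params
    out = stack
    if flip_h:
        out = out[:, :, ::-1]
    if flip_v:
        out = out[:, ::-1, :]
    out = np.ascontiguousarray(out)
    if any(p != 0 for p in (params[2] - 1.0, *params[3], params[4], params[5])):
        out = np.stack(
            [_affine_channel(out[c], params, orders[c]) for c in range(out.shape[0])]
        )
    return out


def augment(
    image: Image | np.ndarray,
    masks: np.ndarray,
    spec: AugmentationSpec,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """One jointly sampled transform applied to an image and a (K, H, W)
    mask stack; masks stay binary, shapes are unchanged."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    img = image.data if isinstance(image, Image) else np.asarray(image, dtype=np.float64)
    masks = np.asarray(masks)
    if masks.ndim != 3:
        raise ValueError(f"expected (K, H, W) mask stack, got shape {masks.shape}")
    img_chw = img[None] if img.ndim == 2 else np.moveaxis(img, 2, 0)
    params = _sample_transform(spec, img_chw.shape[1:], rng)
    out_img_chw = _apply_transform(img_chw, params, [1] * img_chw.shape[0])
    out_masks = _apply_transform(
        masks.astype(np.float32), params, [0] * masks.shape[0]
    ) > 0.5
    out_img = out_img_chw[0] if img.ndim == 2 else np.moveaxis(out_img_chw, 0, 2)
    return np.clip(out_img, 0.0, 1.0), out_masks


def _augment_xy(x: np.ndarray, y: np.ndarray, spec: AugmentationSpec, rng):
    """Augment a training pair of network tensors (C,H,W float) and
    (K,H,W float) with one shared transform."""
    params = _sample_transform(spec, x.shape[1:], rng)
    xa = _apply_transform(x.astype(np.float64), params, [1] * x.shape[0])
    ya = _apply_transform(y.astype(np.float64), params, [0] * y.shape[0])
    return xa.astype(np.float32), (ya > 0.5).astype(np.float32)


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------


def _mean_val_dice(model, val_data, batch_size: int = 8) -> float:
    scores = []
    for x, y in val_data:
        prob = model.predict(np.asarray(x, dtype=np.float32)[None])[0]
        scores.append(metrics.dice_cost(prob, y))
    return float(np.mean(scores))


def train_stage(
    model,
    train_data: Sequence[tuple[np.ndarray, np.ndarray]],
    val_data: Sequence[tuple[np.ndarray, np.ndarray]],
    cfg: TrainConfig,
    monitor: Callable | None = None,
    rng: np.random.Generator | None = None,
):
    """Train with RMSprop on 1 - mean Dice, early-stopping on the validation
    score.

    The parameters achieving the best validation score are restored at the
    end. ``monitor`` defaults to the mean validation dice_cost; an
    improvement must exceed the best score by 1e-5. Training halts after
    ``patience`` consecutive epochs without improvement or at
    ``max_epochs``, whichever comes first.
    """
    if len(train_data) == 0:
        raise ValueError("training dataset is empty")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if monitor is None:
        if len(val_data) == 0:
            raise ValueError("validation dataset is empty and no monitor given")
        monitor = lambda m: _mean_val_dice(m, val_data)  # noqa: E731
    opt = RMSprop(model.params, lr=cfg.learning_rate)
    best_score = -np.inf
    best_state = model.get_state()
    epochs_without_improvement = 0
    history: dict[str, list[float]] = {"train": [], "val": []}
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(train_data))
        batch_losses = []
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xs, ys = [], []
            for i in idx:
                x, y = train_data[i]
                if cfg.augment:
                    x, y = _augment_xy(x, y, cfg.augmentation, rng)
                xs.append(np.asarray(x, dtype=np.float32))
                ys.append(np.asarray(y, dtype=np.float32))
            loss_score, grads = model.loss_and_grads(np.stack(xs), np.stack(ys))
            opt.step(model.params, grads)
            batch_losses.append(loss_score)
        val_score = float(monitor(model))
        history["train"].append(float(np.mean(batch_losses)))
        history["val"].append(val_score)
        if val_score > best_score + 1e-5:
            best_score = val_score
            best_state = model.get_state()
            epochs_without_improvement = 0
        else:
            epochs_without_improvement += 1
            if epochs_without_improvement >= cfg.patience:
                logger.info("early stop at epoch %d (best val %.4f)", epoch + 1, best_score)
                break
    model.set_state(best_state)
    return model, history


def rotate_subsets(
    items: Sequence, n_experiments: int = 6, seed: int = 0
) -> list[tuple[list, list, list]]:
    """Partition items into three equal subsets and rotate them through the
    train/val/test roles.

    With the default six experiments every subset serves in every role
    twice. When the item count is not divisible by three, the remainder is
    appended to the training split of every experiment (and logged).
    """
    if not 1 <= n_experiments <= 6:
        raise ValueError("n_experiments must be between 1 and 6")
    items = list(items)
    if len(items) < 3:
        raise ValueError("need at least 3 items")
    rng = np.random.default_rng(seed)
    shuffled = [items[i] for i in rng.permutation(len(items))]
    third = len(items) // 3
    subsets = [shuffled[:third], shuffled[third : 2 * third], shuffled[2 * third : 3 * third]]
    remainder = shuffled[3 * third :]
    if remainder:
        logger.info("dataset size %d not divisible by 3; %d extra item(s) go to train",
                    len(items), len(remainder))
    splits = []
    for perm in list(itertools.permutations(range(3)))[:n_experiments]:
        train = subsets[perm[0]] + remainder
        val = subsets[perm[1]]
        test = subsets[perm[2]]
        splits.append((train, val, test))
    return splits


# ---------------------------------------------------------------------------
# fine-stage inputs
# ---------------------------------------------------------------------------


def fine_channel_count(image_channels: int, n_objects: int, input_mode: str) -> int:
    """Channels the fine network consumes: image channels when the mode
    includes ORI or BEI, plus one BUM channel per object."""
    if input_mode not in INPUT_MODES:
        raise ValueError(f"input_mode must be one of {INPUT_MODES}")
    extra = image_channels if input_mode in ("ori+bum", "bei+bum") else 0
    return extra + n_objects


def build_fine_input(
    image: Image,
    coarse_masks: Sequence[BinaryMask],
    r_m: int,
    r_g: int,
    input_mode: str,
) -> np.ndarray:
    """(C, H, W) fine-stage input from one image and its per-object coarse
    masks.

    Per-object bundles supply one BUM channel each; for ``bei+bum`` the BEI
    is computed from the union of the per-object PBRs. Empty coarse masks
    fall back to an all-ones PBR (whole image uncertain) so the channel is
    still trainable. Raises :class:`LeakageError` if any coarse mask is
    tagged as ground truth.
    """
    for m in coarse_masks:
        if m.provenance == "truth":
            raise LeakageError(
                f"ground-truth mask {m.object_id!r} must not enter bundle construction"
            )
    bundles = [
        build_uncertainty_bundle(m, image, r_m, r_g, empty_coarse="full")
        for m in coarse_masks
    ]
    channels: list[np.ndarray] = []
    if input_mode == "ori+bum":
        channels.extend(_image_channels(image.data))
    elif input_mode == "bei+bum":
        union = np.zeros(image.spatial_shape, dtype=bool)
        for b in bundles:
            union |= b.pbr.data
        weight = union.astype(np.float64)
        data = image.data * (weight if image.data.ndim == 2 else weight[:, :, None])
        channels.extend(_image_channels(data))
    channels.extend(b.bum for b in bundles)
    out = np.stack(channels).astype(np.float32)
    expected = fine_channel_count(image.channels, len(coarse_masks), input_mode)
    assert out.shape[0] == expected
    return out


def _image_channels(data: np.ndarray) -> list[np.ndarray]:
    if data.ndim == 2:
        return [data]
    return [data[:, :, c] for c in range(data.shape[2])]


# ---------------------------------------------------------------------------
# the full two-stage pipeline
# ---------------------------------------------------------------------------


@dataclass
class UglsResult:
    coarse_model: UNet
    fine_model: UNet
    coarse_rows: pd.DataFrame
    fine_rows: pd.DataFrame
    coarse_report: pd.DataFrame
    fine_report: pd.DataFrame
    coarse_history: dict
    fine_history: dict
    # input-mode ablation: mode -> (per-image rows, aggregated report)
    ablation: dict[str, tuple[pd.DataFrame, pd.DataFrame]] = field(default_factory=dict)


def _image_chw(image: Image) -> np.ndarray:
    d = image.data
    return (d[None] if d.ndim == 2 else np.moveaxis(d, 2, 0)).astype(np.float32)


def _truth_stack(masks: dict[str, BinaryMask], objects: Sequence[str]) -> np.ndarray:
    return np.stack([masks[o].data for o in objects]).astype(np.float32)


def _predict_binary(model: UNet, x: np.ndarray, threshold: float) -> np.ndarray:
    prob = model.predict(x[None])[0]
    return binarize(prob, threshold)


def run_ugls(
    dataset, cfg: TrainConfig, ablation_modes: Sequence[str] = ()
) -> UglsResult:
    """Coarse training, bundle generation and fine training on one dataset.

    ``dataset`` must expose ``objects`` (ordered object names),
    ``ids_for(role)`` for the three roles, and a ``phantoms``/``samples``
    mapping from id to a record with ``image`` and ``masks``. Bundles for
    every split are built from that split's own coarse predictions.

    ``ablation_modes`` trains additional fine networks (one per input mode,
    sharing the coarse model) and reports their test metrics.
    """
    objects = tuple(dataset.objects)
    records = getattr(dataset, "phantoms", None) or dataset.samples
    role_ids = {role: list(dataset.ids_for(role)) for role in ("train", "val", "test")}
    if not role_ids["train"] or not role_ids["val"] or not role_ids["test"]:
        raise ValueError("dataset must contain train, val and test images")
    all_ids = role_ids["train"] + role_ids["val"] + role_ids["test"]

    sample0 = records[all_ids[0]]
    img_channels = sample0.image.channels
    k = len(objects)
    seeds = np.random.SeedSequence(cfg.seed).generate_state(4)

    xs = {pid: _image_chw(records[pid].image) for pid in all_ids}
    ys = {pid: _truth_stack(records[pid].masks, objects) for pid in all_ids}

    def pairs(ids, inputs):
        return [(inputs[pid], ys[pid]) for pid in ids]

    coarse_cfg = BackboneConfig(img_channels, k, cfg.base_filters, cfg.depth)
    coarse = build_backbone(coarse_cfg, seed=int(seeds[0]))
    coarse, coarse_history = train_stage(
        coarse,
        pairs(role_ids["train"], xs),
        pairs(role_ids["val"], xs),
        cfg,
        rng=np.random.default_rng(int(seeds[1])),
    )

    r_m, r_g = cfg.r_m, cfg.effective_r_g
    coarse_preds = {}
    for pid in all_ids:
        pred = _predict_binary(coarse, xs[pid], cfg.threshold)
        coarse_preds[pid] = [
            BinaryMask(pred[i], object_id=objects[i], provenance="prediction")
            for i in range(k)
        ]

    def fine_inputs_for(mode):
        return {
            pid: build_fine_input(records[pid].image, coarse_preds[pid], r_m, r_g, mode)
            for pid in all_ids
        }

    def train_fine(mode, inputs):
        fine_cfg = BackboneConfig(
            fine_channel_count(img_channels, k, mode), k, cfg.base_filters, cfg.depth
        )
        net = build_backbone(fine_cfg, seed=int(seeds[2]))
        return train_stage(
            net,
            pairs(role_ids["train"], inputs),
            pairs(role_ids["val"], inputs),
            cfg,
            rng=np.random.default_rng(int(seeds[3])),
        )

    def test_rows(model, inputs):
        rows = []
        for pid in role_ids["test"]:
            pred = _predict_binary(model, inputs[pid], cfg.threshold)
            for i, obj in enumerate(objects):
                row = {"object": obj, "image_id": pid}
                row.update(metrics.evaluate_pair(pred[i], records[pid].masks[obj].data))
                rows.append(row)
        return pd.DataFrame(rows)

    fine_xs = fine_inputs_for(cfg.input_mode)
    fine, fine_history = train_fine(cfg.input_mode, fine_xs)

    ablation: dict[str, tuple[pd.DataFrame, pd.DataFrame]] = {}
    for mode in ablation_modes:
        if mode == cfg.input_mode:
            continue
        mode_xs = fine_inputs_for(mode)
        mode_net, _ = train_fine(mode, mode_xs)
        mode_rows = test_rows(mode_net, mode_xs)
        ablation[mode] = (mode_rows, metrics.aggregate(mode_rows))

    coarse_rows = test_rows(coarse, xs)
    fine_rows = test_rows(fine, fine_xs)
    return UglsResult(
        coarse_model=coarse,
        fine_model=fine,
        coarse_rows=coarse_rows,
        fine_rows=fine_rows,
        coarse_report=metrics.aggregate(coarse_rows),
        fine_report=metrics.aggregate(fine_rows),
        coarse_history=coarse_history,
        fine_history=fine_history,
        ablation=ablation,
    )
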