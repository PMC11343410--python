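"""U-Net training: weighted BCE, geometric augmentations, model selection.

Training minimises pixel-wise binary cross entropy, optionally weighting
the foreground term to counter class imbalance (sparse nuclei in large
fields).  Augmentations are flips and 90-degree rotations applied jointly
to image and mask (90-degree steps avoid interpolation artifacts in label
masks; arbitrary-angle rotation is available behind a flag with
nearest-neighbour mask resampling), plus optional blur/sharpen on the image
only.  Training runs on random square crops whose side must be a multiple
of 2^depth.

Model selection follows the validation-based protocols: checkpoints are
scored on the validation set with either the image-wise average adapted F1
at tau1 (the general protocol) or the mean big-cell IOU above a physical
size cutoff (the large-nucleus retraining protocol), and the checkpoint
with the highest score wins (ties -> earliest).  A grid search over
learning rate and loss weight with replicates reports every cell's score.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi

from .imgio import FileList, IntensityImage, read_image, read_mask
from .metrics import MetricConfig, adapted_f1, evaluate_pair, object_iou_by_size
from .nn.layers import F32, Adam
from .nn.unet import UNet, UNetConfig, downsampling_factor, predict
from .postprocess import PostprocessConfig, postprocess


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-3
    epochs: int = 20
    batch_size: int = 4
    loss_weight: float = 1.0           # weight of the positive (foreground) term
    crop_size: int = 128
    augmentations: tuple[str, ...] = ("flip", "rotate90")
    arbitrary_rotation: bool = False
    replicates: int = 1
    seed: int = 0
    selection_criterion: str = "adapted_f1_avg"   # or "mean_big_cell_iou"
    checkpoint_every: int | None = None           # None -> every epoch (<=100) else every 10
    metric_config: MetricConfig = field(default_factory=MetricConfig)
    postprocess_config: PostprocessConfig = field(
        default_factory=lambda: PostprocessConfig(min_object_px=10, min_hole_px=10)
    )

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.loss_weight <= 0:
            raise ValueError("loss_weight must be positive")


@dataclass
class TrainHistory:
    epoch_losses: list[float] = field(default_factory=list)
    checkpoint_epochs: list[int] = field(default_factory=list)
    checkpoint_scores: list[float] = field(default_factory=list)
    selected_epoch: int = -1
    selected_score: float = float("nan")
    init_val_score: float | None = None
    wall_seconds: float = 0.0


def weighted_bce(prob: np.ndarray, target: np.ndarray, w: float = 1.0) -> float:
    """Pixel-mean weighted binary cross entropy on probabilities.

    ``-mean(w * y * log p + (1 - y) * log(1 - p))``; non-negative, zero only
    as p -> y everywhere.
    """
    prob = np.asarray(prob, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if prob.shape != target.shape:
        raise ValueError(f"shape mismatch {prob.shape} vs {target.shape}")
    p = np.clip(prob, 1e-12, 1 - 1e-12)
    return float(-np.mean(w * target * np.log(p) + (1 - target) * np.log(1 - p)))


def _bce_logits_and_grad(
    logits: np.ndarray, target: np.ndarray, w: float
) -> tuple[float, np.ndarray]:
    """Numerically stable loss + gradient w.r.t. logits in one pass."""
    z = logits.astype(np.float64)
    y = target.astype(np.float64)
    # log(1 + e^z) computed stably; loss = -[w y log p + (1-y) log(1-p)]
    log1pez = np.logaddexp(0.0, z)
    loss = np.mean(w * y * (log1pez - z) + (1 - y) * log1pez)
    p = 1.0 / (1.0 + np.exp(-z))
    grad = (p * (w * y + 1 - y) - w * y) / z.size
    return float(loss), grad.astype(F32)


def augment(
    image: np.ndarray,
    mask: np.ndarray,
    config: TrainConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Jointly augment an image/mask pair; returns crops of ``crop_size``.

    The identical geometric transform is applied to both; blur/sharpen (when
    enabled) perturbs the image only.
    """
    image = np.asarray(image)
    mask = np.asarray(mask)
    if image.shape != mask.shape:
        raise ValueError("image and mask must share a shape")
    cs = config.crop_size
    h, w = image.shape
    if h < cs or w < cs:
        raise ValueError(f"source {h}x{w} smaller than crop_size {cs}")
    if h > cs or w > cs:
        y0 = int(rng.integers(0, h - cs + 1))
        x0 = int(rng.integers(0, w - cs + 1))
        image = image[y0 : y0 + cs, x0 : x0 + cs]
        mask = mask[y0 : y0 + cs, x0 : x0 + cs]
    if config.arbitrary_rotation:
        angle = float(rng.uniform(0, 360))
        image = ndi.rotate(image, angle, reshape=False, order=1, mode="reflect")
        mask = ndi.rotate(mask, angle, reshape=False, order=0, mode="constant")
    if "flip" in config.augmentations:
        if rng.uniform() < 0.5:
            image, mask = image[:, ::-1], mask[:, ::-1]
        if rng.uniform() < 0.5:
            image, mask = image[::-1, :], mask[::-1, :]
    if "rotate90" in config.augmentations:
        k = int(rng.integers(0, 4))
        image, mask = np.rot90(image, k), np.rot90(mask, k)
    if "blur_sharpen" in config.augmentations and rng.uniform() < 0.5:
        sigma = float(rng.uniform(0.3, 1.2))
        blurred = ndi.gaussian_filter(image.astype(np.float64), sigma)
        if rng.uniform() < 0.5:
            image = blurred
        else:
            image = np.clip(2 * image.astype(np.float64) - blurred, 0, None)
    return np.ascontiguousarray(image), np.ascontiguousarray(mask)


def _load_pairs(data) -> list[tuple[np.ndarray, np.ndarray]]:
    """FileList -> [(image in [0,1], binary target)], or pass arrays through."""
    pairs = []
    if isinstance(data, FileList):
        for img_path, mask_path in data:
            if mask_path is None:
                raise ValueError(f"{img_path}: training requires mask paths")
            img = read_image(img_path)
            arr = img.pixels.astype(F32) / F32(2**img.bit_depth - 1)
            pairs.append((arr, (read_mask(mask_path) > 0)))
    else:
        for img, mask in data:
            if isinstance(img, IntensityImage):
                img = img.pixels.astype(F32) / F32(2**img.bit_depth - 1)
            arr = np.asarray(img, dtype=F32)
            if arr.max(initial=0.0) > 1.0:
                arr = arr / F32(255.0)
            pairs.append((arr, np.asarray(mask) > 0))
    if not pairs:
        raise ValueError("empty training set")
    return pairs


def validation_score(
    model: UNet,
    val_pairs: list[tuple[np.ndarray, np.ndarray]],
    cfg: TrainConfig,
) -> float:
    """Score a checkpoint on (image, instance-mask) validation pairs."""
    from .postprocess import label_instances

    scores = []
    for img, gt in val_pairs:
        prob = predict(model, img)
        pred = postprocess(prob, cfg.postprocess_config)
        gt_inst = gt if gt.dtype.kind in "iu" and gt.max(initial=0) > 1 else label_instances(gt > 0)
        if cfg.selection_criterion == "adapted_f1_avg":
            m = evaluate_pair(gt_inst, pred, cfg.metric_config)
            scores.append(adapted_f1(m, cfg.metric_config.eps))
        elif cfg.selection_criterion == "mean_big_cell_iou":
            res = object_iou_by_size(gt_inst, pred, cfg.metric_config)
            if not np.isnan(res["large_mean_iou"]):
                scores.append(res["large_mean_iou"])
        else:
            raise ValueError(f"unknown criterion {cfg.selection_criterion!r}")
    return float(np.mean(scores)) if scores else 0.0


def train(
    train_set,
    val_set,
    unet_cfg: UNetConfig,
    cfg: TrainConfig,
    init: UNet | None = None,
) -> tuple[UNet, TrainHistory]:
    """Train the U-Net; return the best validation checkpoint + history.

    ``train_set``/``val_set`` are FileLists of (image, mask) paths or
    in-memory (image, mask) pairs.  Fully deterministic for a fixed seed.
    Validation masks may be instance masks (used as-is) or binary masks
    (instance-labelled on the fly).
    """
    t0 = time.time()
    if cfg.crop_size % downsampling_factor(unet_cfg) != 0:
        raise ValueError(
            f"crop_size {cfg.crop_size} must be a multiple of 2^depth "
            f"({downsampling_factor(unet_cfg)})"
        )
    train_pairs = _load_pairs(train_set)
    val_raw = _load_pairs_instances(val_set)
    rng = np.random.default_rng(cfg.seed)
    model = init.copy() if init is not None else UNet(unet_cfg, rng_seed=cfg.seed)
    optim = Adam(model.layers(), lr=cfg.learning_rate)
    history = TrainHistory()
    if init is not None:
        history.init_val_score = validation_score(model, val_raw, cfg)

    every = cfg.checkpoint_every
    if every is None:
        every = 1 if cfg.epochs <= 100 else 10

    best_state: dict[str, np.ndarray] | None = None
    for epoch in range(1, cfg.epochs + 1):
        order = rng.permutation(len(train_pairs))
        losses = []
        for start in range(0, len(order), cfg.batch_size):
            batch_idx = order[start : start + cfg.batch_size]
            imgs, tgts = [], []
            for bi in batch_idx:
                img, msk = train_pairs[bi]
                ai, am = augment(img, msk, cfg, rng)
                imgs.append(ai)
                tgts.append(am > 0)
            x = np.stack(imgs).astype(F32)[..., None]
            y = np.stack(tgts).astype(F32)[..., None]
            logits = model.forward_logits(x, train=True)
            loss, dlogits = _bce_logits_and_grad(logits, y, cfg.loss_weight)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: {loss}; "
                    "reduce the learning rate or loss weight"
                )
            optim.zero_grad()
            model.backward(dlogits)
            optim.step()
            losses.append(loss)
        history.epoch_losses.append(float(np.mean(losses)))
        if epoch % every == 0 or epoch == cfg.epochs:
            score = validation_score(model, val_raw, cfg)
            history.checkpoint_epochs.append(epoch)
            history.checkpoint_scores.append(score)
            if score > history.selected_score or np.isnan(history.selected_score):
                history.selected_score = score
                history.selected_epoch = epoch
                best_state = {k: v.copy() for k, v in model.state_arrays().items()}
    if best_state is not None:
        model.load_state_arrays(best_state)
    history.wall_seconds = time.time() - t0
    return model, history


def _load_pairs_instances(data) -> list[tuple[np.ndarray, np.ndarray]]:
    """Like _load_pairs but keeps instance labels in the mask."""
    pairs = []
    if isinstance(data, FileList):
        for img_path, mask_path in data:
            if mask_path is None:
                raise ValueError(f"{img_path}: validation requires mask paths")
            img = read_image(img_path)
            arr = img.pixels.astype(F32) / F32(2**img.bit_depth - 1)
            pairs.append((arr, read_mask(mask_path)))
    else:
        for img, mask in data:
            if isinstance(img, IntensityImage):
                img = img.pixels.astype(F32) / F32(2**img.bit_depth - 1)
            arr = np.asarray(img, dtype=F32)
            if arr.max(initial=0.0) > 1.0:
                arr = arr / F32(255.0)
            pairs.append((arr, np.asarray(mask)))
    if not pairs:
        raise ValueError("empty validation set")
    return pairs


def grid_search(
    train_set,
    val_set,
    unet_cfg: UNetConfig,
    base_cfg: TrainConfig,
    learning_rates: tuple[float, ...] = (1e-3,),
    loss_weights: tuple[float, ...] = (1.0,),
    replicates: int = 1,
    init: UNet | None = None,
):
    """Train every (lr, loss weight) x replicate; select by validation score.

    Returns ``(best_model, report, best_history)``: the report lists one
    row per run with its hyperparameters, replicate seed, best validation
    score and the selected epoch; the argmax over report rows is the
    returned model, whose full training history is also returned.
    """
    import pandas as pd

    rows = []
    best: tuple | None = None
    for lr in learning_rates:
        for w in loss_weights:
            for rep in range(replicates):
                cfg = replace(
                    base_cfg, learning_rate=lr, loss_weight=w,
                    seed=base_cfg.seed + 10_000 * rep,
                )
                model, hist = train(train_set, val_set, unet_cfg, cfg, init=init)
                rows.append(
                    {
                        "learning_rate": lr, "loss_weight": w, "replicate": rep,
                        "seed": cfg.seed, "val_score": hist.selected_score,
                        "selected_epoch": hist.selected_epoch,
                    }
                )
                if best is None or hist.selected_score > best[1]:
                    best = (model, hist.selected_score, hist)
    report = pd.DataFrame(rows)
    return best[0], report, best[2]
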