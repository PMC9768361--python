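"""Training loop, data augmentation, and whole-slide inference.

The training recipe follows the production configuration: Adam at learning
rate 3e-4, batch size 4, 50 epochs, with online augmentation of every
image/label pair — a rotation drawn from 0-359 degrees, vertical/horizontal
translations of up to 50 pixels (reflection padding), and random vertical
and horizontal flips.  The identical geometric transform is applied to the
image (bilinear) and to its class map (nearest-neighbor, so no fractional
classes are invented).  Class imbalance is handled by patch-level random
oversampling upstream, not by loss weighting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .loss_metrics import combined_loss, combined_loss_grad, miou
from .model import SegNetwork
from .tiling import probmap_argmax, stitch_probmaps, tile_slide

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    """Optimization and augmentation settings."""

    learning_rate: float = 3e-4
    epochs: int = 50
    batch_size: int = 4
    rotation_range: tuple = (0.0, 359.0)
    shift_range: tuple = (0, 50)
    flips: bool = True
    rng_seed: int = 0
    device: str = "cpu"
    jaccard_smooth: float = 1.0

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if min(self.rotation_range) < 0 or min(self.shift_range) < 0:
            raise ValueError("augmentation ranges must be non-negative")
        if self.device != "cpu":
            raise ValueError("only cpu execution is supported")

    def to_dict(self) -> dict:
        from dataclasses import asdict

        d = asdict(self)
        d["rotation_range"] = list(self.rotation_range)
        d["shift_range"] = list(self.shift_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        d = dict(d)
        for k in ("rotation_range", "shift_range"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


def augment(
    image: np.ndarray,
    cm: np.ndarray,
    cfg: TrainConfig,
    rng: np.random.Generator,
):
    """Apply one random rotate -> shift -> flip draw to an image/mask pair.

    The image is interpolated bilinearly, the class map with nearest
    neighbor; both use reflection padding so no out-of-tissue zeros appear.
    Output shapes equal input shapes.  Deterministic given the generator
    state.
    """
    image = np.asarray(image)
    cm = np.asarray(cm)
    if image.shape[:2] != cm.shape[:2]:
        raise ValueError("image and class map shapes differ")

    angle = float(rng.uniform(*cfg.rotation_range))
    dy = int(rng.integers(cfg.shift_range[0], cfg.shift_range[1] + 1))
    dx = int(rng.integers(cfg.shift_range[0], cfg.shift_range[1] + 1))
    sy = int(rng.choice([-1, 1]))
    sx = int(rng.choice([-1, 1]))
    flip_v = cfg.flips and bool(rng.integers(0, 2))
    flip_h = cfg.flips and bool(rng.integers(0, 2))

    img = image.astype(np.float32)
    if angle != 0.0:
        img = ndimage.rotate(img, angle, axes=(0, 1), reshape=False, order=1,
                             mode="reflect")
        cm = ndimage.rotate(cm, angle, axes=(0, 1), reshape=False, order=0,
                            mode="reflect")
    if dy or dx:
        shift_img = (sy * dy, sx * dx) + (0,) * (img.ndim - 2)
        img = ndimage.shift(img, shift_img, order=1, mode="reflect")
        cm = ndimage.shift(cm, (sy * dy, sx * dx), order=0, mode="reflect")
    if flip_v:
        img, cm = img[::-1], cm[::-1]
    if flip_h:
        img, cm = img[:, ::-1], cm[:, ::-1]

    if np.issubdtype(image.dtype, np.integer):
        img = np.clip(np.rint(img), 0, 255).astype(image.dtype)
    return np.ascontiguousarray(img), np.ascontiguousarray(cm)


#: fixed affine input scaling: centers typical stained-tissue intensities
INPUT_MEAN = 0.5
INPUT_STD = 0.25


def normalize_images(images) -> np.ndarray:
    """uint8 HWC patches -> centered float32 NCHW network input."""
    x = np.stack(
        [(np.asarray(im, dtype=np.float32) / 255.0 - INPUT_MEAN) / INPUT_STD
         for im in images]
    )
    return np.ascontiguousarray(x.transpose(0, 3, 1, 2))


def _to_batch(images, maps, num_classes):
    """uint8 HWC images + class maps -> network input and one-hot target."""
    x = normalize_images(images)
    y = np.stack([np.eye(num_classes, dtype=np.float32)[np.asarray(m)] for m in maps])
    y = np.ascontiguousarray(y.transpose(0, 3, 1, 2))
    return x, y


def train(
    network: SegNetwork,
    data,
    cfg: TrainConfig,
    val_data=None,
    checkpoint_dir=None,
    augment_data: bool = True,
) -> pd.DataFrame:
    """Minimize the combined loss over (image, class map) pairs.

    Parameters
    ----------
    network : SegNetwork
    data : sequence of (uint8 HxWx3 image, class map) pairs — typically the
        oversampled tile set of the training slides.
    cfg : TrainConfig
    val_data : optional held-out pairs; MIoU is logged per epoch.
    checkpoint_dir : optional directory; a checkpoint is written per epoch.

    Returns
    -------
    pandas.DataFrame with one row per epoch: epoch, mean_loss, jaccard_part,
    ce_part[, val_miou].
    """
    from .nn.optim import Adam

    data = list(data)
    if not data:
        raise ValueError("empty training set")
    rng = np.random.default_rng(cfg.rng_seed)
    opt = Adam(network.parameters(), lr=cfg.learning_rate)
    K = network.cfg.num_classes

    log_rows = []
    for epoch in range(1, cfg.epochs + 1):
        order = rng.permutation(len(data))
        totals, jparts, ceparts = [], [], []
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            ims, cms = [], []
            for i in idx:
                im, cm = data[i]
                if augment_data:
                    im, cm = augment(im, cm, cfg, rng)
                ims.append(im)
                cms.append(cm)
            x, y = _to_batch(ims, cms, K)
            p = network.forward(x, train=True)
            lv = combined_loss(p, y, smooth=cfg.jaccard_smooth, channel_axis=1)
            if not np.isfinite(lv.total):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: {lv}"
                )
            g = combined_loss_grad(p, y, smooth=cfg.jaccard_smooth, channel_axis=1)
            opt.zero_grad()
            network.backward(g)
            opt.step()
            totals.append(lv.total)
            jparts.append(lv.jaccard_part)
            ceparts.append(lv.ce_part)

        row = {
            "epoch": epoch,
            "mean_loss": float(np.mean(totals)),
            "jaccard_part": float(np.mean(jparts)),
            "ce_part": float(np.mean(ceparts)),
        }
        if val_data:
            row["val_miou"] = evaluate_miou(network, val_data)
        log_rows.append(row)
        logger.info("epoch %d: %s", epoch, row)
        if checkpoint_dir is not None:
            from pathlib import Path

            d = Path(checkpoint_dir)
            d.mkdir(parents=True, exist_ok=True)
            network.save(d / f"epoch_{epoch:03d}.npz")
    return pd.DataFrame(log_rows)


def predict_batch(network: SegNetwork, images, batch_size: int = 4) -> np.ndarray:
    """Forward a list of uint8 HWC patches in eval mode -> (N, K, H, W)."""
    outs = []
    for start in range(0, len(images), batch_size):
        x = normalize_images(images[start : start + batch_size])
        outs.append(network.forward(x, train=False))
    return np.concatenate(outs, axis=0)


def evaluate_miou(network: SegNetwork, pairs, batch_size: int = 4) -> float:
    """Mean of per-patch MIoU over (image, class map) pairs."""
    images = [p[0] for p in pairs]
    probs = predict_batch(network, images, batch_size)
    preds = probs.argmax(axis=1)
    K = network.cfg.num_classes
    return float(np.mean([miou(pr, t, K) for pr, (_, t) in zip(preds, pairs)]))


def predict_slide(
    network: SegNetwork,
    slide: np.ndarray,
    tile_size: int | None = None,
    stride: int | None = None,
    batch_size: int = 4,
):
    """Segment a whole slide: tile, forward per tile, stitch, argmax.

    Overlapping tiles (stride < tile_size) are resolved by per-pixel
    probability averaging before the argmax; exact ties go to the lowest
    class index.

    Returns
    -------
    (class_map (H, W), prob_map (H, W, K))
    """
    tile_size = tile_size or network.cfg.input_size
    stride = stride or tile_size
    manifest, records = tile_slide(slide, tile_size, stride)
    probs = predict_batch(network, [r.pixels for r in records], batch_size)
    prob_tiles = [
        (probs[i].transpose(1, 2, 0), records[i].origin) for i in range(len(records))
    ]
    prob_map = stitch_probmaps(prob_tiles, manifest.slide_shape)
    return probmap_argmax(prob_map), prob_map
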