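"""Training loop and the model/results interface.

The network is fitted with mean-squared-error against {0,1} mask targets
using Adam (step size 1e-3, beta1 0.9, beta2 0.999, eps 1e-8 — the
canonical settings; only the optimiser name, epoch count 60, steps per
epoch 250 and batch size 2 are prescribed by the reference workflow).
Batches are drawn uniformly with replacement, so an epoch is a fixed
number of sampled steps rather than a full pass. After every epoch the
validation loss, pixel accuracy and segmentation metrics are recorded;
the parameters with the best validation loss are the ones retained.

`GlandSegmentationModel` / `SegmentationResults` wrap this in the usual
model-object idiom: build the model from tile arrays (or whole scenes),
call :meth:`GlandSegmentationModel.fit`, and read the history, metrics and
``summary()`` off the results object.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import metrics as _metrics
from . import tiling as _tiling
from .network import IppNet, NetworkSpec, binarize, build_network

__all__ = [
    "TrainConfig",
    "mse_loss",
    "train",
    "GlandSegmentationModel",
    "SegmentationResults",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation settings; defaults follow the reference workflow."""

    lr: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    epochs: int = 60
    steps_per_epoch: int = 250
    batch_size: int = 2
    seed: int = 0
    tau: float = 0.5          # binarisation threshold for validation metrics
    val_batch_size: int = 4

    def __post_init__(self):
        if min(self.epochs, self.steps_per_epoch, self.batch_size) < 1:
            raise ValueError("epochs, steps_per_epoch and batch_size must be >= 1")


def mse_loss(pred: np.ndarray, label: np.ndarray) -> float:
    """Mean squared error over all pixels and batch items."""
    pred = np.asarray(pred, dtype=np.float32)
    label = np.asarray(label, dtype=np.float32)
    if pred.shape != label.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {label.shape}")
    diff = pred - label
    return float(np.mean(diff * diff, dtype=np.float64))


def _as_float_images(images: np.ndarray) -> np.ndarray:
    images = np.asarray(images)
    if images.dtype == np.uint8:
        return images.astype(np.float32) / 255.0
    return images.astype(np.float32)


def _evaluate(net: IppNet, images: np.ndarray, masks: np.ndarray,
              tau: float, batch_size: int) -> tuple:
    losses = []
    conf = _metrics.ConfusionCounts(0, 0, 0, 0)
    for i in range(0, len(images), batch_size):
        x = _as_float_images(images[i:i + batch_size])
        t = masks[i:i + batch_size].astype(np.float32)
        y = net.forward(x, train=False)
        losses.append(mse_loss(y, t) * len(x))
        conf = conf + _metrics.confusion(binarize(y, tau), masks[i:i + batch_size])
    return sum(losses) / len(images), _metrics.segmentation_metrics(conf)


def train(net: IppNet, train_set: tuple, val_set: tuple,
          config: TrainConfig | None = None) -> pd.DataFrame:
    """Fit ``net`` in place; returns the per-epoch history.

    ``train_set`` / ``val_set`` are ``(images, masks)`` pairs of stacked
    tiles: images (N, H, W, 3) uint8 (or float in [0, 1]), masks (N, H, W)
    in {0, 1}. Row 0 of the history is the untrained validation state. If
    the loss diverges to NaN the run stops and the best finite parameters
    are restored.
    """
    config = config or TrainConfig()
    tr_images, tr_masks = train_set
    if len(tr_images) == 0 or len(val_set[0]) == 0:
        raise ValueError("training and validation sets must be non-empty")
    rng = np.random.default_rng(config.seed)
    opt = net.make_optimizer(lr=config.lr, beta1=config.beta1,
                             beta2=config.beta2, eps=config.eps)

    rows = []

    def log_epoch(epoch, train_loss):
        val_loss, report = _evaluate(net, val_set[0], val_set[1],
                                     config.tau, config.val_batch_size)
        rows.append({"epoch": epoch, "train_loss": train_loss,
                     "val_loss": val_loss,
                     "val_pixel_accuracy": report.pixel_accuracy,
                     "val_miou": report.miou, "val_precision": report.precision,
                     "val_recall": report.recall, "val_f1": report.f1})
        return val_loss

    best_loss = log_epoch(0, float("nan"))
    best_state = net.state_dict()
    diverged = False
    for epoch in range(1, config.epochs + 1):
        step_losses = []
        for _ in range(config.steps_per_epoch):
            idx = rng.integers(0, len(tr_images), size=config.batch_size)
            x = _as_float_images(tr_images[idx])
            t = tr_masks[idx].astype(np.float32)
            y = net.forward(x, train=True)
            loss = mse_loss(y, t)
            if not np.isfinite(loss):
                diverged = True
                break
            step_losses.append(loss)
            grad = (2.0 / y.size) * (y - t)
            net.backward(grad.astype(np.float32))
            opt.step()
        if diverged:
            break
        val_loss = log_epoch(epoch, float(np.mean(step_losses)))
        if val_loss < best_loss:
            best_loss = val_loss
            best_state = net.state_dict()
    net.load_state_dict(best_state)
    history = pd.DataFrame(rows)
    history.attrs["diverged"] = diverged
    return history


class GlandSegmentationModel:
    """Gland segmentation model: tile data + architecture + train settings."""

    def __init__(self, train_images, train_masks, val_images, val_masks,
                 spec: NetworkSpec | None = None,
                 config: TrainConfig | None = None):
        self.train_images = np.asarray(train_images)
        self.train_masks = np.asarray(train_masks)
        self.val_images = np.asarray(val_images)
        self.val_masks = np.asarray(val_masks)
        size = self.train_images.shape[1]
        self.spec = spec or NetworkSpec(input_size=size)
        self.config = config or TrainConfig()
        if self.train_images.shape[1] != self.spec.input_size:
            raise ValueError("tile size does not match the network spec")

    @classmethod
    def from_scenes(cls, train_scenes, val_scenes, tile_size: int = 100,
                    context_size: int = 120, spec=None, config=None):
        """Build the tile datasets by cropping whole scenes."""
        def stack(scenes):
            imgs, msks = [], []
            for s in scenes:
                grid = _tiling.TileGrid(*s.image.shape[:2], tile_size=tile_size,
                                        context_size=context_size)
                imgs.append(_tiling.crop_tiles(s.image, grid))
                msks.append(_tiling.crop_tiles(s.mask, grid))
            return np.concatenate(imgs), np.concatenate(msks)

        tr = stack(train_scenes)
        va = stack(val_scenes)
        if spec is None:
            spec = NetworkSpec(input_size=context_size)
        return cls(tr[0], tr[1], va[0], va[1], spec=spec, config=config)

    def fit(self, seed: int | None = None) -> "SegmentationResults":
        """Train a fresh network and return the results object."""
        cfg = self.config if seed is None else \
            dataclasses.replace(self.config, seed=seed)
        net = build_network(self.spec, seed=cfg.seed)
        history = train(net, (self.train_images, self.train_masks),
                        (self.val_images, self.val_masks), cfg)
        return SegmentationResults(model=self, network=net,
                                   history=history, config=cfg)


class SegmentationResults:
    """Fitted network plus its training history and validation metrics."""

    def __init__(self, model, network: IppNet, history: pd.DataFrame,
                 config: TrainConfig):
        self.model = model
        self.network = network
        self.history = history
        self.config = config

    @property
    def best_epoch(self) -> int:
        return int(self.history.loc[self.history["val_loss"].idxmin(), "epoch"])

    @property
    def final_metrics(self) -> pd.Series:
        """Validation metrics of the retained (best-loss) parameters."""
        return self.history.loc[self.history["val_loss"].idxmin()]

    def predict(self, image: np.ndarray, tile_size: int = 100,
                tau: float | None = None, batch_size: int = 8) -> np.ndarray:
        """Segment a full image (tile, forward, binarise, stitch)."""
        from .pipeline import segment_image
        tau = self.config.tau if tau is None else tau
        return segment_image(self.network, image, tile_size=tile_size,
                             tau=tau, batch_size=batch_size)

    def count(self, image: np.ndarray, filter_config=None,
              tile_size: int = 100, tau: float | None = None) -> int:
        """Segment a full image and count the surviving connected domains."""
        from .pipeline import count_image
        tau = self.config.tau if tau is None else tau
        return count_image(self.network, image, filter_config=filter_config,
                           tile_size=tile_size, tau=tau)[0]

    def save(self, path) -> None:
        self.network.save(path)

    def summary(self) -> str:
        m = self.final_metrics
        spec = self.network.spec
        lines = [
            "Gland segmentation results",
            "==========================",
            f"architecture        interp-first/pool-second encoder-decoder "
            f"({spec.up_blocks} up / {spec.down_blocks} down)",
            f"input tile          {spec.input_size} px, "
            f"{spec.input_channels} channels",
            f"base channels       {spec.base_channels}",
            f"parameters          {self.network.n_parameters()}",
            f"epochs run          {int(self.history['epoch'].max())} "
            f"(best: {self.best_epoch})",
            f"train loss (last)   {self.history['train_loss'].iloc[-1]:.5f}",
            f"val loss (best)     {m['val_loss']:.5f}",
            f"val pixel accuracy  {m['val_pixel_accuracy']:.4f}",
            f"val mIoU            {m['val_miou']:.4f}",
            f"val precision       {m['val_precision']:.4f}",
            f"val recall          {m['val_recall']:.4f}",
            f"val F1              {m['val_f1']:.4f}",
        ]
        return "\n".join(lines)
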