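"""Training loop: Adam with exponentially decaying learning rate and cosine
warm restarts, class-weighted soft Dice objective, seeded augmentation."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .augment import AugmentConfig, augment
from .loss import ClassWeights, weighted_soft_dice_loss_grad
from .unet import UNet, prepare_input


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 20
    batch_size: int = 8
    lr: float = 1e-3
    lr_decay: float = 0.97  # multiplicative, per epoch
    warm_restart_epochs: int = 25  # cosine restart period
    lr_min_frac: float = 0.1  # floor of the cosine factor
    smooth: float = 1.0  # Dice smoothing during training
    seed: int = 0
    augment: bool = True
    augment_config: AugmentConfig = field(default_factory=AugmentConfig)
    checkpoint_dir: str | None = None

    def __post_init__(self) -> None:
        if min(self.epochs, self.batch_size, self.warm_restart_epochs) <= 0 or self.lr <= 0:
            raise ValueError("epochs, batch size, restart period and lr must be positive")

    def lr_at(self, epoch: int) -> float:
        t = (epoch % self.warm_restart_epochs) / self.warm_restart_epochs
        cos = 0.5 * (1 + np.cos(np.pi * t))
        factor = self.lr_min_frac + (1 - self.lr_min_frac) * cos
        return self.lr * (self.lr_decay**epoch) * factor


def train(
    dataset: list[tuple[np.ndarray, np.ndarray] | tuple[np.ndarray, np.ndarray, np.ndarray]],
    net: UNet,
    config: TrainConfig | None = None,
    class_weights: ClassWeights | None = None,
) -> dict:
    """Fit ``net`` on (rgb, one-hot mask[, ignore mask]) tiles.

    Returns a history dict with per-epoch mean loss and learning rate.
    Raises on an empty dataset; aborts with a diagnostic if the loss goes
    non-finite.
    """
    if not dataset:
        raise ValueError("empty training dataset")
    config = config or TrainConfig()
    class_weights = class_weights or ClassWeights()
    w = class_weights.as_array()[: net.config.n_classes]
    rng = np.random.default_rng(config.seed)
    opt = nn.Adam(net.layers(), lr=config.lr)

    history: dict = {"epoch_loss": [], "lr": [], "step_loss": []}
    n = len(dataset)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        lr = config.lr_at(epoch)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xs, gs, igns = [], [], []
            for i in idx:
                sample = dataset[i]
                rgb, mask = sample[0], sample[1]
                ign = sample[2] if len(sample) > 2 else None
                if config.augment:
                    rgb, mask = augment(rgb, mask, rng, config.augment_config)
                xs.append(prepare_input(rgb))
                gs.append(mask.transpose(2, 0, 1))
                igns.append(ign)
            x = np.stack(xs)
            g = np.stack(gs).astype(np.float64)
            probs = net.forward(x, train=True)
            p_cl = probs.transpose(0, 2, 3, 1)  # class-last for the loss
            g_cl = g.transpose(0, 2, 3, 1)
            ign_cl = None
            if any(i is not None for i in igns):
                ign_cl = np.stack([i if i is not None else np.zeros(x.shape[2:], bool) for i in igns])
            loss, dp_cl = weighted_soft_dice_loss_grad(p_cl, g_cl, w, smooth=config.smooth, ignore=ign_cl)
            if not np.isfinite(loss):
                raise RuntimeError(f"non-finite loss at epoch {epoch}: {loss}")
            net.backward(dp_cl.transpose(0, 3, 1, 2))
            opt.step(lr=lr)
            losses.append(loss)
            history["step_loss"].append(float(loss))
        history["epoch_loss"].append(float(np.mean(losses)))
        history["lr"].append(float(lr))

    if config.checkpoint_dir:
        out = Path(config.checkpoint_dir)
        out.mkdir(parents=True, exist_ok=True)
        net.save(out / "model.npz")
        meta = {"train_config": _config_dict(config), "class_order": net.class_order, "history": {
            "epoch_loss": history["epoch_loss"], "lr": history["lr"]}}
        (out / "history.json").write_text(json.dumps(meta, indent=1))
    return history


def _config_dict(config: TrainConfig) -> dict:
    d = asdict(config)
    return d
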