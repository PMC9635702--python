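"""The sex-conditional age-regression model f(X, z; theta).

A convolutional backbone feeds a global-average-pooling vector through
dropout into a dense layer with three ReLU-activated output nodes — one age
estimate per sex group (male, female, unknown).  The final prediction is the
dot product of the three outputs with the one-hot sex code, so sex acts as
prior information selecting a specialized head while the feature extractor is
shared across groups.  Output biases can be initialized at the per-group mean
ages to accelerate convergence; before any training such a model *is* the
group-mean predictor, which doubles as the natural baseline.

Training minimizes the mean squared error of the sex-selected output with an
L2 penalty on the weights, using Adam, train-time augmentation and early
stopping on a validation set.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .pipeline import AugmentSpec, DatasetTable, augment, encode_sex

__all__ = ["ModelConfig", "AgeRegressor", "TrainingHistory", "relu",
           "build_model", "predict_age", "mse_loss",
           "train_with_early_stopping", "random_search"]


def relu(x):
    """max(x, 0); maps any pre-activation to a valid (non-negative) age."""
    return np.maximum(x, 0.0)


@dataclasses.dataclass(frozen=True)
class ModelConfig:
    backbone: str = "tiny"
    input_side: int = 64
    dropout_rate: float = 0.4
    l2_weight: float = 1e-2
    learning_rate: float = 3e-3
    batch_size: int = 32
    freeze_normalization_stats: bool = False
    output_bias_init: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if not 0.0 <= self.dropout_rate <= 0.5:
            raise ValueError("dropout_rate must be in [0, 0.5]")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.backbone not in _BACKBONES:
            raise ValueError(
                f"unknown backbone {self.backbone!r}; options: {sorted(_BACKBONES)}")


def _tiny_backbone(cfg: ModelConfig, rng: np.random.Generator):
    """Three stride-2 conv blocks; adequate for 32-128 px inputs."""
    fz = cfg.freeze_normalization_stats
    layers = []
    c_in = 3
    for c_out in (8, 16, 32):
        layers += [nn.Conv2D(c_in, c_out, kernel=3, stride=2, pad=1, rng=rng),
                   nn.BatchNorm2D(c_out, frozen_stats=fz),
                   nn.ReLU()]
        c_in = c_out
    return layers, c_in


def _paper_scale_backbone(cfg: ModelConfig, rng: np.random.Generator):
    """Five stride-2 conv blocks sized for 256 px inputs.

    A stand-in feature extractor with the same interface contract as a large
    pretrained network; any backbone producing a feature map works here.
    """
    fz = cfg.freeze_normalization_stats
    layers = []
    c_in = 3
    for c_out in (16, 32, 64, 128, 128):
        layers += [nn.Conv2D(c_in, c_out, kernel=3, stride=2, pad=1, rng=rng),
                   nn.BatchNorm2D(c_out, frozen_stats=fz),
                   nn.ReLU()]
        c_in = c_out
    return layers, c_in


_BACKBONES = {"tiny": _tiny_backbone, "paper-scale": _paper_scale_backbone}


@dataclasses.dataclass
class TrainingHistory:
    train_loss: list[float]
    val_loss: list[float]
    best_epoch: int      # 1-based epoch with minimum validation loss
    stopped_epoch: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"epoch": np.arange(1, len(self.train_loss) + 1),
                             "train_loss": self.train_loss,
                             "val_loss": self.val_loss})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


class AgeRegressor:
    """Backbone -> GAP -> dropout -> dense(3) -> ReLU, with sex-selected readout."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        layers, feat = _BACKBONES[config.backbone](config, rng)
        layers += [nn.GlobalAvgPool(), nn.Dropout(config.dropout_rate)]
        self.head = nn.Dense(feat, 3, rng=rng,
                             bias_init=np.asarray(config.output_bias_init))
        self.net = nn.Sequential(layers + [self.head])
        self.out_relu = nn.ReLU()

    # -- forward ------------------------------------------------------------

    def _to_nchw(self, images: np.ndarray) -> np.ndarray:
        images = np.asarray(images, dtype=np.float32)
        if images.ndim == 3:
            images = images[None]
        side = self.config.input_side
        if images.shape[1] != side or images.shape[2] != side:
            raise ValueError(
                f"expected {side}x{side} images, got {images.shape[1:3]}")
        return images.transpose(0, 3, 1, 2)

    def forward(self, images: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        """All three conditional age estimates, shape (N, 3), after ReLU."""
        logits = self.net.forward(self._to_nchw(images), training=training, rng=rng)
        return self.out_relu.forward(logits, training=training)

    def predict(self, images: np.ndarray, sex_codes: np.ndarray,
                batch_size: int = 64) -> np.ndarray:
        """Sex-selected ages for a stack of images; dropout inactive."""
        images = np.asarray(images)
        if images.ndim == 3:
            images = images[None]
        sex_codes = np.atleast_2d(np.asarray(sex_codes, dtype=np.float32))
        outs = []
        for i in range(0, len(images), batch_size):
            out3 = self.forward(images[i:i + batch_size], training=False)
            outs.append((out3 * sex_codes[i:i + batch_size]).sum(axis=1))
        return np.concatenate(outs)

    def predict_with_gradient(self, image: np.ndarray, sex,
                              guided: bool = False):
        """Sex-selected age plus its gradient w.r.t. the input image (H, W, 3).

        ``guided`` switches every ReLU backward pass to propagate positive
        gradients only (guided backpropagation).
        """
        code = encode_sex(sex) if isinstance(sex, str) else np.asarray(sex)
        out3 = self.forward(image, training=False)          # (1, 3)
        pred = float((out3[0] * code).sum())
        dout = (np.zeros_like(out3) + code[None, :]).astype(np.float32)
        grad_logits = self.out_relu.backward(dout, guided=guided)
        self._zero_param_grads()
        grad_in = self.net.backward(grad_logits, guided=guided)
        return pred, grad_in[0].transpose(1, 2, 0).astype(np.float64)

    def predict_batch_with_gradients(self, images: np.ndarray, sex,
                                     guided: bool = False):
        """Vector version over a stack of images sharing one sex code."""
        code = encode_sex(sex) if isinstance(sex, str) else np.asarray(sex)
        out3 = self.forward(images, training=False)
        preds = (out3 * code[None, :]).sum(axis=1)
        dout = np.broadcast_to(code[None, :], out3.shape).astype(np.float32).copy()
        grad_logits = self.out_relu.backward(dout, guided=guided)
        self._zero_param_grads()
        grads = self.net.backward(grad_logits, guided=guided)
        return preds, grads.transpose(0, 2, 3, 1).astype(np.float64)

    # -- parameters ----------------------------------------------------------

    def _zero_param_grads(self):
        for p in self.net.params():
            p.grad[...] = 0.0

    def get_state(self):
        return ([p.value.copy() for p in self.net.params()],
                [(l.running_mean.copy(), l.running_var.copy())
                 for l in self.net.layers if isinstance(l, nn.BatchNorm2D)])

    def set_state(self, state):
        values, bn_stats = state
        for p, v in zip(self.net.params(), values):
            p.value[...] = v
        bn = [l for l in self.net.layers if isinstance(l, nn.BatchNorm2D)]
        for layer, (m, v) in zip(bn, bn_stats):
            layer.running_mean[...] = m
            layer.running_var[...] = v

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        values, bn_stats = self.get_state()
        arrays = {f"param_{i}": v for i, v in enumerate(values)}
        for i, (m, v) in enumerate(bn_stats):
            arrays[f"bn_mean_{i}"] = m
            arrays[f"bn_var_{i}"] = v
        np.savez(path, config=json.dumps(dataclasses.asdict(self.config)),
                 **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "AgeRegressor":
        with np.load(Path(path), allow_pickle=False) as data:
            cfg_dict = json.loads(str(data["config"]))
            cfg_dict["output_bias_init"] = tuple(cfg_dict["output_bias_init"])
            model = cls(ModelConfig(**cfg_dict))
            values = [data[f"param_{i}"] for i in range(len(model.net.params()))]
            n_bn = sum(isinstance(l, nn.BatchNorm2D) for l in model.net.layers)
            bn = [(data[f"bn_mean_{i}"], data[f"bn_var_{i}"]) for i in range(n_bn)]
        model.set_state((values, bn))
        return model


def build_model(config: ModelConfig, seed: int = 0) -> AgeRegressor:
    """Construct an untrained model; with zero head weights and bias init set
    to the group mean ages this is exactly the per-sex-mean predictor."""
    return AgeRegressor(config, seed=seed)


def predict_age(model: AgeRegressor, image: np.ndarray, sex) -> float:
    """Single-image convenience wrapper; always >= 0 by the ReLU contract."""
    code = encode_sex(sex) if isinstance(sex, str) else np.asarray(sex)
    return float(model.predict(image[None] if image.ndim == 3 else image,
                               code[None])[0])


def mse_loss(truth, pred) -> float:
    """Mean squared residual (the training criterion, without the L2 term)."""
    truth = np.asarray(truth, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if truth.shape != pred.shape:
        raise ValueError("truth and pred must have equal length")
    if truth.size == 0:
        raise ValueError("mse_loss requires at least one sample")
    return float(np.mean((truth - pred) ** 2))


def _validation_loss(model: AgeRegressor, table: DatasetTable) -> float:
    preds = model.predict(table.images, table.sex_codes,
                          batch_size=model.config.batch_size)
    return mse_loss(table.read_ages, preds)


def train_with_early_stopping(model: AgeRegressor, train: DatasetTable,
                              val: DatasetTable,
                              augment_spec: AugmentSpec | None = None,
                              patience: int = 20, max_epochs: int = 100,
                              seed: int = 0, val_loss_fn=None):
    """Fit with Adam + MSE on the sex-selected output; early stopping.

    Only training batches are augmented.  Training stops once ``patience``
    epochs pass without improvement of the validation loss (or at
    ``max_epochs``), and the parameters from the best epoch are restored.
    ``val_loss_fn(model, val) -> float`` may replace the default validation
    MSE, e.g. for diagnostics.
    """
    if len(train) == 0 or len(val) == 0:
        raise ValueError("train and validation sets must be non-empty")
    if train.images is None or val.images is None:
        raise ValueError("train and validation sets must carry images")
    overlap = set(train.sample_ids) & set(val.sample_ids)
    if overlap:
        raise ValueError(f"train/validation overlap: {sorted(overlap)[:5]} ...")
    if val_loss_fn is None:
        val_loss_fn = _validation_loss

    cfg = model.config
    rng = np.random.default_rng(seed)
    opt = nn.Adam(model.net.params(), lr=cfg.learning_rate, l2=cfg.l2_weight)
    sex_idx = np.argmax(train.sex_codes, axis=1)
    ages = train.read_ages.astype(np.float32)

    history_train, history_val = [], []
    best_loss, best_epoch, best_state = np.inf, 0, model.get_state()
    stopped_epoch = 0
    for epoch in range(1, max_epochs + 1):
        order = rng.permutation(len(train))
        epoch_losses = []
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            batch = train.images[idx]
            if augment_spec is not None:
                batch = np.stack([augment(im, augment_spec, rng) for im in batch])
            logits = model.net.forward(model._to_nchw(batch), training=True,
                                       rng=rng)
            sel = sex_idx[idx]
            z = logits[np.arange(len(idx)), sel]
            preds = relu(z)
            resid = preds - ages[idx]
            epoch_losses.append(float(np.mean(resid ** 2)))
            dlogits = np.zeros_like(logits)
            dlogits[np.arange(len(idx)), sel] = \
                (2.0 / len(idx)) * resid * (z > 0)
            opt.zero_grad()
            model.net.backward(dlogits)
            opt.step()
        vloss = float(val_loss_fn(model, val))
        history_train.append(float(np.mean(epoch_losses)))
        history_val.append(vloss)
        if vloss < best_loss:
            best_loss, best_epoch = vloss, epoch
            best_state = model.get_state()
        stopped_epoch = epoch
        if epoch - best_epoch >= patience:
            break
    model.set_state(best_state)
    history = TrainingHistory(history_train, history_val,
                              best_epoch=best_epoch,
                              stopped_epoch=stopped_epoch)
    return model, history


DROPOUT_GRID = np.round(np.arange(0, 6) * 0.1, 1)
LR_RANGE = (1e-6, 1e-1)


def sample_dropout(rng: np.random.Generator) -> float:
    """Dropout rate drawn from the linear grid 0, 0.1, ..., 0.5."""
    return float(rng.choice(DROPOUT_GRID))


def sample_learning_rate(rng: np.random.Generator) -> float:
    """Learning rate drawn log-uniformly over 1e-6 .. 1e-1."""
    lo, hi = np.log10(LR_RANGE[0]), np.log10(LR_RANGE[1])
    return float(10.0 ** rng.uniform(lo, hi))


def random_search(train: DatasetTable, val: DatasetTable,
                  base_config: ModelConfig, n_trials: int = 20,
                  augment_spec: AugmentSpec | None = None,
                  patience: int = 20, max_epochs: int = 100, seed: int = 0):
    """Random hyperparameter search over dropout (grid 0..0.5, step 0.1) and
    learning rate (log-uniform over 1e-6..1e-1); returns the best config and
    the full trial table sorted as run."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    rows, best = [], None
    for trial in range(n_trials):
        dropout = sample_dropout(rng)
        lr = sample_learning_rate(rng)
        cfg = dataclasses.replace(base_config, dropout_rate=dropout,
                                  learning_rate=lr)
        mdl = build_model(cfg, seed=seed + trial + 1)
        mdl, hist = train_with_early_stopping(
            mdl, train, val, augment_spec=augment_spec, patience=patience,
            max_epochs=max_epochs, seed=seed + trial + 1)
        vloss = min(hist.val_loss)
        rows.append({"trial": trial, "dropout_rate": dropout,
                     "learning_rate": lr, "val_loss": vloss,
                     "best_epoch": hist.best_epoch})
        if best is None or vloss < best[0]:
            best = (vloss, cfg)
    return best[1], pd.DataFrame(rows)
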