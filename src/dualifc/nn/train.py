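"""Training loop, Adam optimizer, LR schedule and cross-validation.

The reference training recipe: Adam with beta1 = 0.99 and beta2 = 0.9999,
learning rate 1e-5 for the first five epochs then raised to 5e-5, halved
whenever the validation metric (balanced accuracy) fails to improve for
five consecutive epochs, 50 epochs total. Those are the defaults here; a
``desk_config`` preset scales the recipe down (10 epochs, larger rates,
conventional betas) for CPU-scale synthetic experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ..bench import CVResult, confusion, stratified_folds
from ..data import Dataset
from .losses import grad_logits, grad_recon, loss_ce, loss_mse, loss_total, softmax
from .unet import ArchConfig, FusedUNet, desk_arch


@dataclass(frozen=True)
class TrainingConfig:
    """All Fused UNet training hyperparameters."""

    epochs: int = 50
    lr_initial: float = 1e-5
    lr_raised: float = 5e-5
    warmup_epochs: int = 5  # epochs at lr_initial before raising
    plateau_patience: int = 5
    plateau_factor: float = 0.5
    min_delta: float = 1e-4
    batch_size: int = 32
    w1: float = 0.5  # 2D weight inside the reconstruction loss
    w2: float = 0.5  # classification weight in the total loss
    beta1: float = 0.99
    beta2: float = 0.9999
    conventional_betas: bool = False  # switch to Adam's usual (0.9, 0.999)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.w1 <= 1.0 and 0.0 <= self.w2 <= 1.0):
            raise ValueError("w1 and w2 must be in [0, 1]")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")

    @property
    def betas(self) -> tuple[float, float]:
        return (0.9, 0.999) if self.conventional_betas else (self.beta1, self.beta2)


def desk_config(seed: int = 0, epochs: int = 10) -> TrainingConfig:
    """CPU-scale preset: short schedule, proportionally larger rates."""
    return TrainingConfig(
        epochs=epochs,
        lr_initial=1e-3,
        lr_raised=3e-3,
        warmup_epochs=2,
        conventional_betas=True,
        seed=seed,
    )


class Adam:
    """Standard Adam with bias correction over a flat parameter list."""

    def __init__(self, params: list[np.ndarray], betas: tuple[float, float]) -> None:
        self.params = params
        self.beta1, self.beta2 = betas
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0
        self.eps = 1e-8

    def step(self, grads: list[np.ndarray], lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            m_hat = m / (1 - b1**self.t)
            v_hat = v / (1 - b2**self.t)
            p -= lr * m_hat / (np.sqrt(v_hat) + self.eps)


def _as_batches(dataset: Dataset, classes: tuple[str, ...], dtype=np.float32):
    """Dataset -> (x2 (N,1,80,80), x3 (N,1,40,40,40), y_onehot (N,C))."""
    x2 = np.asarray(dataset.transmission, dtype=dtype)[:, None]
    x3 = np.asarray(dataset.ssc, dtype=dtype)[:, None]
    labels = dataset.labels
    y = np.zeros((len(labels), len(classes)), dtype=dtype)
    for i, c in enumerate(classes):
        y[labels == c, i] = 1.0
    return x2, x3, y


def _balanced_accuracy(y_true_idx: np.ndarray, y_pred_idx: np.ndarray, n_classes: int) -> float:
    recalls = []
    for c in range(n_classes):
        sel = y_true_idx == c
        if sel.any():
            recalls.append(float((y_pred_idx[sel] == c).mean()))
    return float(np.mean(recalls))


def evaluate(
    model: FusedUNet, x2: np.ndarray, x3: np.ndarray, y: np.ndarray, batch_size: int = 32
) -> tuple[np.ndarray, float]:
    """Predicted class indices and balanced accuracy, batched."""
    preds = []
    for start in range(0, len(x2), batch_size):
        sl = slice(start, start + batch_size)
        preds.append(model.predict_proba(x2[sl], x3[sl]).argmax(axis=1))
    pred_idx = np.concatenate(preds)
    true_idx = y.argmax(axis=1)
    return pred_idx, _balanced_accuracy(true_idx, pred_idx, y.shape[1])


def train(
    model: FusedUNet,
    train_set: Dataset,
    val_set: Dataset,
    config: TrainingConfig,
    classes: tuple[str, ...] = ("diseased", "healthy"),
) -> dict:
    """Train the fused model; returns the per-epoch history.

    History records, per epoch: the learning rate actually used, the
    epoch-mean total/CE/MSE training losses, and validation balanced
    accuracy. The LR trace follows the warm-up schedule exactly, with
    plateau halving (patience ``plateau_patience``, threshold
    ``min_delta``) applied multiplicatively on top.
    """
    x2, x3, y = _as_batches(train_set, classes, np.dtype(model.arch.dtype))
    vx2, vx3, vy = _as_batches(val_set, classes, np.dtype(model.arch.dtype))
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.params, config.betas)

    history: dict[str, list] = {"lr": [], "loss": [], "ce": [], "mse": [], "val_balanced_accuracy": []}
    plateau_scale = 1.0
    best_metric = -np.inf
    stall = 0
    n = len(x2)
    for epoch in range(1, config.epochs + 1):
        base_lr = config.lr_initial if epoch <= config.warmup_epochs else config.lr_raised
        lr = base_lr * plateau_scale
        order = rng.permutation(n)
        ep_loss, ep_ce, ep_mse, n_batches = 0.0, 0.0, 0.0, 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            bx2, bx3, by = x2[idx], x3[idx], y[idx]
            logits, r2, r3, cache = model.forward(bx2, bx3)
            probs = softmax(logits)
            ce = loss_ce(by, probs)
            mse = loss_mse(bx2, r2, bx3, r3, config.w1)
            total = loss_total(ce, mse, config.w2)
            if not np.isfinite(total):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch} (ce={ce}, mse={mse}, lr={lr})"
                )
            model.zero_grad()
            model.backward(
                grad_logits(by, probs, config.w2).astype(logits.dtype),
                grad_recon(bx2, r2, config.w1, config.w2).astype(r2.dtype),
                grad_recon(bx3, r3, 1.0 - config.w1, config.w2).astype(r3.dtype),
                cache,
            )
            opt.step(model.grads, lr)
            ep_loss += total
            ep_ce += ce
            ep_mse += mse
            n_batches += 1

        _, val_ba = evaluate(model, vx2, vx3, vy, config.batch_size)
        history["lr"].append(lr)
        history["loss"].append(ep_loss / n_batches)
        history["ce"].append(ep_ce / n_batches)
        history["mse"].append(ep_mse / n_batches)
        history["val_balanced_accuracy"].append(val_ba)

        if val_ba > best_metric + config.min_delta:
            best_metric = val_ba
            stall = 0
        else:
            stall += 1
            if stall >= config.plateau_patience:
                plateau_scale *= config.plateau_factor
                stall = 0
    return history


def cross_validate(
    dataset: Dataset,
    arch: ArchConfig | None = None,
    config: TrainingConfig | None = None,
    k: int = 4,
) -> tuple[CVResult, list[dict]]:
    """Stratified k-fold CV of the fused model on a labelled cohort.

    Each fold's held-out cells serve as the validation set during that
    fold's training (driving the plateau rule)
    and are then summarized in the fold's confusion matrix. Returns the
    CVResult plus per-fold training histories.
    """
    if arch is None:
        arch = desk_arch()
    if config is None:
        config = desk_config()
    labels = dataset.labels
    classes = tuple(sorted(np.unique(labels)))
    folds = stratified_folds(labels, k=k, seed=config.seed, subjects=dataset.subjects)
    fold_cms, histories = [], []
    for f in range(k):
        train_idx = np.flatnonzero(folds != f)
        val_idx = np.flatnonzero(folds == f)
        model = FusedUNet(replace(arch, n_classes=len(classes)), seed=config.seed + f)
        try:
            history = train(
                model,
                dataset.select(train_idx),
                dataset.select(val_idx),
                config,
                classes,
            )
        except Exception as exc:
            raise RuntimeError(f"training failed in fold {f}: {exc}") from exc
        vx2, vx3, vy = _as_batches(dataset.select(val_idx), classes, np.dtype(arch.dtype))
        pred_idx, _ = evaluate(model, vx2, vx3, vy, config.batch_size)
        y_pred = np.asarray(classes)[pred_idx]
        fold_cms.append(confusion(labels[val_idx], y_pred, classes))
        histories.append(history)
    result = CVResult(
        model="fused_unet", classes=classes, fold_confusions=fold_cms, seed=config.seed
    )
    return result, histories
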