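"""Loss functions of the fused autoencoder-classifier.

The training objective combines a mini-batch averaged cross-entropy on the
softmax class output with a weighted dual-modality reconstruction MSE:

    L_MSE = (1/N) sum_j [ w1/M2d * ||x2d - x^2d||^2 + (1-w1)/M3d * ||x3d - x^3d||^2 ]
    L     = w2 * L_CE + (1 - w2) * L_MSE

with M2d = 6400 and M3d = 64000 the flattened image dimensions. Cross
entropy uses the natural logarithm; probabilities are clamped at 1e-12.
"""

from __future__ import annotations

import logging

import numpy as np

log = logging.getLogger(__name__)

EPS = 1e-12


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax, computed in the numerically stable shifted form."""
    logits = np.asarray(logits, dtype=float)
    shifted = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def loss_ce(y_onehot: np.ndarray, probs: np.ndarray) -> float:
    """Mini-batch averaged cross-entropy, natural log."""
    y_onehot = np.asarray(y_onehot, dtype=float)
    probs = np.asarray(probs, dtype=float)
    if y_onehot.shape != probs.shape:
        raise ValueError("shape mismatch between targets and predictions")
    if probs.ndim != 2 or probs.shape[0] < 1:
        raise ValueError("expected (N, C) probability batch with N >= 1")
    picked = (y_onehot * probs).sum(axis=1)
    if np.any(picked <= EPS):
        log.warning("predicted probability at true class clamped to %.0e", EPS)
    return float(-np.log(np.clip(picked, EPS, None)).mean())


def loss_mse(
    x2: np.ndarray, xh2: np.ndarray, x3: np.ndarray, xh3: np.ndarray, w1: float = 0.5
) -> float:
    """Weighted dual-modality reconstruction MSE (per-element, batch mean)."""
    if not 0.0 <= w1 <= 1.0:
        raise ValueError("w1 must be in [0, 1]")
    x2, xh2, x3, xh3 = (np.asarray(a, dtype=float) for a in (x2, xh2, x3, xh3))
    if x2.shape != xh2.shape or x3.shape != xh3.shape:
        raise ValueError("input and reconstruction shapes differ")
    n = x2.shape[0]
    m2 = int(np.prod(x2.shape[1:]))
    m3 = int(np.prod(x3.shape[1:]))
    term2 = ((x2 - xh2) ** 2).reshape(n, -1).sum(axis=1) / m2
    term3 = ((x3 - xh3) ** 2).reshape(n, -1).sum(axis=1) / m3
    return float((w1 * term2 + (1.0 - w1) * term3).mean())


def loss_total(ce: float, mse: float, w2: float = 0.5) -> float:
    """Weighted sum of classification and reconstruction losses."""
    if not 0.0 <= w2 <= 1.0:
        raise ValueError("w2 must be in [0, 1]")
    return w2 * ce + (1.0 - w2) * mse


# --- analytic gradients ------------------------------------------------------


def grad_logits(y_onehot: np.ndarray, probs: np.ndarray, w2: float) -> np.ndarray:
    """d(total loss)/d(logits) for softmax + cross-entropy: w2*(p - y)/N."""
    n = y_onehot.shape[0]
    return w2 * (probs - y_onehot) / n


def grad_recon(
    x: np.ndarray, xh: np.ndarray, modality_weight: float, w2: float
) -> np.ndarray:
    """d(total loss)/d(reconstruction) for one modality.

    ``modality_weight`` is w1 for the 2D branch and (1 - w1) for 3D.
    """
    n = x.shape[0]
    m = int(np.prod(x.shape[1:]))
    return (1.0 - w2) * modality_weight * 2.0 * (xh - x) / (n * m)
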