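"""Fused dual-branch UNet autoencoder-classifier.

Two UNet branches — a 2D one for the 80x80 transmission image and a 3D one
for the 40x40x40 side-scatter stack — each contract the input through
conv/ReLU/max-pool levels and expand it back through upsample/skip/conv
levels to a reconstruction of the input. The two bottlenecks are
average-pooled onto a coarse spatial grid, flattened, concatenated, and fed
to a single affine layer whose softmax output is the class prediction.

A coarse pooled grid (default 5 cells per axis) rather than a fully global
average is used for the latent: it keeps the classifier head small while
retaining where structure sits inside the cell, which a global average
destroys.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layers import AdaptiveAvgPool, Affine, AvgPool, ConvND, MaxPool, ReLU, Upsample
from .losses import softmax


@dataclass(frozen=True)
class ArchConfig:
    """Architecture hyperparameters of the fused model.

    Channel widths double per encoder level. ``latent_grid`` is the number
    of pooled cells per axis of each bottleneck. Input spatial sizes are
    fixed by the acquisition contract (80x80 and 40x40x40).
    """

    depth: int = 3
    base_channels_2d: int = 16
    base_channels_3d: int = 8
    latent_grid: int = 5
    n_classes: int = 2
    stem_pool: int = 1  # 1 = native resolution; 2 = half-resolution trunk
    dtype: type = np.float32

    def __post_init__(self) -> None:
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.stem_pool not in (1, 2):
            raise ValueError("stem_pool must be 1 or 2")


def desk_arch(n_classes: int = 2) -> ArchConfig:
    """Quarter-width, half-resolution architecture for CPU-scale runs."""
    return ArchConfig(
        base_channels_2d=4, base_channels_3d=2, n_classes=n_classes, stem_pool=2
    )


class UNetBranch:
    """One modality branch: encoder, decoder with skips, pooled latent."""

    def __init__(
        self,
        ndim: int,
        input_size: int,
        base_channels: int,
        depth: int,
        latent_grid: int,
        rng: np.random.Generator,
        dtype=np.float32,
        stem_pool: int = 1,
    ) -> None:
        self.ndim = ndim
        self.depth = depth
        self.stem_pool = stem_pool
        if stem_pool > 1:
            # half-resolution trunk: average-pool the input once, run the
            # UNet at the reduced grid, upsample before the output conv so
            # the reconstruction keeps the acquisition shape
            self.stem = AvgPool(ndim, stem_pool)
            self.stem_up = Upsample(ndim)
            input_size //= stem_pool
        widths = [base_channels * 2**i for i in range(depth)]
        self.enc = [
            ConvND(1 if i == 0 else widths[i - 1], widths[i], ndim, 3, rng, dtype)
            for i in range(depth)
        ]
        self.dec_up = [ConvND(widths[i + 1], widths[i], ndim, 1, rng, dtype) for i in range(depth - 1)]
        self.dec_mix = [ConvND(2 * widths[i], widths[i], ndim, 3, rng, dtype) for i in range(depth - 1)]
        self.out_conv = ConvND(widths[0], 1, ndim, 1, rng, dtype)
        self.pool = MaxPool(ndim)
        self.up = Upsample(ndim)
        self.relu = ReLU()
        self.avg = AdaptiveAvgPool(ndim, latent_grid)
        bottleneck_size = input_size // 2 ** (depth - 1)
        if bottleneck_size % latent_grid:
            raise ValueError("latent_grid must divide the bottleneck size")
        self.latent_dim = widths[-1] * latent_grid**ndim

    @property
    def layers(self) -> list:
        return self.enc + self.dec_up + self.dec_mix + [self.out_conv]

    def forward(self, x: np.ndarray):
        cache: dict = {"enc": [], "pool": [], "dec": []}
        skips = []
        h = x
        if self.stem_pool > 1:
            h, cache["stem"] = self.stem.forward(h)
        for i, conv in enumerate(self.enc):
            h, c_conv = conv.forward(h)
            h, c_relu = self.relu.forward(h)
            cache["enc"].append((c_conv, c_relu))
            if i < self.depth - 1:
                skips.append(h)
                h, c_pool = self.pool.forward(h)
                cache["pool"].append(c_pool)
        latent_map, c_avg = self.avg.forward(h)
        cache["avg"] = c_avg
        n = x.shape[0]
        latent = latent_map.reshape(n, -1)
        cache["latent_map_shape"] = latent_map.shape

        d = h
        for j, i in enumerate(reversed(range(self.depth - 1))):
            d, c_up = self.up.forward(d)
            d, c_up1 = self.dec_up[i].forward(d)
            d = np.concatenate([d, skips[i]], axis=1)
            d, c_mix = self.dec_mix[i].forward(d)
            d, c_relu = self.relu.forward(d)
            cache["dec"].append((i, c_up, c_up1, c_mix, c_relu))
        if self.stem_pool > 1:
            d, cache["stem_up"] = self.stem_up.forward(d)
        recon, c_out = self.out_conv.forward(d)
        cache["out"] = c_out
        return recon, latent, cache

    def backward(self, drecon: np.ndarray, dlatent: np.ndarray, cache: dict) -> None:
        d = self.out_conv.backward(drecon, cache["out"])
        if self.stem_pool > 1:
            d = self.stem_up.backward(d, cache["stem_up"])
        dskips: dict[int, np.ndarray] = {}
        for i, c_up, c_up1, c_mix, c_relu in reversed(cache["dec"]):
            d = self.relu.backward(d, c_relu)
            d = self.dec_mix[i].backward(d, c_mix)
            width = d.shape[1] // 2
            d, dskip = d[:, :width], d[:, width:]
            dskips[i] = dskip
            d = self.dec_up[i].backward(d, c_up1)
            d = self.up.backward(d, c_up)

        # gradient into the bottleneck: decoder path + pooled latent path
        dlat_map = dlatent.reshape(cache["latent_map_shape"])
        d = d + self.avg.backward(dlat_map, cache["avg"])

        for i in reversed(range(self.depth)):
            c_conv, c_relu = cache["enc"][i]
            if i < self.depth - 1:
                d = self.pool.backward(d, cache["pool"][i])
                d = d + dskips[i]
            d = self.relu.backward(d, c_relu)
            d = self.enc[i].backward(d, c_conv)


class FusedUNet:
    """The dual-modality model: 2D branch + 3D branch + softmax classifier."""

    def __init__(self, arch: ArchConfig | None = None, seed: int = 0) -> None:
        if arch is None:
            arch = ArchConfig()
        self.arch = arch
        rng = np.random.default_rng(seed)
        dtype = arch.dtype
        self.branch2d = UNetBranch(
            2, 80, arch.base_channels_2d, arch.depth, arch.latent_grid, rng, dtype,
            stem_pool=arch.stem_pool,
        )
        self.branch3d = UNetBranch(
            3, 40, arch.base_channels_3d, arch.depth, arch.latent_grid, rng, dtype,
            stem_pool=arch.stem_pool,
        )
        self.classifier = Affine(
            self.branch2d.latent_dim + self.branch3d.latent_dim, arch.n_classes, rng, dtype
        )

    @property
    def layers(self) -> list:
        return self.branch2d.layers + self.branch3d.layers + [self.classifier]

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()

    def forward(self, x2: np.ndarray, x3: np.ndarray):
        """Returns (logits, recon2, recon3, cache)."""
        recon2, lat2, c2 = self.branch2d.forward(x2)
        recon3, lat3, c3 = self.branch3d.forward(x3)
        latent = np.concatenate([lat2, lat3], axis=1)
        logits, c_cls = self.classifier.forward(latent)
        return logits, recon2, recon3, {"b2": c2, "b3": c3, "cls": c_cls, "split": lat2.shape[1]}

    def backward(
        self, dlogits: np.ndarray, drecon2: np.ndarray, drecon3: np.ndarray, cache: dict
    ) -> None:
        dlatent = self.classifier.backward(dlogits, cache["cls"])
        split = cache["split"]
        self.branch2d.backward(drecon2, dlatent[:, :split], cache["b2"])
        self.branch3d.backward(drecon3, dlatent[:, split:], cache["b3"])

    def predict_proba(self, x2: np.ndarray, x3: np.ndarray) -> np.ndarray:
        logits, _, _, _ = self.forward(x2, x3)
        return softmax(logits)
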