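"""Minimal numpy layer framework with explicit backpropagation.

Implements exactly the operations the fused autoencoder-classifier needs:
N-dimensional stride-1 same-padding convolution (2D and 3D), ReLU, 2x max
pooling, 2x nearest-neighbor upsampling, adaptive average pooling and an
affine layer. Every layer exposes ``forward(x) -> (y, cache)`` and
``backward(dy, cache) -> dx`` and accumulates parameter gradients in
``grads``; correctness is validated against central finite differences in
the test suite.

Convolutions use an im2col/GEMM formulation; the input-gradient pass reuses
the same machinery as a correlation with the spatially flipped, channel-
transposed kernel. Batches are processed in chunks to bound the size of the
unfolded column matrix.
"""

from __future__ import annotations

import numpy as np


class Layer:
    """Base class; parameter-free layers leave ``params`` empty."""

    def __init__(self) -> None:
        self.params: list[np.ndarray] = []
        self.grads: list[np.ndarray] = []

    def zero_grad(self) -> None:
        for g in self.grads:
            g[...] = 0.0


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, dtype) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


class ConvND(Layer):
    """Stride-1, same-padding cross-correlation over 2 or 3 spatial dims.

    The kernel is applied by shift-and-accumulate: for each of the k**ndim
    kernel offsets, a strided slice of the padded input is contracted over
    channels with one GEMM. This avoids materializing the full im2col
    matrix, whose layout copy dominates runtime at these channel counts.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        ndim: int,
        kernel_size: int = 3,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ) -> None:
        super().__init__()
        if kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd for same padding")
        if rng is None:
            rng = np.random.default_rng()
        self.cin, self.cout, self.ndim, self.k = in_channels, out_channels, ndim, kernel_size
        fan_in = in_channels * kernel_size**ndim
        self.weight = _he_init(rng, (out_channels, fan_in), fan_in, dtype)
        self.bias = np.zeros(out_channels, dtype=dtype)
        self.dweight = np.zeros_like(self.weight)
        self.dbias = np.zeros_like(self.bias)
        self.params = [self.weight, self.bias]
        self.grads = [self.dweight, self.dbias]

    def _offsets(self):
        from itertools import product

        return list(product(range(self.k), repeat=self.ndim))

    @staticmethod
    def _patch(xp: np.ndarray, offset, spatial):
        sl = (slice(None), slice(None)) + tuple(
            slice(o, o + s) for o, s in zip(offset, spatial)
        )
        return xp[sl]

    @property
    def _spec_fwd(self) -> str:
        s = "ij" if self.ndim == 2 else "ijk"
        return f"nc{s},oc->no{s}"

    @property
    def _spec_dw(self) -> str:
        s = "ij" if self.ndim == 2 else "ijk"
        return f"no{s},nc{s}->oc"

    def _correlate(
        self,
        x: np.ndarray,
        weight: np.ndarray,
        bias: np.ndarray | None,
        xp: np.ndarray | None = None,
    ) -> np.ndarray:
        """Cross-correlate x (n, cin, *S) with weight (cout, cin * k**nd)."""
        spatial = x.shape[2:]
        cout = weight.shape[0]
        cin = x.shape[1]
        if self.k == 1:
            out = np.einsum(self._spec_fwd, x, weight.reshape(cout, cin))
        else:
            if xp is None:
                pad = self.k // 2
                xp = np.pad(x, [(0, 0), (0, 0)] + [(pad, pad)] * self.ndim)
            wr = weight.reshape((cout, cin) + (self.k,) * self.ndim)
            out = None
            for offset in self._offsets():
                patch = self._patch(xp, offset, spatial)
                w_o = wr[(slice(None), slice(None)) + offset]  # (cout, cin)
                term = np.einsum(self._spec_fwd, patch, w_o)
                out = term if out is None else out + term
        if bias is not None:
            out += bias.reshape((1, cout) + (1,) * self.ndim)
        return out

    def forward(self, x: np.ndarray):
        if self.k == 1:
            return self._correlate(x, self.weight, self.bias), (x, None)
        pad = self.k // 2
        xp = np.pad(x, [(0, 0), (0, 0)] + [(pad, pad)] * self.ndim)
        return self._correlate(x, self.weight, self.bias, xp), (x, xp)

    def _flipped_weight(self) -> np.ndarray:
        """Kernel for the input-gradient pass: spatial flip + channel swap."""
        w = self.weight.reshape((self.cout, self.cin) + (self.k,) * self.ndim)
        flip = tuple(slice(None, None, -1) for _ in range(self.ndim))
        w = w[(slice(None), slice(None)) + flip]
        w = np.swapaxes(w, 0, 1)  # (Cin, Cout, *k)
        return np.ascontiguousarray(w).reshape(self.cin, -1)

    def backward(self, dy: np.ndarray, cache) -> np.ndarray:
        x, xp = cache
        spatial = x.shape[2:]
        sum_axes = (0,) + tuple(range(2, 2 + self.ndim))
        if self.k == 1:
            self.dweight += np.einsum(self._spec_dw, dy, x).reshape(self.dweight.shape)
        else:
            dwr = self.dweight.reshape((self.cout, self.cin) + (self.k,) * self.ndim)
            for offset in self._offsets():
                patch = self._patch(xp, offset, spatial)
                dwr[(slice(None), slice(None)) + offset] += np.einsum(
                    self._spec_dw, dy, patch
                )
        self.dbias += dy.sum(axis=sum_axes)
        return self._correlate(dy, self._flipped_weight(), None)


class ReLU(Layer):
    def forward(self, x: np.ndarray):
        mask = x > 0
        return x * mask, mask

    def backward(self, dy: np.ndarray, mask: np.ndarray) -> np.ndarray:
        return dy * mask


def _block_view(x: np.ndarray, factor: int, ndim: int) -> np.ndarray:
    """(N, C, *S) -> (N, C, S1/f, f, S2/f, f, ...)."""
    shape = [x.shape[0], x.shape[1]]
    for dim in x.shape[2:]:
        if dim % factor:
            raise ValueError(f"spatial dim {dim} not divisible by {factor}")
        shape.extend([dim // factor, factor])
    return x.reshape(shape)


class MaxPool(Layer):
    """2x max pooling over all spatial dimensions."""

    def __init__(self, ndim: int) -> None:
        super().__init__()
        self.ndim = ndim
        self.axes = tuple(3 + 2 * i for i in range(ndim))

    def forward(self, x: np.ndarray):
        blocks = _block_view(x, 2, self.ndim)
        out = blocks.max(axis=self.axes)
        expand = out.reshape([s if i not in self.axes else 1 for i, s in enumerate(blocks.shape)])
        mask = blocks == expand
        counts = mask.sum(axis=self.axes, keepdims=True)
        return out, (x.shape, mask, counts)

    def backward(self, dy: np.ndarray, cache) -> np.ndarray:
        x_shape, mask, counts = cache
        dexp = dy.reshape(counts.shape)
        dblocks = mask * (dexp / counts)
        return dblocks.reshape(x_shape)


class Upsample(Layer):
    """2x nearest-neighbor upsampling over all spatial dimensions."""

    def __init__(self, ndim: int) -> None:
        super().__init__()
        self.ndim = ndim
        self.axes = tuple(3 + 2 * i for i in range(ndim))

    def forward(self, x: np.ndarray):
        out = x
        for axis in range(2, 2 + self.ndim):
            out = np.repeat(out, 2, axis=axis)
        return out, x.shape

    def backward(self, dy: np.ndarray, x_shape) -> np.ndarray:
        blocks = _block_view(dy, 2, self.ndim)
        return blocks.sum(axis=self.axes).reshape(x_shape)


class AvgPool(Layer):
    """Average pooling by an integer factor over all spatial dimensions."""

    def __init__(self, ndim: int, factor: int) -> None:
        super().__init__()
        self.ndim = ndim
        self.factor = factor
        self.axes = tuple(3 + 2 * i for i in range(ndim))

    def forward(self, x: np.ndarray):
        blocks = _block_view(x, self.factor, self.ndim)
        return blocks.mean(axis=self.axes), x.shape

    def backward(self, dy: np.ndarray, x_shape) -> np.ndarray:
        out = dy * (1.0 / self.factor**self.ndim)
        for axis in range(2, 2 + self.ndim):
            out = np.repeat(out, self.factor, axis=axis)
        return out


class AdaptiveAvgPool(Layer):
    """Average-pool each spatial axis down to ``out_size`` cells."""

    def __init__(self, ndim: int, out_size: int) -> None:
        super().__init__()
        self.ndim = ndim
        self.out_size = out_size

    def forward(self, x: np.ndarray):
        factor = x.shape[2] // self.out_size
        if any(dim != factor * self.out_size for dim in x.shape[2:]):
            raise ValueError(
                f"spatial dims {x.shape[2:]} not divisible into {self.out_size} cells"
            )
        blocks = _block_view(x, factor, self.ndim)
        axes = tuple(3 + 2 * i for i in range(self.ndim))
        return blocks.mean(axis=axes), (x.shape, factor)

    def backward(self, dy: np.ndarray, cache) -> np.ndarray:
        x_shape, factor = cache
        scale = 1.0 / factor**self.ndim
        out = dy * scale
        for axis in range(2, 2 + self.ndim):
            out = np.repeat(out, factor, axis=axis)
        return out


class Affine(Layer):
    def __init__(
        self,
        in_features: int,
        out_features: int,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ) -> None:
        super().__init__()
        if rng is None:
            rng = np.random.default_rng()
        self.weight = _he_init(rng, (out_features, in_features), in_features, dtype)
        self.bias = np.zeros(out_features, dtype=dtype)
        self.dweight = np.zeros_like(self.weight)
        self.dbias = np.zeros_like(self.bias)
        self.params = [self.weight, self.bias]
        self.grads = [self.dweight, self.dbias]

    def forward(self, x: np.ndarray):
        return x @ self.weight.T + self.bias, x

    def backward(self, dy: np.ndarray, x: np.ndarray) -> np.ndarray:
        self.dweight += dy.T @ x
        self.dbias += dy.sum(axis=0)
        return dy @ self.weight
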