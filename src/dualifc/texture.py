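"""Gray-level co-occurrence texture analysis in 2D and 3D.

A gray-level co-occurrence matrix (GLCM) counts how often a pair of
quantized intensity levels occurs at a fixed spatial displacement inside the
segmented cell. Thirteen second-order (Haralick) statistics are computed per
GLCM and averaged over a fixed set of displacement configurations: four
distances x four angles in 2D (16 matrices) and four offsets x the thirteen
unique directions of the 26-neighborhood in 3D (52 matrices).

Background voxels are excluded from pair counting: quantization assigns a
sentinel level to everything outside the mask and only pairs with both ends
in-mask are counted.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .registry import HARALICK_NAMES

log = logging.getLogger(__name__)

#: Sentinel level for out-of-mask elements; never counted in a GLCM.
BACKGROUND = -1

#: Unit displacement (row, col) for each 2D angle in degrees. Angles follow
#: the usual image convention: 0 deg walks along the positive column axis,
#: 90 deg along the negative row axis.
ANGLE_VECTORS_2D: dict[int, tuple[int, int]] = {
    0: (0, 1),
    45: (-1, 1),
    90: (-1, 0),
    135: (-1, -1),
}


def directions_3d() -> tuple[tuple[int, int, int], ...]:
    """The 13 unique direction vectors of the 26-neighborhood.

    Each voxel has 26 neighbors; opposite displacements produce transposed
    co-occurrence counts, so only one of each +/- pair is kept (first
    non-zero component positive).
    """
    out = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                v = (dz, dy, dx)
                if v == (0, 0, 0):
                    continue
                first = next(c for c in v if c != 0)
                if first > 0:
                    out.append(v)
    assert len(out) == 13
    return tuple(out)


DIRECTIONS_3D: tuple[tuple[int, int, int], ...] = directions_3d()


class EmptyGLCMError(ValueError):
    """No valid in-mask level pairs exist for the requested displacement."""


@dataclass(frozen=True)
class TextureConfig:
    """Configuration of the co-occurrence analysis.

    ``n_levels`` is the gray-level quantization depth L. Distances/offsets
    are in pixels (2D) or voxels (3D). Entropies are reported in bits.
    """

    n_levels: int = 32
    distances_2d: tuple[int, ...] = (1, 2, 3, 4)
    angles_2d: tuple[int, ...] = (0, 45, 90, 135)
    offsets_3d: tuple[int, ...] = (1, 2, 3, 4)
    directions_3d: tuple[tuple[int, int, int], ...] = field(default=DIRECTIONS_3D)
    symmetric: bool = True

    def __post_init__(self) -> None:
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")
        for a in self.angles_2d:
            if a not in ANGLE_VECTORS_2D:
                raise ValueError(f"unsupported 2D angle {a}")

    def displacements_2d(self) -> list[tuple[int, int]]:
        return [
            (d * v[0], d * v[1])
            for d in self.distances_2d
            for v in (ANGLE_VECTORS_2D[a] for a in self.angles_2d)
        ]

    def displacements_3d(self) -> list[tuple[int, int, int]]:
        return [
            (o * v[0], o * v[1], o * v[2])
            for o in self.offsets_3d
            for v in self.directions_3d
        ]


def quantize(image: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    """Linearly bin masked intensities into ``{0..n_levels-1}``.

    Bin edges span [min, max] of the masked values; a constant region maps to
    level 0. Out-of-mask elements receive the :data:`BACKGROUND` sentinel.
    """
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if image.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    if not mask.any():
        raise ValueError("mask is empty")
    vals = image[mask]
    lo, hi = vals.min(), vals.max()
    levels = np.full(image.shape, BACKGROUND, dtype=np.int64)
    if hi == lo:
        levels[mask] = 0
        return levels
    binned = np.floor((vals - lo) / (hi - lo) * n_levels).astype(np.int64)
    levels[mask] = np.clip(binned, 0, n_levels - 1)
    return levels


def glcm(
    levels: np.ndarray,
    displacement: tuple[int, ...],
    n_levels: int,
    symmetric: bool = True,
) -> np.ndarray:
    """Normalized co-occurrence matrix for one displacement vector.

    Counts pairs ``(levels[p], levels[p + displacement])`` with both ends
    inside the mask (level != BACKGROUND), adds the transpose when
    ``symmetric``, and normalizes to unit sum.
    """
    levels = np.asarray(levels)
    if levels.ndim != len(displacement):
        raise ValueError("displacement dimensionality does not match image")
    src_slices, dst_slices = [], []
    for dim, d in zip(levels.shape, displacement):
        if abs(d) >= dim:
            raise EmptyGLCMError(f"displacement {displacement} exceeds image extent")
        if d >= 0:
            src_slices.append(slice(0, dim - d))
            dst_slices.append(slice(d, dim))
        else:
            src_slices.append(slice(-d, dim))
            dst_slices.append(slice(0, dim + d))
    src = levels[tuple(src_slices)].ravel()
    dst = levels[tuple(dst_slices)].ravel()
    valid = (src != BACKGROUND) & (dst != BACKGROUND)
    if not valid.any():
        raise EmptyGLCMError(f"no in-mask pairs for displacement {displacement}")
    pair_index = src[valid] * n_levels + dst[valid]
    counts = np.bincount(pair_index, minlength=n_levels * n_levels).astype(float)
    counts = counts.reshape(n_levels, n_levels)
    if symmetric:
        counts = counts + counts.T
    return counts / counts.sum()


def _entropy_bits(p: np.ndarray) -> float:
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def haralick(P: np.ndarray) -> dict[str, float]:
    """Thirteen second-order texture statistics of a normalized GLCM.

    Entropies are in bits and 0*log(0) is taken as 0. Correlation of a
    degenerate (zero-variance) matrix is defined as 1.
    """
    P = np.asarray(P, dtype=float)
    L = P.shape[0]
    if P.shape != (L, L):
        raise ValueError("GLCM must be square")
    total = P.sum()
    if not np.isclose(total, 1.0):
        raise ValueError("GLCM must be normalized to unit sum")

    i = np.arange(L, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x = float((i * px).sum())
    mu_y = float((i * py).sum())
    sd_x = float(np.sqrt(((i - mu_x) ** 2 * px).sum()))
    sd_y = float(np.sqrt(((i - mu_y) ** 2 * py).sum()))

    # distributions of i+j (0..2L-2) and |i-j| (0..L-1)
    k_sum = np.arange(2 * L - 1, dtype=float)
    p_sum = np.zeros(2 * L - 1)
    np.add.at(p_sum, (ii + jj).astype(int), P)
    k_diff = np.arange(L, dtype=float)
    p_diff = np.zeros(L)
    np.add.at(p_diff, np.abs(ii - jj).astype(int), P)

    if sd_x > 0 and sd_y > 0:
        correlation = float(((ii - mu_x) * (jj - mu_y) * P).sum() / (sd_x * sd_y))
    else:
        correlation = 1.0

    sum_avg = float((k_sum * p_sum).sum())
    diff_mean = float((k_diff * p_diff).sum())
    dev = ii + jj - mu_x - mu_y

    return {
        "energy": float((P**2).sum()),
        "entropy": _entropy_bits(P),
        "contrast": float(((ii - jj) ** 2 * P).sum()),
        "correlation": correlation,
        "homogeneity": float((P / (1.0 + np.abs(ii - jj))).sum()),
        "max_probability": float(P.max()),
        "variance": float(((ii - mu_x) ** 2 * P).sum()),
        "sum_average": sum_avg,
        "sum_entropy": _entropy_bits(p_sum),
        "difference_entropy": _entropy_bits(p_diff),
        "difference_variance": float(((k_diff - diff_mean) ** 2 * p_diff).sum()),
        "cluster_shade": float((dev**3 * P).sum()),
        "cluster_prominence": float((dev**4 * P).sum()),
    }


def average_texture(
    image: np.ndarray,
    mask: np.ndarray,
    config: TextureConfig | None = None,
    ndim: int | None = None,
) -> dict[str, float]:
    """Mean of each of the 13 texture statistics over all configured GLCMs.

    Statistics (not matrices) are averaged across displacements — 16 GLCMs
    in 2D, 52 in 3D. A displacement with no valid in-mask pairs is skipped
    with a warning; if every displacement is skipped an error is raised.
    """
    if config is None:
        config = TextureConfig()
    image = np.asarray(image, dtype=float)
    if ndim is None:
        ndim = image.ndim
    if ndim == 2:
        displacements = config.displacements_2d()
    elif ndim == 3:
        displacements = config.displacements_3d()
    else:
        raise ValueError("only 2D and 3D images are supported")

    levels = quantize(image, mask, config.n_levels)
    per_disp: list[dict[str, float]] = []
    for disp in displacements:
        try:
            P = glcm(levels, disp, config.n_levels, symmetric=config.symmetric)
        except EmptyGLCMError:
            log.warning("skipping displacement %s: no valid pairs", disp)
            continue
        per_disp.append(haralick(P))
    if not per_disp:
        raise EmptyGLCMError("no displacement produced a valid GLCM")
    return {
        name: float(np.mean([d[name] for d in per_disp])) for name in HARALICK_NAMES
    }


def zscore_columns(
    values: np.ndarray, mean: np.ndarray | None = None, sigma: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column-wise z-score ``(r - mean) / sigma`` with population sigma.

    When ``mean``/``sigma`` are given (e.g. from training folds) they are
    applied as-is. Constant columns (sigma == 0) map to zeros.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValueError("expected a 2D matrix (cells x features)")
    if mean is None:
        if values.shape[0] < 2:
            raise ValueError("need at least 2 rows to fit z-score parameters")
        mean = values.mean(axis=0)
        sigma = values.std(axis=0)  # population sigma
    mean = np.asarray(mean, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma == 0):
        warnings.warn("constant feature column(s) mapped to zeros", stacklevel=2)
    safe = np.where(sigma == 0, 1.0, sigma)
    out = (values - mean) / safe
    out[:, sigma == 0] = 0.0
    return out, mean, sigma
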