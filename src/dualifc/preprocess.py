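"""Background removal, global normalization and balanced per-subject sampling."""

from __future__ import annotations

import numpy as np
from skimage.filters import threshold_otsu

from .data import Dataset


def remove_background(image: np.ndarray, tau: float = 0.05, method: str = "fraction") -> np.ndarray:
    """Zero every element below the intensity threshold, leave the rest unchanged.

    ``method='fraction'`` thresholds at ``tau * max(image)``; ``method='otsu'``
    ignores ``tau`` and uses Otsu's threshold. An all-zero image is returned
    unchanged.
    """
    image = np.asarray(image, dtype=float)
    if not 0.0 <= tau <= 1.0:
        raise ValueError("tau must be in [0, 1]")
    out = image.copy()
    peak = out.max()
    if peak <= 0:
        return out
    if method == "fraction":
        threshold = tau * peak
    elif method == "otsu":
        threshold = threshold_otsu(out)
    else:
        raise ValueError(f"unknown method {method!r}")
    out[out < threshold] = 0.0
    return out


def absorbance(transmission: np.ndarray) -> np.ndarray:
    """Convert a bright-background transmission image to absorbance.

    The cell attenuates light, so it is dark on a bright background;
    ``max - image`` flips it into a cell-bright image on which thresholding
    and texture analysis operate naturally.
    """
    transmission = np.asarray(transmission, dtype=float)
    return transmission.max() - transmission


def remove_background_dataset(
    dataset: Dataset, tau: float = 0.05, method: str = "fraction", per_image: bool = True
) -> Dataset:
    """Apply :func:`remove_background` to both modalities of every pair.

    Transmission images are converted to absorbance first so that the cell,
    not the illuminated background, survives thresholding. ``per_image=False``
    thresholds each modality at a single dataset-global level instead.
    """
    t = np.stack([absorbance(np.asarray(dataset.transmission[i])) for i in range(len(dataset))])
    s = np.asarray(dataset.ssc, dtype=float)
    if per_image:
        t = np.stack([remove_background(img, tau, method) for img in t])
        s = np.stack([remove_background(vol, tau, method) for vol in s])
    else:
        for arr in (t, s):
            peak = arr.max()
            if peak > 0:
                arr[arr < tau * peak] = 0.0
    return Dataset(
        transmission=t.astype(np.float32),
        ssc=s.astype(np.float32),
        meta=dataset.meta.copy(),
    )


def normalize_global(dataset: Dataset) -> Dataset:
    """Divide each modality by its dataset-wide maximum intensity.

    Transmission and side-scatter have different dynamic ranges, so each is
    normalized by its own global maximum; afterwards both have max 1.0.
    Idempotent. Raises if a modality is entirely zero.
    """
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    t = np.asarray(dataset.transmission, dtype=np.float32)
    s = np.asarray(dataset.ssc, dtype=np.float32)
    out = []
    for arr, name in ((t, "transmission"), (s, "ssc")):
        peak = float(arr.max())
        if peak <= 0:
            raise ValueError(f"{name} modality is entirely zero")
        out.append(arr / peak)
    return Dataset(transmission=out[0], ssc=out[1], meta=dataset.meta.copy())


def select_balanced_indices(subject_ids: np.ndarray, n_per_subject: int, seed: int) -> np.ndarray:
    """Indices of ``n_per_subject`` cells per subject, without replacement.

    Subjects are processed in sorted order with a fixed RNG, and selected
    indices are returned sorted within each subject, so the selection is a
    pure function of (subject_ids, n_per_subject, seed).
    """
    subject_ids = np.asarray(subject_ids)
    rng = np.random.default_rng(seed)
    chosen = []
    for subject in sorted(np.unique(subject_ids)):
        idx = np.flatnonzero(subject_ids == subject)
        if len(idx) < n_per_subject:
            raise ValueError(
                f"subject {subject!r} has only {len(idx)} pairs, need {n_per_subject}"
            )
        pick = rng.choice(idx, size=n_per_subject, replace=False)
        chosen.append(np.sort(pick))
    return np.concatenate(chosen)


def balance_sample(dataset: Dataset, n_per_subject: int, seed: int = 0) -> Dataset:
    """Class-balancing subsample: exactly ``n_per_subject`` pairs per subject.

    Returns an index-level view (no pixel copy); raises naming the first
    subject with fewer than ``n_per_subject`` pairs.
    """
    indices = select_balanced_indices(dataset.subjects, n_per_subject, seed)
    return dataset.select(indices)
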