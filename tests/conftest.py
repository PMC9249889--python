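"""Shared fixtures: synthetic cohorts and their feature tables.

The heavier cohorts are session-scoped so the classifier-recovery and
permutation-null tests share one generation + feature-extraction pass.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from dualifc.data import SSC_SHAPE, TRANSMISSION_SHAPE, Dataset
from dualifc.features import FeatureTable, extract_table
from dualifc.phantom import PRESETS, CohortDesign, generate_cohort
from dualifc.preprocess import normalize_global, remove_background_dataset
from dualifc.texture import BACKGROUND


def brute_force_glcm(levels, displacement, n_levels, symmetric=True):
    """Exhaustive pair-counting oracle, independent of the vectorized path."""
    counts = np.zeros((n_levels, n_levels))
    for idx in np.ndindex(levels.shape):
        nbr = tuple(int(i) + d for i, d in zip(idx, displacement))
        if all(0 <= n < s for n, s in zip(nbr, levels.shape)):
            a, b = int(levels[idx]), int(levels[nbr])
            if a != BACKGROUND and b != BACKGROUND:
                counts[a, b] += 1
    if symmetric:
        counts = counts + counts.T
    total = counts.sum()
    assert total > 0
    return counts / total


def broadcast_dataset(cells_per_subject: int, subjects: list[tuple[str, str]], seed=0) -> Dataset:
    """Large synthetic cohort whose per-subject images are broadcast views.

    Keeps a 20,000-pair dataset at a few kilobytes: shape and metadata
    contracts are real, pixel data are shared per subject.
    """
    rng = np.random.default_rng(seed)
    t_parts, s_parts, rows = [], [], []
    for subject_id, label in subjects:
        t = rng.random((1,) + TRANSMISSION_SHAPE, dtype=np.float32)
        s = rng.random((1,) + SSC_SHAPE, dtype=np.float32)
        t_parts.append(np.broadcast_to(t, (cells_per_subject,) + TRANSMISSION_SHAPE))
        s_parts.append(np.broadcast_to(s, (cells_per_subject,) + SSC_SHAPE))
        rows += [
            (f"{subject_id}-{i:05d}", subject_id, "HSC", label)
            for i in range(cells_per_subject)
        ]

    class _Concat:
        def __init__(self, parts):
            self.parts = parts
            self.sizes = [len(p) for p in parts]
            self.shape = (sum(self.sizes),) + parts[0].shape[1:]

        def __getitem__(self, i):
            for part, size in zip(self.parts, self.sizes):
                if i < size:
                    return part[i]
                i -= size
            raise IndexError(i)

    meta = pd.DataFrame(rows, columns=["cell_id", "subject_id", "cell_type", "label"])
    return Dataset(transmission=_Concat(t_parts), ssc=_Concat(s_parts), meta=meta)


def make_cohort(preset: str, cells_per_subject: int, seed: int) -> Dataset:
    design = CohortDesign(
        cells_per_subject=cells_per_subject,
        class_params_map=dict(PRESETS[preset]),
        seed=seed,
    )
    return generate_cohort(design)


def preprocessed(dataset: Dataset) -> Dataset:
    return normalize_global(remove_background_dataset(dataset))


@pytest.fixture(scope="session")
def small_cohort() -> Dataset:
    """24 cells, default class contrast — for contract/shape tests."""
    return make_cohort("default", cells_per_subject=6, seed=11)


@pytest.fixture(scope="session")
def strong_cohort() -> Dataset:
    """800 cells across 4 pseudo-subjects with strong class separation."""
    return make_cohort("strong", cells_per_subject=200, seed=7)


@pytest.fixture(scope="session")
def strong_cohort_preprocessed(strong_cohort) -> Dataset:
    return preprocessed(strong_cohort)


@pytest.fixture(scope="session")
def strong_features(strong_cohort_preprocessed) -> FeatureTable:
    frame = extract_table(strong_cohort_preprocessed, transmission_is_absorbance=True)
    return FeatureTable(frame=frame)


@pytest.fixture(scope="session")
def phase_cohort() -> Dataset:
    """800 cells whose classes differ only by radial texture polarity."""
    return make_cohort("texture_phase", cells_per_subject=200, seed=13)


@pytest.fixture(scope="session")
def phase_cohort_preprocessed(phase_cohort) -> Dataset:
    return preprocessed(phase_cohort)


@pytest.fixture(scope="session")
def phase_features(phase_cohort_preprocessed) -> FeatureTable:
    frame = extract_table(phase_cohort_preprocessed, transmission_is_absorbance=True)
    return FeatureTable(frame=frame)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
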