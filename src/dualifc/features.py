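"""Assembly of the 55-feature panel and the z-scored feature table.

Per cell: 15 morphometric + 13 averaged texture features from the 2D
transmission image (28) and 14 morphometric + 13 texture features from the
3D side-scatter stack (27). Column order is fixed by
:data:`dualifc.registry.FEATURE_NAMES`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import morphometry, texture
from .data import Dataset, ImagePair
from .preprocess import absorbance
from .registry import (
    FEATURE_NAMES,
    HARALICK_NAMES,
    META_COLUMNS,
    MORPHOMETRY_2D_NAMES,
    MORPHOMETRY_3D_NAMES,
)


class FeatureExtractionError(RuntimeError):
    """Segmentation or texture failure, tagged with the offending cell."""


def extract_features(
    pair: ImagePair,
    config: texture.TextureConfig | None = None,
    tau: float = 0.05,
    transmission_is_absorbance: bool = False,
) -> pd.Series:
    """The 55-feature vector of one image pair.

    The transmission image is converted to absorbance (cell-bright) before
    segmentation and texture analysis; the side-scatter stack is used
    directly. Pass ``transmission_is_absorbance=True`` for pairs that went
    through :func:`dualifc.preprocess.remove_background_dataset`, which
    already stores absorbance. Returns a Series indexed by registry names.
    """
    if config is None:
        config = texture.TextureConfig()
    a2 = (
        np.asarray(pair.transmission, dtype=float)
        if transmission_is_absorbance
        else absorbance(pair.transmission)
    )
    seg2 = morphometry.segment_cell(a2, tau)
    f2 = morphometry.features_2d(a2, seg2)
    t2 = texture.average_texture(a2, seg2.mask, config, ndim=2)

    v3 = np.asarray(pair.ssc, dtype=float)
    seg3 = morphometry.segment_cell(v3, tau)
    f3 = morphometry.features_3d(v3, seg3)
    t3 = texture.average_texture(v3, seg3.mask, config, ndim=3)

    values = (
        [f2[n] for n in MORPHOMETRY_2D_NAMES]
        + [t2[n] for n in HARALICK_NAMES]
        + [f3[n] for n in MORPHOMETRY_3D_NAMES]
        + [t3[n] for n in HARALICK_NAMES]
    )
    return pd.Series(values, index=list(FEATURE_NAMES), dtype=float)


def extract_table(
    dataset: Dataset,
    config: texture.TextureConfig | None = None,
    tau: float = 0.05,
    transmission_is_absorbance: bool = False,
) -> pd.DataFrame:
    """Feature table for a whole cohort: metadata columns + 55 features."""
    rows = []
    for i in range(len(dataset)):
        pair = dataset.pair(i)
        cell_id = dataset.meta.iloc[i]["cell_id"]
        try:
            feats = extract_features(pair, config, tau, transmission_is_absorbance)
        except Exception as exc:  # re-raise with cell identity
            raise FeatureExtractionError(f"cell {cell_id!r}: {exc}") from exc
        rows.append(
            {
                "cell_id": cell_id,
                "subject_id": pair.subject_id,
                "cell_type": pair.cell_type,
                "label": pair.label,
                **feats.to_dict(),
            }
        )
    return pd.DataFrame(rows, columns=list(META_COLUMNS) + list(FEATURE_NAMES))


@dataclass
class FeatureTable:
    """Feature matrix with explicit normalization state.

    ``state`` is ``"raw"`` or ``"zscored"``; when z-scored, the per-feature
    mean and population sigma used are stored so the same transform can be
    applied to held-out data.
    """

    frame: pd.DataFrame
    state: str = "raw"
    mean: pd.Series | None = None
    sigma: pd.Series | None = None

    def __post_init__(self) -> None:
        missing = [c for c in list(META_COLUMNS) + list(FEATURE_NAMES) if c not in self.frame]
        if missing:
            raise ValueError(f"feature table missing columns: {missing[:5]}...")

    @property
    def values(self) -> np.ndarray:
        return self.frame[list(FEATURE_NAMES)].to_numpy(dtype=float)

    @property
    def labels(self) -> np.ndarray:
        return self.frame["label"].to_numpy()


def zscore(table: FeatureTable) -> FeatureTable:
    """Z-score each feature column to zero mean and unit (population) sigma.

    Constant columns are mapped to zeros with a warning.
    """
    if table.state == "zscored":
        warnings.warn("table is already z-scored; returning as-is", stacklevel=2)
        return table
    vals, mean, sigma = texture.zscore_columns(table.values)
    frame = table.frame.copy()
    frame[list(FEATURE_NAMES)] = vals
    return FeatureTable(
        frame=frame,
        state="zscored",
        mean=pd.Series(mean, index=list(FEATURE_NAMES)),
        sigma=pd.Series(sigma, index=list(FEATURE_NAMES)),
    )


def apply_zscore(table: FeatureTable, mean: pd.Series, sigma: pd.Series) -> FeatureTable:
    """Apply previously fitted z-score parameters (e.g. training-fold stats)."""
    vals, _, _ = texture.zscore_columns(
        table.values, mean.to_numpy(dtype=float), sigma.to_numpy(dtype=float)
    )
    frame = table.frame.copy()
    frame[list(FEATURE_NAMES)] = vals
    return FeatureTable(frame=frame, state="zscored", mean=mean, sigma=sigma)


def write_features(table: FeatureTable | pd.DataFrame, path) -> None:
    """Write the feature table as CSV in exact registry column order."""
    frame = table.frame if isinstance(table, FeatureTable) else table
    frame = frame[list(META_COLUMNS) + list(FEATURE_NAMES)]
    frame.to_csv(path, index=False)


def read_features(path) -> FeatureTable:
    """Read a feature CSV, rejecting any column-order deviation."""
    frame = pd.read_csv(path)
    expected = list(META_COLUMNS) + list(FEATURE_NAMES)
    if list(frame.columns) != expected:
        raise ValueError(
            f"feature CSV columns do not match the registry contract in {path}"
        )
    return FeatureTable(frame=frame)


def write_zscore_params(table: FeatureTable, path) -> None:
    """Save z-score mean/sigma as a JSON sidecar."""
    if table.state != "zscored":
        raise ValueError("table is not z-scored")
    payload = {
        "mean": {k: float(v) for k, v in table.mean.items()},
        "sigma": {k: float(v) for k, v in table.sigma.items()},
    }
    with open(path, "w") as f:
        json.dump(payload, f, indent=1)


def read_zscore_params(path) -> tuple[pd.Series, pd.Series]:
    with open(path) as f:
        payload = json.load(f)
    mean = pd.Series(payload["mean"]).reindex(list(FEATURE_NAMES))
    sigma = pd.Series(payload["sigma"]).reindex(list(FEATURE_NAMES))
    if mean.isna().any() or sigma.isna().any():
        raise ValueError("z-score sidecar does not cover the full feature registry")
    return mean, sigma
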