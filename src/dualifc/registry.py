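"""Fixed feature-panel registry.

The panel is the public contract of the feature-extraction stage: 55 named
features per cell, 28 computed on the 2D transmission image and 27 on the 3D
side-scatter stack. Column order in every feature table and CSV follows the
lists below exactly.
"""

from __future__ import annotations

#: 13 second-order (Haralick) texture statistics, computed from a normalized
#: gray-level co-occurrence matrix and averaged over all direction/offset
#: configurations.
HARALICK_NAMES: tuple[str, ...] = (
    "energy",
    "entropy",
    "contrast",
    "correlation",
    "homogeneity",
    "max_probability",
    "variance",
    "sum_average",
    "sum_entropy",
    "difference_entropy",
    "difference_variance",
    "cluster_shade",
    "cluster_prominence",
)

#: First-order intensity statistics over the segmented cell mask.
FIRST_ORDER_NAMES: tuple[str, ...] = (
    "mean_intensity",
    "std_intensity",
    "min_intensity",
    "max_intensity",
    "integrated_intensity",
)

#: Geometric features of the 2D segmentation (units: µm, µm², rad, or none).
GEOMETRY_2D_NAMES: tuple[str, ...] = (
    "area",
    "perimeter",
    "equivalent_diameter",
    "major_axis_length",
    "minor_axis_length",
    "eccentricity",
    "orientation",
    "solidity",
    "extent",
    "circularity",
)

#: Geometric features of the 3D segmentation (units: µm³, µm², µm, or none).
GEOMETRY_3D_NAMES: tuple[str, ...] = (
    "volume",
    "surface_area",
    "principal_axis_major",
    "principal_axis_intermediate",
    "principal_axis_minor",
    "equivalent_radius",
    "sphericity",
    "extent",
    "solidity",
)

MORPHOMETRY_2D_NAMES: tuple[str, ...] = GEOMETRY_2D_NAMES + FIRST_ORDER_NAMES
MORPHOMETRY_3D_NAMES: tuple[str, ...] = GEOMETRY_3D_NAMES + FIRST_ORDER_NAMES

FEATURE_NAMES_2D: tuple[str, ...] = tuple(
    f"{name}_2d" for name in MORPHOMETRY_2D_NAMES + HARALICK_NAMES
)
FEATURE_NAMES_3D: tuple[str, ...] = tuple(
    f"{name}_3d" for name in MORPHOMETRY_3D_NAMES + HARALICK_NAMES
)

#: The full 55-feature panel, 2D block first.
FEATURE_NAMES: tuple[str, ...] = FEATURE_NAMES_2D + FEATURE_NAMES_3D

#: Metadata columns preceding the feature block in every feature table/CSV.
META_COLUMNS: tuple[str, ...] = ("cell_id", "subject_id", "cell_type", "label")

assert len(FEATURE_NAMES_2D) == 28
assert len(FEATURE_NAMES_3D) == 27
assert len(FEATURE_NAMES) == 55
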