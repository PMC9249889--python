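"""Parametric cell phantoms and dual-modality image rendering.

Stands in for donor hepatic stellate cells (HSC) and liver endothelial
cells (LEC) imaged on a 3D imaging flow cytometer: each phantom is a
randomly oriented ellipsoid carrying a Gaussian-random-field internal
texture and optional low-intensity vacuoles. The 3D side-scatter stack is
the texture field restricted to the cell mask; the 2D transmission image is
a Beer-Lambert attenuation projection along the optic axis.

Class presets encode the qualitative healthy-vs-diseased contrasts the
pipeline is meant to recover: diseased cells have a shorter texture
correlation length (higher co-occurrence entropy, lower homogeneity and
energy), more vacuolation, and a slight volume increase.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import ndtr

from .data import SSC_SHAPE, TRANSMISSION_SHAPE, Dataset

GRID_3D = 40  # voxels per axis, 1 µm pitch
GRID_2D = 80  # pixels per axis, 0.5 µm pitch
FOV_UM = 40.0  # field of view, both modalities

_MAX_RESAMPLE = 25


@dataclass(frozen=True)
class ClassParams:
    """Per-class generative parameters (the effect-size knobs).

    ``texture_corr_len`` is the Gaussian-random-field correlation length in
    µm — shorter means finer texture, hence higher co-occurrence entropy and
    lower homogeneity/energy. ``volume_scale`` multiplies the ellipsoid
    semi-axes, so configured volume ratio = volume_scale**3.
    ``phase_polarity`` (+1/-1/0) superimposes a block-checkerboard pattern
    whose spatial phase encodes the class: invisible to the (translation-
    invariant) texture panel but visible in the raw stack.
    """

    volume_scale: float = 1.0
    texture_corr_len: float = 2.5  # µm
    texture_contrast: float = 0.7
    n_vacuoles: int = 1
    vacuole_radius_range: tuple[float, float] = (1.0, 2.0)  # µm
    base_attenuation: float = 0.04  # per µm
    mean_semi_axes: tuple[float, float, float] = (9.0, 8.0, 7.0)  # µm
    semi_axis_sigma: float = 0.08  # lognormal sigma
    phase_polarity: float = 0.0
    transmission_texture_coupling: float = 1.0

    def validate(self) -> None:
        positive = {
            "volume_scale": self.volume_scale,
            "texture_corr_len": self.texture_corr_len,
            "texture_contrast": self.texture_contrast,
            "semi_axis_sigma": self.semi_axis_sigma,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.n_vacuoles < 0:
            raise ValueError("n_vacuoles must be >= 0")
        if self.base_attenuation < 0:
            raise ValueError("base_attenuation must be >= 0")
        lo, hi = self.vacuole_radius_range
        if not 0 < lo <= hi:
            raise ValueError("vacuole_radius_range must be increasing and positive")
        if any(a <= 0 for a in self.mean_semi_axes):
            raise ValueError("mean_semi_axes must be strictly positive")


@dataclass(frozen=True)
class RenderConfig:
    """Rendering parameters shared across classes."""

    i0: float = 1.0  # incident transmission intensity
    vacuole_factor: float = 0.2  # intensity/attenuation depression inside vacuoles
    noise_sigma_2d: float = 0.005
    noise_sigma_3d: float = 0.01


@dataclass(frozen=True)
class CellPhantom:
    """Sampled 3D cell model from which an image pair is rendered."""

    semi_axes: np.ndarray  # µm, (3,)
    center: np.ndarray  # µm, (3,)
    rotation: np.ndarray  # (3, 3) orthonormal
    texture_field: np.ndarray  # (40, 40, 40) in [0, 1]
    vacuoles: tuple[tuple[np.ndarray, float], ...]  # (center µm, radius µm)
    mask: np.ndarray  # boolean (40, 40, 40)
    base_attenuation: float
    transmission_texture_coupling: float


def _voxel_coords() -> np.ndarray:
    """Voxel-center coordinates in µm, shape (3, 40, 40, 40)."""
    c = np.arange(GRID_3D) + 0.5
    return np.stack(np.meshgrid(c, c, c, indexing="ij"))


_COORDS = _voxel_coords()


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Haar-uniform rotation via QR of a Gaussian matrix."""
    m = rng.standard_normal((3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def _ellipsoid_radius_field(
    semi_axes: np.ndarray, center: np.ndarray, rotation: np.ndarray
) -> np.ndarray:
    """Normalized ellipsoidal radius (<= 1 inside) on the voxel grid."""
    rel = _COORDS - center[:, None, None, None]
    local = np.einsum("ji,jabc->iabc", rotation, rel)
    return np.sqrt(((local / semi_axes[:, None, None, None]) ** 2).sum(axis=0))


def _gaussian_random_field(
    rng: np.random.Generator, corr_len: float, shape=SSC_SHAPE
) -> np.ndarray:
    """Smoothed white noise mapped through the normal CDF to uniform [0, 1]."""
    noise = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(noise, sigma=corr_len, mode="wrap")
    sd = smooth.std()
    if sd == 0:
        return np.full(shape, 0.5)
    return ndtr((smooth - smooth.mean()) / sd)


def sample_phantom(params: ClassParams, rng: np.random.Generator) -> CellPhantom:
    """Draw one phantom; resamples geometry that would clip the field of view."""
    params.validate()
    half = FOV_UM / 2.0
    for _ in range(_MAX_RESAMPLE):
        semi = (
            np.asarray(params.mean_semi_axes)
            * params.volume_scale
            * rng.lognormal(0.0, params.semi_axis_sigma, size=3)
        )
        rotation = _random_rotation(rng)
        center = half + rng.uniform(-4.0, 4.0, size=3)
        # half-extent of the rotated ellipsoid along each grid axis
        extent = np.sqrt((rotation**2 * semi**2).sum(axis=1))
        if np.all(center - extent >= 1.0) and np.all(center + extent <= FOV_UM - 1.0):
            break
    else:
        raise RuntimeError("could not fit a phantom inside the field of view")

    radius = _ellipsoid_radius_field(semi, center, rotation)
    mask = radius <= 1.0

    if params.phase_polarity != 0.0:
        # Co-occurrence-neutral phase contrast: a period-4 3D block
        # checkerboard whose spatial phase flips with polarity. A phase
        # flip is a 2-voxel translation of the pattern, and co-occurrence
        # counting is translation-invariant, so every panel feature is
        # blind to it up to the random mask/lattice alignment (the cell
        # center jitter spans a full pattern period). The absolute lattice
        # phase is, however, plainly visible in the raw stack.
        iz, iy, ix = np.indices(radius.shape)
        parity = ((iz // 2 + iy // 2 + ix // 2) % 2).astype(float)
        sign = (2.0 * parity - 1.0) * params.phase_polarity
        wiggle = rng.random(radius.shape)
        texture = 0.5 + 0.5 * params.texture_contrast * sign + 0.15 * (wiggle - 0.5)
    else:
        grf = _gaussian_random_field(rng, params.texture_corr_len)
        texture = 0.5 + params.texture_contrast * (grf - 0.5)
    texture = np.clip(texture, 0.0, 1.0)

    vacuoles = []
    for _ in range(params.n_vacuoles):
        r_vac = rng.uniform(*params.vacuole_radius_range)
        inner = np.clip(semi - r_vac, 0.1, None)
        for _ in range(_MAX_RESAMPLE):
            local = rng.uniform(-1.0, 1.0, size=3) * inner
            if ((local / inner) ** 2).sum() <= 1.0:
                vacuoles.append((center + rotation @ local, float(r_vac)))
                break

    return CellPhantom(
        semi_axes=semi,
        center=center,
        rotation=rotation,
        texture_field=texture,
        vacuoles=tuple(vacuoles),
        mask=mask,
        base_attenuation=params.base_attenuation,
        transmission_texture_coupling=params.transmission_texture_coupling,
    )


def _vacuole_map(phantom: CellPhantom, factor: float) -> np.ndarray:
    """Multiplicative intensity map: ``factor`` inside vacuoles, 1 elsewhere."""
    out = np.ones(SSC_SHAPE)
    for center, radius in phantom.vacuoles:
        dist2 = ((_COORDS - center[:, None, None, None]) ** 2).sum(axis=0)
        out[dist2 <= radius**2] = factor
    return out


def render_pair(
    phantom: CellPhantom,
    config: RenderConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Render (transmission 80x80, ssc 40x40x40) from a phantom.

    SSC is the masked texture field with vacuoles imposed as low-intensity
    spheres. Transmission is ``i0 * exp(-optical depth)`` where the
    attenuation coefficient is ``base_attenuation * (1 + coupling *
    (texture - 0.5))`` inside the mask, integrated along the first grid
    axis and bilinearly resampled onto the 0.5 µm pixel grid.
    """
    if config is None:
        config = RenderConfig()
    vac = _vacuole_map(phantom, config.vacuole_factor)
    ssc = phantom.texture_field * phantom.mask * vac

    mu = (
        phantom.base_attenuation
        * (1.0 + phantom.transmission_texture_coupling * (phantom.texture_field - 0.5))
        * phantom.mask
        * vac
    )
    optical_depth = mu.sum(axis=0) * 1.0  # 1 µm voxel path length
    od80 = ndimage.zoom(optical_depth, 2, order=1, mode="nearest", grid_mode=True)
    transmission = config.i0 * np.exp(-od80)

    if rng is not None:
        if config.noise_sigma_3d > 0:
            ssc = ssc + rng.normal(0.0, config.noise_sigma_3d, SSC_SHAPE)
        if config.noise_sigma_2d > 0:
            transmission = transmission + rng.normal(0.0, config.noise_sigma_2d, TRANSMISSION_SHAPE)
    return np.clip(transmission, 0.0, None), np.clip(ssc, 0.0, None)


# --- class presets -----------------------------------------------------------

#: Diseased cells: ~10% larger volume, finer texture (higher entropy, lower
#: homogeneity/energy), more vacuolation, slightly denser attenuation.
PRESETS: dict[str, dict[str, ClassParams]] = {
    "default": {
        "healthy": ClassParams(),
        "diseased": ClassParams(
            volume_scale=1.10 ** (1.0 / 3.0),
            texture_corr_len=1.2,
            texture_contrast=0.85,
            n_vacuoles=4,
            vacuole_radius_range=(1.0, 2.5),
            base_attenuation=0.045,
        ),
    },
    # Strongly separated classes for classifier recovery experiments.
    "strong": {
        "healthy": ClassParams(texture_corr_len=3.0, texture_contrast=0.5, n_vacuoles=0),
        "diseased": ClassParams(
            volume_scale=1.30 ** (1.0 / 3.0),
            texture_corr_len=1.0,
            texture_contrast=1.0,
            n_vacuoles=5,
            vacuole_radius_range=(1.5, 3.0),
            base_attenuation=0.06,
        ),
    },
    # Classes differ only in the spatial phase of a periodic 3D texture:
    # geometry, first-order statistics and co-occurrence statistics match by
    # construction (co-occurrence counting is translation-invariant), so the
    # 55-feature panel is blind to the difference while the raw images are
    # not.
    "texture_phase": {
        "healthy": ClassParams(n_vacuoles=0, phase_polarity=1.0,
                               transmission_texture_coupling=0.0),
        "diseased": ClassParams(n_vacuoles=0, phase_polarity=-1.0,
                                transmission_texture_coupling=0.0),
    },
}


@dataclass(frozen=True)
class CohortDesign:
    """Study design: subjects per class, cells per subject, seed."""

    cells_per_subject: int
    n_subjects_per_class: int = 2
    cell_type: str = "HSC"
    class_params_map: dict[str, ClassParams] = field(
        default_factory=lambda: dict(PRESETS["default"])
    )
    render_config: RenderConfig = field(default_factory=RenderConfig)
    seed: int = 0

    def validate(self) -> None:
        if self.cells_per_subject < 1 or self.n_subjects_per_class < 1:
            raise ValueError("counts must be >= 1")
        if set(self.class_params_map) != {"healthy", "diseased"}:
            raise ValueError("class_params_map must have 'healthy' and 'diseased'")
        for params in self.class_params_map.values():
            params.validate()


def generate_cohort(design: CohortDesign) -> Dataset:
    """Generate the full labelled cohort deterministically from the design.

    Each subject receives an independent child RNG stream spawned from the
    master seed, so any subject can be regenerated in isolation.
    """
    design.validate()
    subjects = []
    for label_idx, label in enumerate(("healthy", "diseased")):
        for s in range(design.n_subjects_per_class):
            subjects.append((f"{design.cell_type}-{label[0].upper()}{s + 1}", label, label_idx, s))

    master = np.random.SeedSequence(design.seed)
    children = master.spawn(len(subjects))

    n_total = design.cells_per_subject * len(subjects)
    transmission = np.empty((n_total,) + TRANSMISSION_SHAPE, dtype=np.float32)
    ssc = np.empty((n_total,) + SSC_SHAPE, dtype=np.float32)
    rows = []
    i = 0
    for (subject_id, label, _, _), child in zip(subjects, children):
        rng = np.random.default_rng(child)
        params = design.class_params_map[label]
        for c in range(design.cells_per_subject):
            phantom = sample_phantom(params, rng)
            t, v = render_pair(phantom, design.render_config, rng)
            transmission[i] = t
            ssc[i] = v
            rows.append((f"{subject_id}-{c:05d}", subject_id, design.cell_type, label))
            i += 1
    meta = pd.DataFrame(rows, columns=["cell_id", "subject_id", "cell_type", "label"])
    return Dataset(transmission=transmission, ssc=ssc, meta=meta)


def save_design(design: CohortDesign, path) -> None:
    """Serialize a cohort design (including class parameters) to YAML."""
    import yaml

    design.validate()
    payload = {
        "cells_per_subject": design.cells_per_subject,
        "n_subjects_per_class": design.n_subjects_per_class,
        "cell_type": design.cell_type,
        "seed": design.seed,
        "render_config": {k: list(v) if isinstance(v, tuple) else v
                          for k, v in vars(design.render_config).items()},
        "class_params_map": {
            label: {k: list(v) if isinstance(v, tuple) else v for k, v in vars(p).items()}
            for label, p in design.class_params_map.items()
        },
    }
    with open(path, "w") as f:
        yaml.safe_dump(payload, f)


def load_design(path) -> CohortDesign:
    import yaml

    with open(path) as f:
        payload = yaml.safe_load(f)

    def _tuples(d: dict) -> dict:
        return {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}

    design = CohortDesign(
        cells_per_subject=payload["cells_per_subject"],
        n_subjects_per_class=payload["n_subjects_per_class"],
        cell_type=payload["cell_type"],
        seed=payload["seed"],
        render_config=RenderConfig(**_tuples(payload["render_config"])),
        class_params_map={
            label: ClassParams(**_tuples(params))
            for label, params in payload["class_params_map"].items()
        },
    )
    design.validate()
    return design


def subject_cells(design: CohortDesign, subject_index: int) -> Dataset:
    """Regenerate a single subject's cells from the master seed."""
    design.validate()
    single = replace(design, n_subjects_per_class=1)
    labels = ["healthy"] * design.n_subjects_per_class + ["diseased"] * design.n_subjects_per_class
    if not 0 <= subject_index < len(labels):
        raise IndexError("subject_index out of range")
    child = np.random.SeedSequence(design.seed).spawn(len(labels))[subject_index]
    rng = np.random.default_rng(child)
    label = labels[subject_index]
    params = design.class_params_map[label]
    s_in_class = subject_index % design.n_subjects_per_class
    subject_id = f"{design.cell_type}-{label[0].upper()}{s_in_class + 1}"
    transmission = np.empty((design.cells_per_subject,) + TRANSMISSION_SHAPE, dtype=np.float32)
    ssc = np.empty((design.cells_per_subject,) + SSC_SHAPE, dtype=np.float32)
    rows = []
    for c in range(design.cells_per_subject):
        phantom = sample_phantom(params, rng)
        t, v = render_pair(phantom, single.render_config, rng)
        transmission[c] = t
        ssc[c] = v
        rows.append((f"{subject_id}-{c:05d}", subject_id, design.cell_type, label))
    meta = pd.DataFrame(rows, columns=["cell_id", "subject_id", "cell_type", "label"])
    return Dataset(transmission=transmission, ssc=ssc, meta=meta)
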