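"""Temporal encoding/decoding of the optical-sectioning readout.

The flow cytometer sections each cell chronologically: a light sheet scans
the fast axis at 200 kHz, a pinhole array on the side image plane separates
depth planes, and the cell's own flow advances the slow axis. The detector
therefore emits one long temporal intensity sequence per cell, and the image
is recovered by the temporal-spatial transformation — a fixed bijection
between sample index and voxel/pixel coordinate.

Geometry is idealized (no crosstalk, no blur, flow exactly synchronized with
the scan), so encode followed by decode is the identity. Axis convention
shared by all modules: axis 0 = flow (slowest), axis 1 = pinhole/depth,
axis 2 = light-sheet scan (fastest). A 2D image uses (flow, scan).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import h5py
import numpy as np
import yaml


@dataclass(frozen=True)
class ScanConfig:
    """Scan geometry and rates.

    With a 200 kHz scan and one 1 µm voxel column per scan period, the flow
    speed that keeps slices contiguous is 1 µm x 200 kHz = 2e5 µm/s.
    """

    scan_rate: float = 200_000.0  # Hz
    n_pinholes: int = 40  # one per depth plane
    samples_per_scan: int = 40  # voxels along the light-sheet axis
    flow_speed: float = 200_000.0  # µm/s
    noise_sigma: float = 0.0

    def __post_init__(self) -> None:
        if min(self.scan_rate, self.n_pinholes, self.samples_per_scan, self.flow_speed) <= 0:
            raise ValueError("all scan parameters must be positive")

    def check_shape(self, shape: tuple[int, ...]) -> None:
        if len(shape) == 3:
            if shape[1] != self.n_pinholes or shape[2] != self.samples_per_scan:
                raise ValueError(
                    f"volume shape {shape} inconsistent with "
                    f"{self.n_pinholes} pinholes x {self.samples_per_scan} samples/scan"
                )
        elif len(shape) == 2:
            if shape[1] != self.samples_per_scan * 2:
                raise ValueError(
                    f"2D image shape {shape} inconsistent with scan width "
                    f"{self.samples_per_scan * 2}"
                )
        else:
            raise ValueError("only 2D and 3D shapes are supported")


@dataclass(frozen=True)
class TemporalSignal:
    """Ordered detector samples for one cell plus the shape they encode."""

    samples: np.ndarray
    shape: tuple[int, ...]
    config: ScanConfig

    def __post_init__(self) -> None:
        if self.samples.ndim != 1:
            raise ValueError("samples must be a 1D sequence")
        if len(self.samples) != int(np.prod(self.shape)):
            raise ValueError(
                f"signal length {len(self.samples)} != product of shape {self.shape}"
            )


def index_map(t, shape: tuple[int, ...]):
    """Sample index -> grid coordinate bijection.

    The scan axis is fastest, the pinhole axis next, the flow axis slowest;
    i.e. row-major order over (flow, pinhole, scan).
    """
    return np.unravel_index(t, shape)


def inverse_index_map(coords, shape: tuple[int, ...]):
    """Grid coordinate -> sample index (inverse of :func:`index_map`)."""
    return np.ravel_multi_index(coords, shape)


def encode_volume(
    volume: np.ndarray,
    config: ScanConfig | None = None,
    rng: np.random.Generator | None = None,
) -> TemporalSignal:
    """Section a volume (or 2D image) into its temporal detector sequence."""
    if config is None:
        config = ScanConfig()
    volume = np.asarray(volume, dtype=float)
    config.check_shape(volume.shape)
    t = np.arange(volume.size)
    samples = volume[index_map(t, volume.shape)]
    if config.noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng()
        samples = samples + rng.normal(0.0, config.noise_sigma, samples.shape)
    return TemporalSignal(samples=samples, shape=volume.shape, config=config)


def write_signal(signal: TemporalSignal, path) -> None:
    """Store a temporal signal (plus its scan configuration) as HDF5."""
    with h5py.File(path, "w") as f:
        dset = f.create_dataset("samples", data=signal.samples)
        dset.attrs["shape"] = signal.shape
        for key, value in asdict(signal.config).items():
            dset.attrs[f"config_{key}"] = value


def read_signal(path) -> TemporalSignal:
    with h5py.File(path, "r") as f:
        dset = f["samples"]
        config = ScanConfig(
            **{
                key[len("config_"):]: value.item() if hasattr(value, "item") else value
                for key, value in dset.attrs.items()
                if key.startswith("config_")
            }
        )
        return TemporalSignal(
            samples=dset[()], shape=tuple(int(s) for s in dset.attrs["shape"]), config=config
        )


def save_scan_config(config: ScanConfig, path) -> None:
    """Serialize a scan configuration to YAML."""
    with open(path, "w") as f:
        yaml.safe_dump(asdict(config), f)


def load_scan_config(path) -> ScanConfig:
    with open(path) as f:
        return ScanConfig(**yaml.safe_load(f))


def decode_signal(signal: TemporalSignal, config: ScanConfig | None = None) -> np.ndarray:
    """Temporal-spatial transformation: place samples back on the grid.

    Exactly inverts :func:`encode_volume` when the noise level is zero.
    """
    if config is None:
        config = signal.config
    config.check_shape(signal.shape)
    if len(signal.samples) != int(np.prod(signal.shape)):
        raise ValueError("signal length does not match its declared shape")
    out = np.empty(signal.shape, dtype=float)
    t = np.arange(out.size)
    out[index_map(t, signal.shape)] = signal.samples
    return out
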