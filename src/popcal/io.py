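"""Readers and writers: TIFF stacks, protocol files, trace stores, configs.

Conventions enforced here and assumed everywhere: times in seconds,
lengths in µm, pixel indices 0-based.  Movies are multi-page TIFF (one
page per frame) with physical metadata in a YAML sidecar; traces live in
HDF5; small tables are CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import h5py
import numpy as np
import tifffile
import yaml

from .errors import ConfigurationError, FormatError
from .protocol import StimulusProtocol

__all__ = [
    "FrameStack",
    "read_stack",
    "write_stack",
    "read_protocol",
    "write_protocol",
    "write_traces",
    "read_traces",
    "RunConfig",
]


@dataclass
class FrameStack:
    """A movie: (frames, rows, cols) with physical pixel size and rate."""

    data: np.ndarray
    pixel_size: float  # µm/pixel
    frame_rate: float  # Hz

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ConfigurationError("FrameStack data must be (frames, rows, cols)")


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.yaml")


def write_stack(stack: FrameStack, path: str | Path) -> Path:
    """Write a multi-page TIFF plus a YAML metadata sidecar.

    16-bit integer data round trips losslessly; float data is stored as
    float32.
    """
    path = Path(path)
    data = stack.data
    if not np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float32)
    # one grayscale page per frame (a 3-frame stack must not become RGB)
    tifffile.imwrite(path, data, photometric="minisblack")
    meta = {
        "pixel_size_um": float(stack.pixel_size),
        "frame_rate_hz": float(stack.frame_rate),
        "n_frames": int(stack.data.shape[0]),
    }
    _sidecar(path).write_text(yaml.safe_dump(meta))
    return path


def read_stack(path: str | Path) -> FrameStack:
    """Read a multi-page TIFF written by :func:`write_stack`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such stack: {path}")
    try:
        data = tifffile.imread(path)
    except Exception as exc:  # pragma: no cover - passthrough detail
        raise FormatError(f"malformed TIFF {path}: {exc}") from exc
    if data.ndim == 2:
        data = data[None, ...]
    side = _sidecar(path)
    if side.exists():
        meta = yaml.safe_load(side.read_text())
        pixel_size = float(meta.get("pixel_size_um", 1.0))
        frame_rate = float(meta.get("frame_rate_hz", 1.0))
        n = meta.get("n_frames")
        if n is not None and int(n) != data.shape[0]:
            raise FormatError(
                f"{path}: sidecar says {n} frames, file has {data.shape[0]}"
            )
    else:
        pixel_size, frame_rate = 1.0, 1.0
    return FrameStack(data=data, pixel_size=pixel_size, frame_rate=frame_rate)


# ----------------------------------------------------------------------
# protocol files
def write_protocol(protocol: StimulusProtocol, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(protocol.to_dict()))
    return path


def read_protocol(path: str | Path) -> StimulusProtocol:
    """Read a protocol YAML; unknown keys are rejected with a message."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such protocol file: {path}")
    d = yaml.safe_load(path.read_text())
    if not isinstance(d, dict):
        raise FormatError(f"{path}: protocol file must be a mapping")
    try:
        return StimulusProtocol.from_dict(d)
    except ConfigurationError as exc:
        raise FormatError(f"{path}: {exc}") from exc


# ----------------------------------------------------------------------
# trace stores (HDF5)
def write_traces(
    path: str | Path,
    protocol: StimulusProtocol,
    raw: np.ndarray,
    neuropil: np.ndarray,
    corrected: np.ndarray | None = None,
    dff: np.ndarray | None = None,
    f0: np.ndarray | None = None,
    excluded: np.ndarray | None = None,
) -> Path:
    """Store per-cell traces; ``raw``/``neuropil`` are
    (n_cells, session_frames) or (n_cells, n_trials, frames)."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["protocol"] = yaml.safe_dump(protocol.to_dict())
        f.create_dataset("raw", data=raw)
        f.create_dataset("neuropil", data=neuropil)
        for name, arr in (("corrected", corrected), ("dff", dff), ("f0", f0),
                          ("excluded", excluded)):
            if arr is not None:
                f.create_dataset(name, data=arr)
    return path


def read_traces(path: str | Path) -> tuple[StimulusProtocol, dict[str, np.ndarray]]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such trace store: {path}")
    with h5py.File(path, "r") as f:
        protocol = StimulusProtocol.from_dict(yaml.safe_load(f.attrs["protocol"]))
        data = {k: f[k][...] for k in f.keys()}
    n_frames = data["raw"].shape[-1]
    if data["raw"].ndim == 2 and n_frames % protocol.frames_per_trial != 0:
        raise FormatError(
            f"{path}: {n_frames} frames not a multiple of "
            f"{protocol.frames_per_trial} frames/trial"
        )
    return protocol, data


# ----------------------------------------------------------------------
# run configuration
@dataclass
class RunConfig:
    """Resolved configuration of one analysis run.

    Serialized next to every output directory so a run is reproducible
    from its artifacts alone.
    """

    indicator: str = "fast"
    r: float = 0.7
    exclusion_margin: float = 0.03
    alpha: float = 0.01
    dff_threshold: float = 0.05
    baseline_window_s: float | None = None
    protocol: dict = field(default_factory=lambda: StimulusProtocol().to_dict())
    seed: int = 0
    n_cells: int = 50
    tuned_fraction: float = 0.3

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(asdict(self)))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def make_protocol(self) -> StimulusProtocol:
        return StimulusProtocol.from_dict(self.protocol)
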