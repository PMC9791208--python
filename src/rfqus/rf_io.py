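"""RF data model, file I/O, envelope detection and B-mode conversion.

The on-disk format is deliberately simple and open: a flat little-endian
32-bit float binary holding the raw RF samples in axial-fastest order
(axial index varies fastest, then beam, then frame), paired with a plain
``key=value`` text sidecar carrying the acquisition metadata. Vendor RF
containers are proprietary; converters should target this layout.

Conventions used throughout the package:

* arrays are indexed ``[axial, beam, frame]`` — axial rows are fast time,
  beams are columns, frames are slow time;
* ROIs are 0-based and half-open (``row0:row0+height``);
* axial distance per sample is ``c / (2 * fs)`` (two-way pulse-echo travel).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy.signal import hilbert

from .errors import (
    BoundsError,
    DegenerateImageError,
    InvalidSignalError,
    MalformedFileError,
    SchemaError,
)

__all__ = [
    "AcquisitionMeta",
    "RFFrameStack",
    "EnvelopeImage",
    "ROIRect",
    "read_rf_stack",
    "write_rf_stack",
    "hilbert_envelope",
    "log_compress",
    "mm_to_pixels",
    "extract_roi",
    "save_bmode_png",
    "read_roi_table",
    "write_roi_table",
]

_META_FIELDS = (
    "sample_rate",
    "center_frequency",
    "sound_speed",
    "beam_pitch",
    "frame_rate",
    "n_axial",
    "n_beams",
    "n_frames",
)


@dataclass(frozen=True)
class AcquisitionMeta:
    """Acquisition parameters attached to every RF stack.

    Parameters
    ----------
    sample_rate : float
        Axial (fast-time) sampling rate in Hz.
    center_frequency : float
        Probe center frequency in Hz.
    sound_speed : float
        Assumed speed of sound in cm/s (clinical convention; 154,000 cm/s
        corresponds to the usual 1,540 m/s soft-tissue value).
    beam_pitch : float
        Lateral spacing between adjacent beams in mm.
    frame_rate : float
        Slow-time frame rate in Hz.
    n_axial, n_beams, n_frames : int
        Array dimensions.
    """

    sample_rate: float = 3.2e7
    center_frequency: float = 4.0e6
    sound_speed: float = 154_000.0
    beam_pitch: float = 0.3
    frame_rate: float = 20.0
    n_axial: int = 0
    n_beams: int = 0
    n_frames: int = 0

    def __post_init__(self) -> None:
        for name in ("sample_rate", "center_frequency", "sound_speed", "beam_pitch", "frame_rate"):
            if not getattr(self, name) > 0:
                raise SchemaError(f"{name} must be strictly positive, got {getattr(self, name)!r}")
        for name in ("n_axial", "n_beams", "n_frames"):
            if int(getattr(self, name)) < 0:
                raise SchemaError(f"{name} must be non-negative, got {getattr(self, name)!r}")

    @property
    def nyquist(self) -> float:
        """Nyquist frequency in Hz."""
        return self.sample_rate / 2.0

    @property
    def axial_spacing_mm(self) -> float:
        """Axial distance per sample in mm, using two-way pulse-echo travel."""
        return (self.sound_speed * 10.0) / (2.0 * self.sample_rate)

    @property
    def axial_spacing_cm(self) -> float:
        return self.sound_speed / (2.0 * self.sample_rate)

    def to_sidecar(self, path: str | Path) -> None:
        lines = [f"{k}={v}" for k, v in asdict(self).items()]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_sidecar(cls, path: str | Path) -> "AcquisitionMeta":
        record: dict[str, str] = {}
        for raw in Path(path).read_text().splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise SchemaError(f"malformed sidecar line: {line!r}")
            key, value = line.split("=", 1)
            record[key.strip()] = value.strip()
        missing = [f for f in _META_FIELDS if f not in record]
        if missing:
            raise SchemaError(f"sidecar {path} missing fields: {missing}")
        kwargs: dict[str, float | int] = {}
        for f in _META_FIELDS:
            try:
                kwargs[f] = int(record[f]) if f.startswith("n_") else float(record[f])
            except ValueError as exc:
                raise SchemaError(f"sidecar field {f}={record[f]!r} is not numeric") from exc
        return cls(**kwargs)


@dataclass
class RFFrameStack:
    """A 3-D raw-RF sample array ``[axial, beam, frame]`` with its metadata."""

    samples: np.ndarray
    meta: AcquisitionMeta

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float32)
        if self.samples.ndim != 3:
            raise InvalidSignalError(f"expected 3-D samples, got ndim={self.samples.ndim}")
        expected = (self.meta.n_axial, self.meta.n_beams, self.meta.n_frames)
        if self.samples.shape != expected:
            raise SchemaError(
                f"sample array shape {self.samples.shape} does not match metadata {expected}"
            )
        if not np.all(np.isfinite(self.samples)):
            raise InvalidSignalError("RF stack contains non-finite samples")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.samples.shape

    def frame(self, index: int = 0) -> np.ndarray:
        """Return one 2-D RF frame ``[axial, beam]``."""
        return self.samples[:, :, index]


@dataclass
class EnvelopeImage:
    """Non-negative envelope (analytic-signal magnitude) of one RF frame."""

    values: np.ndarray
    meta: AcquisitionMeta | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise InvalidSignalError("envelope must be 2-D [axial, beam]")
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise InvalidSignalError("envelope values must be finite and non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class ROIRect:
    """0-based, half-open rectangular ROI: rows ``row0:row0+height`` etc."""

    row0: int
    col0: int
    height: int
    width: int

    def __post_init__(self) -> None:
        if self.row0 < 0 or self.col0 < 0:
            raise BoundsError("ROI origin must be non-negative")
        if self.height < 1 or self.width < 1:
            raise BoundsError("ROI height and width must be >= 1")

    def check_within(self, n_rows: int, n_cols: int) -> None:
        if self.row0 + self.height > n_rows or self.col0 + self.width > n_cols:
            raise BoundsError(
                f"ROI {self} exceeds image of shape ({n_rows}, {n_cols})"
            )

    @property
    def rows(self) -> slice:
        return slice(self.row0, self.row0 + self.height)

    @property
    def cols(self) -> slice:
        return slice(self.col0, self.col0 + self.width)


def write_rf_stack(stack: RFFrameStack, path: str | Path, meta_path: str | Path) -> None:
    """Write a stack as flat little-endian float32, axial-fastest, plus sidecar."""
    data = np.ascontiguousarray(stack.samples, dtype="<f4")
    data.ravel(order="F").tofile(str(path))
    stack.meta.to_sidecar(meta_path)


def read_rf_stack(path: str | Path, meta_path: str | Path) -> RFFrameStack:
    """Read a flat binary RF stack and its sidecar metadata.

    Raises
    ------
    MalformedFileError
        If the file length does not equal ``n_axial*n_beams*n_frames`` samples.
    SchemaError
        If the sidecar is missing required fields.
    """
    meta = AcquisitionMeta.from_sidecar(meta_path)
    raw = np.fromfile(str(path), dtype="<f4")
    expected = meta.n_axial * meta.n_beams * meta.n_frames
    if raw.size != expected:
        raise MalformedFileError(
            f"{path}: found {raw.size} samples, metadata implies {expected}"
        )
    samples = raw.reshape((meta.n_axial, meta.n_beams, meta.n_frames), order="F")
    return RFFrameStack(samples=samples, meta=meta)


def hilbert_envelope(frame: np.ndarray, meta: AcquisitionMeta | None = None) -> EnvelopeImage:
    """Envelope of a 2-D RF frame: |analytic signal| per beam along the axial axis.

    Edge samples carry the usual transform edge artifacts; no padding is
    applied, and analyses downstream are expected to exclude the edges.
    """
    frame = np.asarray(frame, dtype=np.float64)
    if frame.ndim != 2:
        raise InvalidSignalError("hilbert_envelope expects a 2-D [axial, beam] frame")
    if not np.all(np.isfinite(frame)):
        raise InvalidSignalError("RF frame contains non-finite samples")
    if frame.shape[0] < 8:
        raise InvalidSignalError("each beam must have at least 8 axial samples")
    env = np.abs(hilbert(frame, axis=0))
    return EnvelopeImage(values=env, meta=meta)


def log_compress(env: EnvelopeImage | np.ndarray, dynamic_range: float = 40.0) -> np.ndarray:
    """Log-compress an envelope to a [0, 1] B-mode display image.

    ``20*log10(env/max(env))`` is clipped to ``[-dynamic_range, 0]`` dB and
    rescaled linearly so 0 dB maps to 1 and the clip floor to 0.
    """
    if dynamic_range <= 0:
        raise ValueError("dynamic_range must be > 0")
    values = env.values if isinstance(env, EnvelopeImage) else np.asarray(env, dtype=np.float64)
    peak = values.max()
    if peak <= 0:
        raise DegenerateImageError("all-zero envelope cannot be log-compressed")
    with np.errstate(divide="ignore"):
        db = 20.0 * np.log10(values / peak)
    db = np.clip(db, -dynamic_range, 0.0)
    return (db + dynamic_range) / dynamic_range


def mm_to_pixels(mm: float, meta: AcquisitionMeta) -> tuple[int, int]:
    """Convert a physical length to (axial samples, beams), each forced >= 1."""
    if mm <= 0:
        raise ValueError("mm must be > 0")
    axial = max(1, int(np.round(mm / meta.axial_spacing_mm)))
    beams = max(1, int(np.round(mm / meta.beam_pitch)))
    return axial, beams


def extract_roi(obj, roi: ROIRect):
    """Extract a half-open rectangular ROI from an image, frame or stack.

    Accepts 2-D arrays, 3-D stacks (all frames retained), ``EnvelopeImage``
    and ``RFFrameStack``; returns the same kind of object/array.
    """
    if isinstance(obj, RFFrameStack):
        roi.check_within(obj.meta.n_axial, obj.meta.n_beams)
        sub = obj.samples[roi.rows, roi.cols, :]
        meta = AcquisitionMeta(
            sample_rate=obj.meta.sample_rate,
            center_frequency=obj.meta.center_frequency,
            sound_speed=obj.meta.sound_speed,
            beam_pitch=obj.meta.beam_pitch,
            frame_rate=obj.meta.frame_rate,
            n_axial=roi.height,
            n_beams=roi.width,
            n_frames=obj.meta.n_frames,
        )
        return RFFrameStack(samples=sub.copy(), meta=meta)
    if isinstance(obj, EnvelopeImage):
        roi.check_within(*obj.values.shape)
        return EnvelopeImage(values=obj.values[roi.rows, roi.cols].copy(), meta=obj.meta)
    arr = np.asarray(obj)
    if arr.ndim not in (2, 3):
        raise InvalidSignalError("extract_roi expects a 2-D or 3-D array")
    roi.check_within(arr.shape[0], arr.shape[1])
    return arr[roi.rows, roi.cols, ...].copy()


def save_bmode_png(env: EnvelopeImage | np.ndarray, path: str | Path, dynamic_range: float = 40.0) -> None:
    """Export a log-compressed B-mode image as 8-bit grayscale PNG."""
    img = log_compress(env, dynamic_range)
    Image.fromarray((img * 255.0 + 0.5).astype(np.uint8), mode="L").save(str(path))


_ROI_COLUMNS = ["case_id", "row0", "col0", "height", "width", "label"]


def write_roi_table(rows: pd.DataFrame, path: str | Path) -> None:
    """Write an ROI list CSV with columns case_id,row0,col0,height,width,label."""
    missing = [c for c in _ROI_COLUMNS if c not in rows.columns]
    if missing:
        raise SchemaError(f"ROI table missing columns: {missing}")
    rows[_ROI_COLUMNS].to_csv(path, index=False)


def read_roi_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in _ROI_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"ROI table missing columns: {missing}")
    return table
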