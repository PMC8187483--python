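"""Thermal-video I/O, face masking and time-by-pixel vectorization.

A recording is a stack of temperature frames (°C) sampled at a nominal
5 Hz.  Before blind source separation the face is isolated with a binary
mask and the masked video is flattened into a ``SourceMatrix`` whose rows
are time points and whose columns are single-pixel time series.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage
from skimage import measure

__all__ = [
    "ThermalVideo",
    "FaceMask",
    "SourceMatrix",
    "read_thermal_stack",
    "write_thermal_stack",
    "build_face_mask",
    "vectorize",
    "unflatten",
]


class FormatError(ValueError):
    """Raised when on-disk frames are inconsistent or unreadable."""


class InsufficientDataError(ValueError):
    """Raised when a recording is too short to analyse."""


class EmptyMaskError(ValueError):
    """Raised when masking retains no pixels."""


@dataclass
class ThermalVideo:
    """Time-ordered stack of temperature frames.

    Parameters
    ----------
    frames : ndarray, shape (T, H, W)
        Temperatures in °C.
    rate : float
        Sampling rate in frames/s (nominally 5).
    start_time : float
        Acquisition start in seconds.
    """

    frames: np.ndarray
    rate: float = 5.0
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise FormatError(f"frames must be T×H×W, got shape {self.frames.shape}")
        if self.frames.shape[0] < 2:
            raise InsufficientDataError("a thermal video needs at least 2 frames")
        if self.frames.shape[1] < 16 or self.frames.shape[2] < 16:
            raise FormatError("frames must be at least 16×16 pixels")
        if not np.all(np.isfinite(self.frames)):
            raise FormatError("frames contain non-finite temperatures")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape

    @property
    def times(self) -> np.ndarray:
        """Frame timestamps in seconds."""
        return self.start_time + np.arange(self.n_frames) / self.rate

    @property
    def duration(self) -> float:
        return self.n_frames / self.rate


@dataclass
class FaceMask:
    """Binary face mask matching the video's frame geometry."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")
        if not self.mask.any():
            raise EmptyMaskError("mask retains no pixels")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


@dataclass
class SourceMatrix:
    """Masked video flattened to a T×P matrix.

    Each row is one frame restricted to the mask; each column is the
    time series of a single pixel.  ``pixel_index`` maps columns back to
    (row, col) image coordinates in row-major scan order.
    """

    data: np.ndarray
    pixel_index: np.ndarray  # (P, 2) int array of (row, col)
    image_shape: tuple[int, int] = field(default=(0, 0))
    rate: float = 5.0

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_pixels(self) -> int:
        return self.data.shape[1]


# ---------------------------------------------------------------------------
# reading / writing


def read_thermal_stack(
    path: str | Path,
    format: str | None = None,
    rate: float = 5.0,
    start_time: float = 0.0,
) -> ThermalVideo:
    """Read a thermal video from disk.

    Supported layouts: a multi-page TIFF of float frames (``tiff``), a
    directory of per-frame CSV matrices ordered by the number embedded
    in each file name (``csv_dir``), or a ``.npy``/``.npz`` array
    container (``array_container``).  A JSON sidecar ``<path>.json``
    with ``rate``/``start_time`` overrides the arguments when present.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        if path.is_dir():
            format = "csv_dir"
        elif path.suffix.lower() in {".tif", ".tiff"}:
            format = "tiff"
        else:
            format = "array_container"

    if format == "tiff":
        frames = tifffile.imread(path)
        if frames.ndim == 2:
            frames = frames[None]
    elif format == "csv_dir":
        files = sorted(
            (f for f in path.iterdir() if f.suffix.lower() == ".csv"),
            key=_numeric_key,
        )
        if not files:
            raise FormatError(f"no CSV frames in {path}")
        mats = [np.loadtxt(f, delimiter=",", ndmin=2) for f in files]
        shapes = {m.shape for m in mats}
        if len(shapes) > 1:
            raise FormatError(f"mixed frame sizes {sorted(shapes)} in {path}")
        frames = np.stack(mats)
    elif format == "array_container":
        arr = np.load(path)
        frames = arr["frames"] if hasattr(arr, "files") else arr
    else:
        raise ValueError(f"unknown format {format!r}")

    sidecar = path.with_name(path.name + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        rate = float(meta.get("rate", rate))
        start_time = float(meta.get("start_time", start_time))

    if frames.shape[0] < 2:
        raise InsufficientDataError(f"{path} holds fewer than 2 frames")
    return ThermalVideo(np.asarray(frames, dtype=float), rate=rate, start_time=start_time)


def write_thermal_stack(video: ThermalVideo, path: str | Path) -> Path:
    """Write a video as a float32 multi-page TIFF plus a JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, video.frames.astype(np.float32),
                     photometric="minisblack")
    sidecar = path.with_name(path.name + ".json")
    sidecar.write_text(
        json.dumps({"rate": video.rate, "start_time": video.start_time})
    )
    return path


def _numeric_key(f: Path):
    m = re.findall(r"\d+", f.stem)
    return (int(m[-1]) if m else -1, f.name)


# ---------------------------------------------------------------------------
# masking


def build_face_mask(
    reference_frame: np.ndarray,
    method: str = "threshold",
    threshold: float | None = None,
    polygon: np.ndarray | None = None,
) -> FaceMask:
    """Build a face mask from a reference frame.

    ``threshold`` keeps pixels at or above a temperature, then retains
    the largest 4-connected component and fills its holes — skin is
    warmer than background, and the face is the dominant warm object.
    ``polygon`` rasterizes a manually drawn outline (vertices as
    (row, col) pairs) for recordings where thresholding fails.
    """
    frame = np.asarray(reference_frame, dtype=float)
    if not np.all(np.isfinite(frame)):
        raise ValueError("reference frame contains non-finite values")

    if method == "threshold":
        if threshold is None:
            raise ValueError("threshold method requires a temperature threshold")
        fg = frame >= threshold
        if not fg.any():
            raise EmptyMaskError(f"no pixels at or above {threshold} °C")
        labels = measure.label(fg, connectivity=1)
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        mask = labels == counts.argmax()
        mask = ndimage.binary_fill_holes(mask)
    elif method == "polygon":
        if polygon is None:
            raise ValueError("polygon method requires vertices")
        from skimage.draw import polygon2mask

        mask = polygon2mask(frame.shape, np.asarray(polygon, dtype=float))
        if not mask.any():
            raise EmptyMaskError("polygon encloses no pixels")
    else:
        raise ValueError(f"unknown mask method {method!r}")
    return FaceMask(mask)


# ---------------------------------------------------------------------------
# vectorization


def vectorize(video: ThermalVideo, mask: FaceMask) -> SourceMatrix:
    """Flatten the masked video into a T×P source matrix.

    Columns follow a row-major scan of the mask, so
    ``data[t, j] == frames[t][tuple(pixel_index[j])]``.
    """
    if mask.shape != video.frames.shape[1:]:
        raise ValueError(
            f"mask shape {mask.shape} does not match frames {video.frames.shape[1:]}"
        )
    idx = np.argwhere(mask.mask)  # row-major order
    data = video.frames[:, idx[:, 0], idx[:, 1]]
    return SourceMatrix(
        data=data, pixel_index=idx, image_shape=mask.shape, rate=video.rate
    )


def unflatten(
    matrix: SourceMatrix, values: np.ndarray | None = None, fill: float = np.nan
) -> np.ndarray:
    """Map source-matrix rows (or any K×P array) back onto the image grid.

    Returns a (K, H, W) array with ``fill`` outside the mask.
    """
    vals = matrix.data if values is None else np.atleast_2d(np.asarray(values))
    if vals.shape[1] != matrix.n_pixels:
        raise ValueError("value rows must have one entry per masked pixel")
    out = np.full((vals.shape[0],) + tuple(matrix.image_shape), fill, dtype=float)
    out[:, matrix.pixel_index[:, 0], matrix.pixel_index[:, 1]] = vals
    return out
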