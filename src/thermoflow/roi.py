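"""Fixed-geometry circular-ROI signal extraction.

The traditional benchmark against which the ICA decomposition is
validated: a 9-pixel-radius disk (~250 pixels) placed on the nose tip
of the motion-corrected video, averaged per frame and rescaled to
[0, 1].  The same disk size is used for every subject irrespective of
face morphology.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import FaceMask, ThermalVideo
from .sica import normalize_unit_interval

__all__ = ["CircularROI", "disk_pixels", "extract_roi_signal"]


@dataclass
class CircularROI:
    """Rasterized disk: pixels whose centre lies within ``radius`` of
    ``center`` (Euclidean, pixel-centre distance)."""

    center: tuple[int, int]
    radius: float
    pixels: np.ndarray  # (n, 2) int (row, col)

    @property
    def n_pixels(self) -> int:
        return self.pixels.shape[0]


def disk_pixels(
    center: tuple[int, int], radius: float, image_dims: tuple[int, int]
) -> CircularROI:
    """Enumerate the lattice pixels of a disk, clipped to the image.

    The membership rule is centre-to-centre distance ≤ radius, which
    gives 253 pixels at radius 9.  Pixels falling outside the image are
    dropped with a warning.
    """
    if radius < 0:
        raise ValueError("radius must be non-negative")
    r0, c0 = center
    H, W = image_dims
    if not (0 <= r0 < H and 0 <= c0 < W):
        raise ValueError(f"center {center} outside image of shape {image_dims}")
    rad = int(np.ceil(radius))
    rr, cc = np.meshgrid(
        np.arange(r0 - rad, r0 + rad + 1),
        np.arange(c0 - rad, c0 + rad + 1),
        indexing="ij",
    )
    inside = (rr - r0) ** 2 + (cc - c0) ** 2 <= radius**2
    pix = np.column_stack([rr[inside], cc[inside]])
    in_img = (pix[:, 0] >= 0) & (pix[:, 0] < H) & (pix[:, 1] >= 0) & (pix[:, 1] < W)
    if not in_img.all():
        warnings.warn(
            f"{int((~in_img).sum())} ROI pixels clipped at the image edge",
            RuntimeWarning,
        )
    return CircularROI(center=(int(r0), int(c0)), radius=float(radius),
                       pixels=pix[in_img])


def extract_roi_signal(
    video: ThermalVideo,
    roi: CircularROI,
    mask: FaceMask | None = None,
    normalize: bool = True,
) -> np.ndarray:
    """Per-frame mean temperature over the ROI, rescaled to [0, 1].

    The video is expected to be motion-corrected with the same pipeline
    used before ICA, so a static disk tracks the same anatomy in every
    frame.  If a face mask is given, ROI pixels outside it trigger a
    warning (the disk itself is not trimmed).
    """
    H, W = video.frames.shape[1:]
    if (roi.pixels[:, 0] >= H).any() or (roi.pixels[:, 1] >= W).any():
        raise ValueError("ROI extends outside the video frames")
    if mask is not None:
        outside = ~mask.mask[roi.pixels[:, 0], roi.pixels[:, 1]]
        if outside.any():
            warnings.warn(
                f"{int(outside.sum())} of {roi.n_pixels} ROI pixels lie outside "
                "the face mask",
                RuntimeWarning,
            )
    series = video.frames[:, roi.pixels[:, 0], roi.pixels[:, 1]].mean(axis=1)
    return normalize_unit_interval(series) if normalize else series
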