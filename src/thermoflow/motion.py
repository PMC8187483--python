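"""Dense optical-flow motion correction for thermal video.

Head and face motion is removed by non-linearly warping each frame back
onto a reference.  A dense per-pixel displacement field is estimated
under brightness constancy, smoothed with a Gaussian to suppress
discontinuities at the face boundary, composed with the running field,
and the original frame re-warped — iterating until the incremental
displacement of every pixel drops below a threshold (1 px by default).

The flow core is pluggable; the default is scikit-image's iterative
Lucas–Kanade estimator.  The iterate/smooth/compose scheme and its
convergence rule are the contract: correcting a motion-free video is a
near-identity, and known rigid shifts of a few pixels are recovered to
sub-pixel accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.registration import optical_flow_ilk

from .io import ThermalVideo

__all__ = [
    "DisplacementField",
    "RegistrationReport",
    "estimate_flow",
    "smooth_field",
    "warp",
    "compose_fields",
    "correct_pair",
    "motion_correct",
]


@dataclass
class DisplacementField:
    """Per-pixel displacement: ``v`` rows, ``u`` columns (pixels).

    Sampling the moving image at ``(r + v, c + u)`` approximates the
    reference image.
    """

    u: np.ndarray
    v: np.ndarray

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.u.shape != self.v.shape:
            raise ValueError("u and v must share a shape")

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.u, self.v)

    @classmethod
    def zero(cls, shape: tuple[int, int]) -> "DisplacementField":
        return cls(np.zeros(shape), np.zeros(shape))


@dataclass
class RegistrationReport:
    """Per-frame convergence diagnostics of ``motion_correct``."""

    iterations: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    final_residual: np.ndarray = field(default_factory=lambda: np.empty(0))
    converged: np.ndarray = field(default_factory=lambda: np.empty(0, bool))
    convergence_threshold: float = 1.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": np.arange(len(self.iterations)),
                "iterations": self.iterations,
                "final_residual": self.final_residual,
                "converged": self.converged,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _pyramid_flow(ref: np.ndarray, mov: np.ndarray, levels: int = 3,
                  radius: int = 7, num_warp: int = 3) -> np.ndarray:
    """Coarse-to-fine iterative Lucas–Kanade.

    Single-scale LK only captures displacements up to roughly its window
    radius; estimating at a downscaled level, upscaling the field and
    refining on the pre-warped image extends the range to several times
    that.
    """
    from skimage.transform import pyramid_reduce, resize

    pyr_ref, pyr_mov = [ref], [mov]
    for _ in range(levels - 1):
        if min(pyr_ref[-1].shape) < 32:
            break
        pyr_ref.append(pyramid_reduce(pyr_ref[-1], downscale=2))
        pyr_mov.append(pyramid_reduce(pyr_mov[-1], downscale=2))

    flow = np.zeros((2,) + pyr_ref[-1].shape)
    for lvl in range(len(pyr_ref) - 1, -1, -1):
        r, m = pyr_ref[lvl], pyr_mov[lvl]
        if flow.shape[1:] != r.shape:
            scale_r = r.shape[0] / flow.shape[1]
            scale_c = r.shape[1] / flow.shape[2]
            flow = np.stack([
                resize(flow[0], r.shape, order=1) * scale_r,
                resize(flow[1], r.shape, order=1) * scale_c,
            ])
        rr, cc = np.meshgrid(np.arange(r.shape[0]), np.arange(r.shape[1]),
                             indexing="ij")
        m_warp = ndimage.map_coordinates(m, [rr + flow[0], cc + flow[1]],
                                         order=1, mode="nearest")
        inc = optical_flow_ilk(r, m_warp, radius=radius, num_warp=num_warp)
        # compose: total(x) = inc(x) + prev(x + inc(x))
        f0 = ndimage.map_coordinates(flow[0], [rr + inc[0], cc + inc[1]],
                                     order=1, mode="nearest")
        f1 = ndimage.map_coordinates(flow[1], [rr + inc[0], cc + inc[1]],
                                     order=1, mode="nearest")
        flow = np.stack([f0 + inc[0], f1 + inc[1]])
    return flow


def estimate_flow(
    reference: np.ndarray,
    moving: np.ndarray,
    flow_func: Callable | None = None,
    **flow_params,
) -> DisplacementField:
    """Estimate the dense displacement field mapping ``moving`` onto ``reference``.

    Frame means are removed first, so a pure offset (a sensor-gain or
    baseline-temperature change with no motion) yields a near-zero field.
    The default estimator is scikit-image's iterative Lucas–Kanade with
    a wide integration window (radius 15), which resolves the smooth
    large-scale gradients of thermal faces; pass ``flow_func`` for any
    drop-in dense estimator with the scikit-image flow convention
    (:func:`_pyramid_flow` offers a coarse-to-fine variant for very
    large displacements).
    """
    reference = np.asarray(reference, dtype=float)
    moving = np.asarray(moving, dtype=float)
    if reference.shape != moving.shape:
        raise ValueError("reference and moving frames must share a shape")
    ref0 = reference - reference.mean()
    mov0 = moving - moving.mean()
    if np.array_equal(ref0, mov0):
        return DisplacementField.zero(reference.shape)
    if flow_func is None:
        flow_func = optical_flow_ilk
        flow_params.setdefault("radius", 15)
        # the correction loop re-warps between estimates, so the
        # estimator's internal warping is redundant
        flow_params.setdefault("num_warp", 1)
    flow = flow_func(ref0, mov0, **flow_params)
    return DisplacementField(u=flow[1], v=flow[0])


def smooth_field(fld: DisplacementField, sigma: float) -> DisplacementField:
    """Gaussian-smooth both displacement components (reflected borders)."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return DisplacementField(fld.u.copy(), fld.v.copy())
    return DisplacementField(
        ndimage.gaussian_filter(fld.u, sigma, mode="reflect"),
        ndimage.gaussian_filter(fld.v, sigma, mode="reflect"),
    )


def warp(frame: np.ndarray, fld: DisplacementField, order: int = 1) -> np.ndarray:
    """Warp a frame by a displacement field (bilinear, edge-clamped)."""
    frame = np.asarray(frame, dtype=float)
    rr, cc = np.meshgrid(
        np.arange(frame.shape[0]), np.arange(frame.shape[1]), indexing="ij"
    )
    return ndimage.map_coordinates(
        frame, [rr + fld.v, cc + fld.u], order=order, mode="nearest"
    )


def compose_fields(
    accumulated: DisplacementField, increment: DisplacementField
) -> DisplacementField:
    """Compose so one warp by the result equals warping by ``accumulated``
    then by ``increment``.

    The combined sampling position is ``x + inc(x) + acc(x + inc(x))``,
    so the accumulated field is resampled at the incremented coordinates.
    """
    rr, cc = np.meshgrid(
        np.arange(accumulated.u.shape[0]),
        np.arange(accumulated.u.shape[1]),
        indexing="ij",
    )
    au = ndimage.map_coordinates(
        accumulated.u, [rr + increment.v, cc + increment.u], order=1, mode="nearest"
    )
    av = ndimage.map_coordinates(
        accumulated.v, [rr + increment.v, cc + increment.u], order=1, mode="nearest"
    )
    return DisplacementField(u=au + increment.u, v=av + increment.v)


def _register(
    reference: np.ndarray,
    moving: np.ndarray,
    sigma: float,
    convergence_threshold: float,
    max_iter: int,
    flow_func: Callable | None,
    **flow_params,
) -> tuple[np.ndarray, DisplacementField, int, float]:
    acc = DisplacementField.zero(reference.shape)
    warped = moving
    iterations = 0
    residual = float("inf")
    mismatch = float(np.abs(moving - reference).mean())
    for iterations in range(1, max_iter + 1):
        inc = estimate_flow(reference, warped, flow_func=flow_func, **flow_params)
        inc = smooth_field(inc, sigma)
        acc_new = compose_fields(acc, inc)
        warped_new = warp(moving, acc_new)
        residual = float(inc.magnitude.max())
        new_mismatch = float(np.abs(warped_new - reference).mean())
        if residual < convergence_threshold:
            acc, warped = acc_new, warped_new
            break
        if new_mismatch >= mismatch:
            # the remaining image difference is brightness change, not
            # motion: composing further would accumulate spurious flow
            break
        acc, warped, mismatch = acc_new, warped_new, new_mismatch
    return warped, acc, iterations, residual


def correct_pair(
    reference: np.ndarray,
    moving: np.ndarray,
    sigma: float = 5.0,
    convergence_threshold: float = 1.0,
    max_iter: int = 20,
    flow_func: Callable | None = None,
    **flow_params,
) -> tuple[np.ndarray, DisplacementField, int]:
    """Iteratively register ``moving`` onto ``reference``.

    Each pass estimates flow from the current warped frame to the
    reference, Gaussian-smooths it, composes it with the accumulated
    field and re-warps the *original* moving frame — so interpolation
    error does not accumulate.  Iteration stops once the incremental
    displacement of all pixels is below ``convergence_threshold``
    (default 1 px) or ``max_iter`` is reached.

    Returns ``(warped, accumulated_field, iterations)``.
    """
    reference = np.asarray(reference, dtype=float)
    moving = np.asarray(moving, dtype=float)
    if reference.shape != moving.shape:
        raise ValueError("reference and moving frames must share a shape")
    warped, acc, iterations, _ = _register(
        reference, moving, sigma, convergence_threshold, max_iter, flow_func,
        **flow_params,
    )
    return warped, acc, iterations


def motion_correct(
    video: ThermalVideo,
    sigma: float = 5.0,
    convergence_threshold: float = 1.0,
    reference: str = "first",
    max_iter: int = 20,
    flow_func: Callable | None = None,
    return_fields: bool = False,
    **flow_params,
) -> tuple[ThermalVideo, RegistrationReport] | tuple[
    ThermalVideo, RegistrationReport, list[DisplacementField]
]:
    """Motion-correct a whole video.

    ``reference`` chooses the target frame: ``first`` (default)
    registers every frame to frame 0, ``mean`` to the temporal mean,
    ``previous`` to the previously corrected frame (sequential, fields
    compose back to frame 0 implicitly through the corrected chain).
    """
    if reference not in {"first", "mean", "previous"}:
        raise ValueError(f"unknown reference scheme {reference!r}")

    frames = video.frames
    T = frames.shape[0]
    out = np.empty_like(frames)
    iters = np.zeros(T, int)
    resid = np.zeros(T)
    fields: list[DisplacementField] = []

    ref_frame = {
        "first": frames[0],
        "mean": frames.mean(axis=0),
        "previous": frames[0],
    }[reference]

    for t in range(T):
        if t == 0 and reference in {"first", "previous"}:
            out[0] = frames[0]
            fields.append(DisplacementField.zero(frames[0].shape))
            iters[0] = 0
            continue
        warped, acc, n, res = _register(
            ref_frame,
            np.asarray(frames[t], dtype=float),
            sigma,
            convergence_threshold,
            max_iter,
            flow_func,
            **flow_params,
        )
        out[t] = warped
        iters[t] = n
        resid[t] = res
        fields.append(acc)
        if reference == "previous":
            ref_frame = out[t]

    report = RegistrationReport(
        iterations=iters,
        final_residual=resid,
        converged=resid < convergence_threshold,
        convergence_threshold=convergence_threshold,
    )
    corrected = ThermalVideo(out, rate=video.rate, start_time=video.start_time)
    if return_fields:
        return corrected, report, fields
    return corrected, report
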