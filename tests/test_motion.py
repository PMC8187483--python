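"""Optical-flow estimation and the iterate/smooth/compose correction loop."""

import numpy as np
import pytest
from scipy import ndimage

from thermoflow import (
    DisplacementField,
    ThermalVideo,
    correct_pair,
    estimate_flow,
    motion_correct,
    simulate_thermal_video,
    smooth_field,
    warp,
)


def _shifted(frame, d):
    rr, cc = np.meshgrid(np.arange(frame.shape[0]), np.arange(frame.shape[1]),
                         indexing="ij")
    return ndimage.map_coordinates(frame, [rr - d[0], cc - d[1]], order=1,
                                   mode="nearest")


@pytest.fixture(scope="module")
def face_frame(scene):
    return scene.baseline


@pytest.fixture(scope="module")
def inner_face(scene):
    return ndimage.binary_erosion(scene.face_mask, iterations=4)


def test_identity_flow_is_zero(face_frame):
    f = estimate_flow(face_frame, face_frame)
    assert np.abs(f.u).max() < 0.1
    assert np.abs(f.v).max() < 0.1


def test_known_shift_recovered(face_frame, inner_face):
    mov = _shifted(face_frame, (0, 3))
    f = estimate_flow(face_frame, mov)
    assert abs(np.median(f.u[inner_face]) - 3.0) < 0.5
    assert abs(np.median(f.v[inner_face])) < 0.5


def test_additive_offset_gives_no_motion(face_frame, inner_face):
    f = estimate_flow(face_frame, face_frame + 1.0)
    assert np.abs(f.magnitude[inner_face]).max() < 0.2


def test_flow_shape_mismatch():
    with pytest.raises(ValueError):
        estimate_flow(np.zeros((16, 16)), np.zeros((16, 17)))


def test_smooth_field_sigma_zero_is_identity(rng):
    f = DisplacementField(rng.normal(size=(20, 20)), rng.normal(size=(20, 20)))
    g = smooth_field(f, 0.0)
    assert np.array_equal(g.u, f.u) and np.array_equal(g.v, f.v)


def test_smooth_field_constant_invariant():
    f = DisplacementField(np.full((20, 20), 2.5), np.full((20, 20), -1.5))
    g = smooth_field(f, 3.0)
    assert np.allclose(g.u, 2.5) and np.allclose(g.v, -1.5)


def test_smooth_field_spike_matches_convolution_oracle():
    u = np.zeros((41, 41))
    u[20, 20] = 10.0
    g = smooth_field(DisplacementField(u, np.zeros_like(u)), sigma=2.0)
    oracle = ndimage.gaussian_filter(u, 2.0, mode="reflect")
    assert np.allclose(g.u, oracle)
    # peak attenuated to the kernel centre weight times the spike
    assert g.u[20, 20] == pytest.approx(oracle[20, 20])
    assert g.u[20, 20] < 10.0 / (2 * np.pi * 4) * 1.05


def test_smooth_field_negative_sigma():
    f = DisplacementField.zero((8, 8))
    with pytest.raises(ValueError):
        smooth_field(f, -1.0)


def test_correct_pair_identity(face_frame):
    warped, acc, n = correct_pair(face_frame, face_frame.copy())
    assert n == 1
    assert np.abs(acc.magnitude).max() == 0.0
    assert np.array_equal(warped, face_frame)


def test_correct_pair_recovers_shift(face_frame, inner_face):
    mov = _shifted(face_frame, (3, 2))
    err_before = np.abs(mov - face_frame)[inner_face].mean()
    warped, acc, n = correct_pair(face_frame, mov, sigma=5)
    err_after = np.abs(warped - face_frame)[inner_face].mean()
    assert err_after < 0.1 * err_before


def test_correct_pair_warp_composition(face_frame):
    """Warping the original by the accumulated field reproduces the
    iteratively warped output exactly (the loop re-warps from scratch)."""
    mov = _shifted(face_frame, (2, -3))
    warped, acc, _ = correct_pair(face_frame, mov, sigma=5)
    assert np.allclose(warp(mov, acc), warped)


@pytest.mark.parametrize("shift", [(3, 0), (0, 4), (3, 4), (-2, 5)])
def test_rigid_shift_field_accuracy(face_frame, inner_face, shift):
    """Accumulated field matches the true rigid shift within 0.5 px RMS."""
    mov = _shifted(face_frame, shift)
    _, acc, _ = correct_pair(face_frame, mov, sigma=5)
    rms = np.sqrt(np.mean(
        (acc.v[inner_face] - shift[0]) ** 2 + (acc.u[inner_face] - shift[1]) ** 2
    ))
    assert rms < 0.5


def test_motion_correct_static_video_is_identity(scene):
    frames = np.repeat(scene.baseline[None], 8, axis=0)
    video = ThermalVideo(frames)
    corrected, report = motion_correct(video, sigma=5)
    assert np.abs(corrected.frames - frames).max() < 0.01
    assert report.converged.all()


def test_motion_correct_tracks_centroid(scene):
    """Residual frame-to-frame motion of a tracked warm blob < 0.5 px."""
    video, truth = simulate_thermal_video(
        scene=scene, T=80, seed=21, motion_amplitude=4.0, noise_sigma=0.0,
        source_amp=0.0,  # static face: centroid motion is pure registration
    )
    corrected, report = motion_correct(video, sigma=5)

    def face_centroids(frames):
        # soft-thresholded intensity centroid tracks the warm face
        return np.asarray([
            ndimage.center_of_mass(np.clip(f - 28.0, 0.0, None)) for f in frames
        ])

    cents = face_centroids(corrected.frames)
    assert np.abs(np.diff(cents, axis=0)).max() < 0.5
    assert np.ptp(cents, axis=0).max() < 1.0  # total excursion also small
    # the raw video's face wanders by construction
    assert np.ptp(face_centroids(video.frames), axis=0).max() > 2.0


def test_convergence_report_consistency(scene):
    video, _ = simulate_thermal_video(
        scene=scene, T=64, seed=22, motion_amplitude=3.0
    )
    _, report = motion_correct(video, sigma=5, convergence_threshold=1.0)
    assert np.array_equal(report.converged, report.final_residual < 1.0)
    assert (report.iterations <= 20).all()
    assert np.isfinite(report.final_residual).all()


def test_incremental_displacement_shrinks(scene, inner_face):
    """The incremental displacement decreases over iterations on a rigid
    shift (monotone over the final steps up to estimator noise)."""
    from thermoflow.motion import compose_fields

    ref = scene.baseline
    mov = _shifted(ref, (4, 3))
    acc = DisplacementField.zero(ref.shape)
    warped = mov
    incs = []
    for _ in range(5):
        inc = smooth_field(estimate_flow(ref, warped), 5.0)
        acc = compose_fields(acc, inc)
        warped = warp(mov, acc)
        incs.append(inc.magnitude.max())
    assert incs[-1] < 1.0
    assert incs[-1] <= incs[0]
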