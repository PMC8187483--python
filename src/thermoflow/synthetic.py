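"""Synthetic face-like thermal video and coupled physiological signals.

Real facial-thermography recordings are privacy-restricted, so every
pipeline stage is exercised on generated data with known ground truth.
The generative model is exactly the one spatial ICA assumes: a static
baseline face plus a small number of spatial sources (nose, bilateral
cheeks, a nostril respiration plume) with independent-ish time courses,
rigidly (plus mildly elastically) moved frame to frame, and degraded
with Gaussian sensor noise at the thermal camera's noise floor
(NEDT ≈ 0.05 °C).

Group simulations share one latent "arousal" process across subjects:
nasal temperature loads on it negatively (vasoconstriction), skin
conductance positively through a slow recovery kernel, and the
inter-beat interval through an LF-band modulation — so inter-subject
correlation, cross-modal tests and the HRV pipeline all have known
expected outcomes.  The shared-variance parameterization makes the
expected pairwise ISC of the nose series equal the parameter itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal as sps

from .io import FaceMask, ThermalVideo
from .physio import PhysioSeries

__all__ = [
    "FaceScene",
    "SyntheticGroundTruth",
    "GroupDataset",
    "make_face_scene",
    "simulate_thermal_video",
    "simulate_subject_group",
    "simulate_ecg_like",
]

#: Thermal-camera noise floor in °C (typical uncooled microbolometer NEDT).
DEFAULT_NOISE_SIGMA = 0.05


@dataclass
class FaceScene:
    """Parametric face: elliptical mask, anatomical templates, baseline map."""

    face_mask: np.ndarray
    templates: dict[str, np.ndarray]
    baseline: np.ndarray
    shape: tuple[int, int]

    def template_vectors(self, mask: np.ndarray | None = None) -> dict[str, np.ndarray]:
        """Templates flattened over a mask's row-major pixel order."""
        m = self.face_mask if mask is None else mask
        idx = np.argwhere(m)
        return {
            name: tmpl[idx[:, 0], idx[:, 1]] for name, tmpl in self.templates.items()
        }


@dataclass
class SyntheticGroundTruth:
    """Everything needed to score recovery of the planted model."""

    spatial_maps: np.ndarray  # K0×H×W
    timecourses: np.ndarray  # T×K0
    source_names: list[str]
    motion_trajectory: np.ndarray  # T×2 rigid (row, col) shifts
    noise_sigma: float
    seed: int
    rate: float
    latent: np.ndarray | None = None
    respiration_freq: float | None = None


@dataclass
class GroupDataset:
    """Per-subject multimodal recordings sharing one latent process."""

    nose_series: np.ndarray  # N×T at `rate`
    gsr: list[PhysioSeries]
    beat_times: list[np.ndarray]
    emotion_scores: np.ndarray  # N×(duration s) at 1 Hz
    latent: np.ndarray
    videos: list[ThermalVideo] = field(default_factory=list)
    scene: FaceScene | None = None
    ground_truths: list[SyntheticGroundTruth] = field(default_factory=list)
    rate: float = 5.0
    shared_variance_fraction: float = 0.0
    gsr_coupling: float = 0.0
    seed: int = 0


# ---------------------------------------------------------------------------
# scene construction


def _ellipse(shape, center, axes) -> np.ndarray:
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    return ((rr - center[0]) / axes[0]) ** 2 + ((cc - center[1]) / axes[1]) ** 2 <= 1.0


def make_face_scene(
    shape: tuple[int, int] = (96, 96),
    seed: int = 0,
    face_temp: float = 33.0,
    background_temp: float = 22.0,
    texture_amp: float = 1.0,
) -> FaceScene:
    """Build the parametric face used by all video simulations.

    The baseline adds a smooth seeded texture inside the face so dense
    optical flow has gradients to lock onto (real faces have structured
    temperature, e.g. warmer periorbital and cooler nose regions).  At
    the default 96×96 geometry the nose tip spans ~17 px, so the
    standard 9-px-radius benchmark ROI is nose-tip-sized and clear of
    the nostril airflow region — the same proportions a 640×480 camera
    sees at conversational distance.
    """
    H, W = shape
    cy, cx = H // 2, W // 2
    face = _ellipse(shape, (cy, cx), (0.42 * H, 0.32 * W))
    nose = _ellipse(shape, (cy + int(0.07 * H), cx), (0.09 * H, 0.065 * W))
    nostril = _ellipse(shape, (cy + int(0.21 * H), cx), (0.035 * H, 0.055 * W))
    lcheek = _ellipse(shape, (cy + int(0.06 * H), cx - int(0.19 * W)),
                      (0.09 * H, 0.07 * W))
    rcheek = _ellipse(shape, (cy + int(0.06 * H), cx + int(0.19 * W)),
                      (0.09 * H, 0.07 * W))
    forehead = _ellipse(shape, (cy - int(0.25 * H), cx), (0.08 * H, 0.18 * W))
    for t in (nose, nostril, lcheek, rcheek, forehead):
        t &= face
    nose &= ~nostril
    cheeks = (lcheek | rcheek) & ~nose & ~nostril
    forehead &= ~nose & ~nostril & ~cheeks

    rng = np.random.default_rng(seed)
    texture = ndimage.gaussian_filter(rng.standard_normal(shape), 4.0)
    texture = texture / np.abs(texture).max() * texture_amp
    baseline = np.where(face, face_temp + texture, background_temp)
    return FaceScene(
        face_mask=face,
        templates={
            "nose": nose,
            "cheeks": cheeks,
            "forehead": forehead,
            "nostril": nostril,
        },
        baseline=baseline,
        shape=shape,
    )


# ---------------------------------------------------------------------------
# time-course generators


def _lowpass_drift(T: int, rate: float, cutoff: float, rng) -> np.ndarray:
    """Unit-variance random walk low-passed below ``cutoff`` Hz."""
    x = np.cumsum(rng.standard_normal(T))
    sos = sps.butter(4, cutoff, btype="low", fs=rate, output="sos")
    x = sps.sosfiltfilt(sos, x)
    x -= x.mean()
    return x / x.std()


def _smooth_noise(T: int, rate: float, cutoff: float, rng) -> np.ndarray:
    """Unit-variance band-limited Gaussian noise (shares the latent's
    spectral character so mixtures have interpretable variance shares)."""
    x = rng.standard_normal(T)
    sos = sps.butter(4, cutoff, btype="low", fs=rate, output="sos")
    x = sps.sosfiltfilt(sos, x)
    x -= x.mean()
    return x / x.std()


# ---------------------------------------------------------------------------
# single-subject video


def simulate_thermal_video(
    scene: FaceScene | None = None,
    T: int = 600,
    rate: float = 5.0,
    motion_amplitude: float = 0.0,
    noise_sigma: float = DEFAULT_NOISE_SIGMA,
    seed: int = 0,
    nose_timecourse: np.ndarray | None = None,
    source_amp: float = 0.5,
    elastic_amp: float = 0.15,
) -> tuple[ThermalVideo, SyntheticGroundTruth]:
    """Simulate one subject's thermal video with planted sources.

    Sources: a slow nasal drift (< 0.05 Hz, vasomotor), a nostril
    respiration oscillation with a per-subject frequency drawn from the
    normal respiratory range 0.16–0.35 Hz, and a cheek drift carrying a
    scaled copy of the respiration waveform (cheek and respiration
    components overlap spectrally in real data).  ``source_amp`` scales
    the sources in °C; with the default 0.5 °C and the 0.05 °C noise
    floor the per-pixel SNR is 10.  ``motion_amplitude`` drives a slow
    sinusoidal rigid translation plus a mild elastic wobble.
    """
    if T < 64:
        raise ValueError("T must be at least 64 frames")
    if motion_amplitude < 0 or noise_sigma < 0:
        raise ValueError("motion amplitude and noise sigma must be non-negative")
    if scene is None:
        scene = make_face_scene(seed=seed)
    rng = np.random.default_rng(seed)
    H, W = scene.shape
    t = np.arange(T) / rate

    nose_tc = (
        np.asarray(nose_timecourse, dtype=float)
        if nose_timecourse is not None
        else _lowpass_drift(T, rate, 0.05, rng)
    )
    if nose_tc.size != T:
        raise ValueError("nose_timecourse length must equal T")
    resp_freq = float(rng.uniform(0.16, 0.35))
    resp_tc = np.sin(2 * np.pi * resp_freq * t + rng.uniform(0, 2 * np.pi))
    resp_tc = (resp_tc - resp_tc.mean()) / resp_tc.std()
    cheek_tc = 0.8 * _lowpass_drift(T, rate, 0.05, rng) + 0.4 * resp_tc
    cheek_tc = (cheek_tc - cheek_tc.mean()) / cheek_tc.std()

    # smooth-edged spatial maps (°C per unit time course)
    def soft(tmpl):
        m = ndimage.gaussian_filter(tmpl.astype(float), 1.0)
        return m / m.max()

    maps = np.stack(
        [
            soft(scene.templates["nose"]),
            soft(scene.templates["cheeks"]),
            soft(scene.templates["nostril"]),
        ]
    )
    tcs = np.column_stack([nose_tc, cheek_tc, resp_tc]) * source_amp
    amp_resp = 0.6  # respiration plume is a bit weaker than vasomotor drifts
    tcs[:, 2] *= amp_resp

    clean = scene.baseline[None] + np.einsum("tk,khw->thw", tcs, maps)

    # rigid sinusoidal translation + slow elastic wobble; zero phase so the
    # displacement is zero at t=0 (ground-truth maps live in the first-frame
    # pose) and bounded by motion_amplitude throughout
    f1, f2 = rng.uniform(0.02, 0.06), rng.uniform(0.02, 0.06)
    traj = np.column_stack(
        [
            motion_amplitude * np.sin(2 * np.pi * f1 * t),
            motion_amplitude * np.sin(2 * np.pi * f2 * t),
        ]
    )
    frames = np.empty((T, H, W))
    if motion_amplitude > 0:
        rr, cc = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
        ebase_r = ndimage.gaussian_filter(rng.standard_normal((H, W)), 8.0)
        ebase_c = ndimage.gaussian_filter(rng.standard_normal((H, W)), 8.0)
        ebase_r /= np.abs(ebase_r).max()
        ebase_c /= np.abs(ebase_c).max()
        ewave = np.sin(2 * np.pi * rng.uniform(0.02, 0.06) * t)
        for i in range(T):
            dr = traj[i, 0] + elastic_amp * motion_amplitude * ewave[i] * ebase_r
            dc = traj[i, 1] + elastic_amp * motion_amplitude * ewave[i] * ebase_c
            # frame(x) = clean(x - d): the face moves by +d
            frames[i] = ndimage.map_coordinates(
                clean[i], [rr - dr, cc - dc], order=1, mode="nearest"
            )
    else:
        frames[:] = clean
    if noise_sigma > 0:
        frames = frames + rng.normal(0.0, noise_sigma, size=frames.shape)

    video = ThermalVideo(frames, rate=rate)
    truth = SyntheticGroundTruth(
        spatial_maps=maps,
        timecourses=tcs,
        source_names=["nose", "cheek", "respiration"],
        motion_trajectory=traj,
        noise_sigma=noise_sigma,
        seed=seed,
        rate=rate,
        respiration_freq=resp_freq,
    )
    return video, truth


# ---------------------------------------------------------------------------
# subject group


def simulate_subject_group(
    n_subjects: int = 17,
    T: int = 6000,
    rate: float = 5.0,
    shared_variance_fraction: float = 0.25,
    gsr_coupling: float = -1.0,
    seed: int = 0,
    with_videos: bool = False,
    with_physio: bool = True,
    video_kwargs: dict | None = None,
    gsr_rate: float = 50.0,
    latent_cutoff: float = 0.04,
) -> GroupDataset:
    """Simulate a group of subjects viewing one stimulus.

    One latent arousal process L (unit variance, band-limited below
    ``latent_cutoff`` Hz) is shared by all subjects.  Each subject's
    nose-temperature series is ``−√f·L + √(1−f)·ε_i`` with matched-
    spectrum idiosyncratic noise, so the expected pairwise ISC equals
    ``f`` and the nose–arousal correlation is negative
    (vasoconstriction).  GSR follows ``sign(−gsr_coupling)·L`` convolved
    with a slow recovery kernel plus noise — with the default negative
    ``gsr_coupling`` the nose-vs-GSR group correlation is negative, as
    autonomic physiology predicts.  The IBI is modulated in the LF band
    by L; emotion scores are a noisy 1 Hz read-out of L.

    GSR is generated at ``gsr_rate`` (upsample externally if a 2 kHz
    fixture is required); beat times come from integrate-and-fire on the
    latent-modulated instantaneous IBI.  ``with_physio=False`` generates
    nose series only (for ISC simulation studies); ``with_videos=True``
    additionally renders each subject's thermal video with the subject's
    nose series planted as the nose-source time course.
    """
    if n_subjects < 2:
        raise ValueError("at least 2 subjects are required")
    if not 0.0 <= shared_variance_fraction <= 1.0:
        raise ValueError("shared_variance_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    f = shared_variance_fraction
    latent = _lowpass_drift(T, rate, latent_cutoff, rng)
    duration = T / rate

    nose = np.empty((n_subjects, T))
    gsr_list: list[PhysioSeries] = []
    beats: list[np.ndarray] = []
    emotions = np.empty((n_subjects, int(duration)))
    videos: list[ThermalVideo] = []
    truths: list[SyntheticGroundTruth] = []
    scene = make_face_scene(seed=seed) if with_videos else None

    # slow skin-conductance recovery kernel (~4 s rise, ~10 s decay)
    tg = np.arange(0, 30 * gsr_rate) / gsr_rate
    kernel = (1 - np.exp(-tg / 2.0)) * np.exp(-tg / 10.0)
    kernel /= kernel.sum()

    t_lat = np.arange(T) / rate
    for i in range(n_subjects):
        eps = _smooth_noise(T, rate, latent_cutoff, rng)
        nose[i] = -np.sqrt(f) * latent + np.sqrt(1 - f) * eps

        if with_physio:
            # GSR at gsr_rate: latent resampled, convolved with recovery kernel
            n_gsr = int(duration * gsr_rate)
            lat_hi = np.interp(np.arange(n_gsr) / gsr_rate, t_lat, latent)
            drive = np.sign(-gsr_coupling) * lat_hi * abs(gsr_coupling)
            g = np.convolve(drive, kernel, mode="same")
            g = g + 0.3 * _smooth_noise(n_gsr, gsr_rate, 0.1, rng)
            gsr_list.append(PhysioSeries(g, rate=gsr_rate, kind="gsr_raw"))

            # IBI modulated in the LF band by the latent plus HF respiration
            resp_f = rng.uniform(0.2, 0.3)
            lf_mod = np.interp(
                np.arange(int(duration * 4)) / 4.0, t_lat, latent
            )  # 4 Hz modulation grid
            t4 = np.arange(lf_mod.size) / 4.0
            ibi_inst = (
                1000.0
                + 40.0 * lf_mod
                + 25.0 * np.sin(2 * np.pi * resp_f * t4 + rng.uniform(0, 2 * np.pi))
                + 10.0 * _smooth_noise(lf_mod.size, 4.0, 0.5, rng)
            )
            ibi_inst = np.clip(ibi_inst, 450.0, 1450.0)
            beats.append(_integrate_and_fire(ibi_inst, 4.0, duration))

            em = np.interp(np.arange(int(duration)), t_lat, latent)
            emotions[i] = 0.7 * em + 0.3 * rng.standard_normal(em.size)
        else:
            emotions[i] = 0.0

        if with_videos:
            vkw = dict(video_kwargs or {})
            video, truth = simulate_thermal_video(
                scene=scene,
                T=T,
                rate=rate,
                seed=int(rng.integers(0, 2**31 - 1)),
                nose_timecourse=nose[i],
                **vkw,
            )
            truth.latent = latent
            videos.append(video)
            truths.append(truth)

    return GroupDataset(
        nose_series=nose,
        gsr=gsr_list,
        beat_times=beats,
        emotion_scores=emotions,
        latent=latent,
        videos=videos,
        scene=scene,
        ground_truths=truths,
        rate=rate,
        shared_variance_fraction=f,
        gsr_coupling=gsr_coupling,
        seed=seed,
    )


def _integrate_and_fire(
    ibi_inst_ms: np.ndarray, grid_rate: float, duration: float, t_start: float = 0.25
) -> np.ndarray:
    """Beat times from an instantaneous-IBI series (integrate-and-fire).

    The train starts slightly after t = 0 and ends slightly before the
    recording does, so every R wave lies fully inside the record.
    """
    times = [t_start]
    t = t_start
    tmax = duration - 0.1
    n = ibi_inst_ms.size
    while True:
        idx = min(int(t * grid_rate), n - 1)
        t = t + ibi_inst_ms[idx] / 1000.0
        if t > tmax:
            break
        times.append(t)
    return np.asarray(times)


# ---------------------------------------------------------------------------
# ECG


def simulate_ecg_like(
    beat_modulation: np.ndarray | None = None,
    duration: float = 300.0,
    rate: float = 2000.0,
    seed: int = 0,
    mean_ibi_ms: float = 1000.0,
    modulation_rate: float = 4.0,
    noise_amp: float = 0.02,
    drift_amp: float = 0.0,
) -> tuple[PhysioSeries, np.ndarray]:
    """Pulse-train ECG surrogate with known beat times.

    ``beat_modulation`` is an additive instantaneous-IBI modulation in
    ms sampled at ``modulation_rate``; beats are generated by
    integrate-and-fire and each carries a Gaussian R wave (σ ≈ 10 ms).
    Returns the signal and the ground-truth beat times.
    """
    rng = np.random.default_rng(seed)
    n_mod = int(duration * modulation_rate)
    mod = np.zeros(n_mod) if beat_modulation is None else np.asarray(
        beat_modulation, dtype=float
    )
    if mod.size != n_mod:
        raise ValueError(
            f"beat_modulation must have duration*modulation_rate={n_mod} samples"
        )
    ibi_inst = mean_ibi_ms + mod
    if np.any(ibi_inst < 400.0) or np.any(ibi_inst > 1500.0):
        raise ValueError("instantaneous IBI must stay within [400, 1500] ms")
    beat_times = _integrate_and_fire(ibi_inst, modulation_rate, duration)

    n = int(duration * rate)
    t = np.arange(n) / rate
    x = np.zeros(n)
    sig = 0.010  # R-wave width (s)
    for bt in beat_times:
        lo = max(0, int((bt - 5 * sig) * rate))
        hi = min(n, int((bt + 5 * sig) * rate))
        x[lo:hi] += np.exp(-0.5 * ((t[lo:hi] - bt) / sig) ** 2)
    if drift_amp:
        x *= 1.0 + drift_amp * np.sin(2 * np.pi * t / duration)
    x += noise_amp * rng.standard_normal(n)
    return PhysioSeries(x, rate=rate, kind="other"), beat_times


def face_mask_from_scene(scene: FaceScene) -> FaceMask:
    """The scene's true face mask as a FaceMask object."""
    return FaceMask(scene.face_mask.copy())
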