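"""Peripheral physiology: GSR preprocessing, R-peak detection, IBI and
autoregressive time-frequency heart-rate variability.

GSR (skin conductance, 2 kHz) is detrended, low-pass filtered at 5 Hz,
resampled and rescaled to [0, 1].  ECG R peaks (detected here with a
derivative-energy detector, or supplied externally from manual
correction tools) yield the inter-beat-interval (IBI) series, which is
cubic-spline resampled at 2 Hz and decomposed into a sliding-window
autoregressive spectrogram.  Band powers are integrated over the LF
(0.04–0.14 Hz, mixed sympathetic/parasympathetic) and HF (0.15–0.4 Hz,
parasympathetic/respiratory) bands; windows overlapping the first and
last ~8 s are edge-flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import interpolate, signal as sps
from statsmodels.regression.linear_model import burg

from .sica import normalize_unit_interval

__all__ = [
    "PhysioSeries",
    "IBISeries",
    "HRVSpectrogram",
    "preprocess_gsr",
    "detect_r_peaks",
    "read_peak_file",
    "compute_ibi",
    "hrv_spectrogram",
    "LF_BAND",
    "HF_BAND",
]

#: Low-frequency HRV band (Hz).
LF_BAND = (0.04, 0.14)
#: High-frequency HRV band (Hz).
HF_BAND = (0.15, 0.4)


class PeakDetectionError(RuntimeError):
    """Raised when no plausible R peaks are found."""


@dataclass
class PhysioSeries:
    """Uniformly sampled physiological signal."""

    values: np.ndarray
    rate: float
    kind: str = "other"
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be 1-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contain non-finite samples")
        if self.rate <= 0:
            raise ValueError("rate must be positive")

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.values.size) / self.rate

    @property
    def duration(self) -> float:
        return self.values.size / self.rate

    @classmethod
    def from_csv(cls, path, rate: float | None = None, kind: str = "other"):
        """Read a (time, value) CSV; rate inferred from time stamps if omitted."""
        df = pd.read_csv(path)
        t = df.iloc[:, 0].to_numpy(dtype=float)
        v = df.iloc[:, 1].to_numpy(dtype=float)
        if rate is None:
            rate = 1.0 / np.median(np.diff(t))
        return cls(v, rate=float(rate), kind=kind, start_time=float(t[0]))


@dataclass
class IBISeries:
    """R-peak times (s) and successive inter-beat intervals (ms)."""

    beat_times: np.ndarray

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        if self.beat_times.size < 3:
            raise ValueError("at least 3 beats are required")
        if not np.all(np.diff(self.beat_times) > 0):
            raise ValueError("beat times must be strictly increasing")

    @property
    def intervals(self) -> np.ndarray:
        """IBI in milliseconds, one per beat pair."""
        return np.diff(self.beat_times) * 1000.0

    @property
    def interval_times(self) -> np.ndarray:
        """Each interval stamped at its second beat (causal convention)."""
        return self.beat_times[1:]

    @property
    def normalized(self) -> np.ndarray:
        return normalize_unit_interval(self.intervals)


@dataclass
class HRVSpectrogram:
    """LF/HF band-power time courses (ms²) from a sliding AR spectrum."""

    times: np.ndarray
    lf_power: np.ndarray
    hf_power: np.ndarray
    edge_flags: np.ndarray
    params: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.times,
                "lf": self.lf_power,
                "hf": self.hf_power,
                "edge": self.edge_flags,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# GSR


def preprocess_gsr(
    raw: PhysioSeries, cutoff: float = 5.0, target_rate: float = 5.0
) -> PhysioSeries:
    """Detrend, low-pass at ``cutoff``, resample and rescale to [0, 1].

    Linear detrending removes slow electrode drift; the zero-phase
    4th-order Butterworth low-pass at 5 Hz strips mains and movement
    noise while preserving the slow sympathetic dynamics; resampling to
    the thermal frame rate makes cross-modal correlation direct.
    """
    if raw.rate <= 2 * cutoff:
        raise ValueError(f"sampling rate {raw.rate} Hz too low for a {cutoff} Hz cutoff")
    x = sps.detrend(raw.values, type="linear")
    sos = sps.butter(4, cutoff, btype="low", fs=raw.rate, output="sos")
    x = sps.sosfiltfilt(sos, x)
    if target_rate != raw.rate:
        from fractions import Fraction

        frac = Fraction(target_rate / raw.rate).limit_denominator(10000)
        x = sps.resample_poly(x, frac.numerator, frac.denominator)
    return PhysioSeries(
        normalize_unit_interval(x),
        rate=target_rate,
        kind="gsr_processed",
        start_time=raw.start_time,
    )


# ---------------------------------------------------------------------------
# ECG / IBI


def detect_r_peaks(
    ecg: PhysioSeries, refractory_s: float = 0.2, threshold_frac: float = 0.4
) -> np.ndarray:
    """Detect R-peak times with a derivative-energy detector.

    The signal is band-passed (5–30 Hz), differentiated, squared and
    smoothed over 120 ms; peaks above ``threshold_frac`` of the 98th
    percentile of the energy envelope, separated by at least the
    refractory period, are refined to the local ECG maximum.  For
    recordings corrected by hand in external tools, supply the peak
    times directly via :func:`read_peak_file` instead.
    """
    if ecg.rate < 100:
        raise ValueError("ECG sampling rate must be at least 100 Hz")
    x = ecg.values - ecg.values.mean()
    if np.allclose(x, 0):
        raise PeakDetectionError("flat ECG signal; no R peaks found")
    sos = sps.butter(2, [5.0, min(30.0, 0.45 * ecg.rate)], btype="band",
                     fs=ecg.rate, output="sos")
    xf = sps.sosfiltfilt(sos, x)
    energy = np.gradient(xf) ** 2
    win = max(3, int(round(0.12 * ecg.rate)))
    env = np.convolve(energy, np.ones(win) / win, mode="same")
    height = threshold_frac * np.percentile(env, 98)
    if height <= 0:
        raise PeakDetectionError("no energy above threshold; no R peaks found")
    locs, _ = sps.find_peaks(env, height=height,
                             distance=int(round(refractory_s * ecg.rate)))
    if locs.size == 0:
        raise PeakDetectionError("no R peaks found")
    # refine each detection to the nearby raw-ECG maximum
    half = int(round(0.05 * ecg.rate))
    refined = []
    for loc in locs:
        lo, hi = max(0, loc - half), min(x.size, loc + half + 1)
        refined.append(lo + int(np.argmax(x[lo:hi])))
    refined = np.unique(refined)
    return ecg.start_time + refined / ecg.rate


def read_peak_file(path) -> np.ndarray:
    """Read externally supplied beat times (one time in seconds per line)."""
    times = np.loadtxt(path, ndmin=1)
    if not np.all(np.diff(times) > 0):
        raise ValueError("peak file times must be strictly increasing")
    return times


def compute_ibi(beat_times: np.ndarray) -> tuple[IBISeries, np.ndarray]:
    """IBI series from beat times plus a [0, 1]-normalized copy."""
    ibi = IBISeries(beat_times)
    return ibi, ibi.normalized


# ---------------------------------------------------------------------------
# AR spectrogram


def _ar_psd(x: np.ndarray, order: int, nfft: int, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided AR (Burg) power spectral density on an nfft grid."""
    x = x - x.mean()
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    if x.var() < np.finfo(float).tiny * 1e6:
        return freqs, np.zeros_like(freqs)  # flat window has no spectrum
    rho, sigma2 = burg(x, order=order, demean=False)
    # x_t = sum rho_k x_{t-k} + e  =>  A(f) = 1 - sum rho_k e^{-2πifk/fs}
    _, h = sps.freqz([1.0], np.concatenate([[1.0], -rho]), worN=freqs, fs=fs)
    psd = 2.0 * sigma2 * np.abs(h) ** 2 / fs
    return freqs, psd


def hrv_spectrogram(
    ibi: IBISeries,
    ar_order: int = 16,
    window_s: float = 16.0,
    overlap_samples: int = 15,
    nfft: int = 1024,
    interp_rate: float = 2.0,
    lf_band: tuple[float, float] = LF_BAND,
    hf_band: tuple[float, float] = HF_BAND,
) -> HRVSpectrogram:
    """Sliding-window autoregressive LF/HF band-power time courses.

    The IBI series (stamped at each interval's second beat) is cubic-
    spline resampled at ``interp_rate``; 16 s windows (32 samples at
    2 Hz) advance by ``window − overlap`` samples; each window's Burg AR
    spectrum is integrated over the LF and HF bands.  Windows touching
    the first or last half-window (~8 s) are edge-flagged.
    """
    nwin = int(round(window_s * interp_rate))
    if ar_order >= nwin:
        raise ValueError(f"AR order {ar_order} must be below window size {nwin}")
    if not 0 <= overlap_samples < nwin:
        raise ValueError("overlap must be shorter than the window")
    t = ibi.interval_times
    y = ibi.intervals
    if t[-1] - t[0] < 2 * window_s:
        raise ValueError("recording must span at least two windows")
    spline = interpolate.CubicSpline(t, y)
    tt = np.arange(t[0], t[-1], 1.0 / interp_rate)
    yy = spline(tt)

    hop = nwin - overlap_samples
    starts = np.arange(0, yy.size - nwin + 1, hop)
    centers = tt[starts] + window_s / 2.0
    lf = np.empty(starts.size)
    hf = np.empty(starts.size)
    for i, s in enumerate(starts):
        freqs, psd = _ar_psd(yy[s:s + nwin], ar_order, nfft, interp_rate)
        df = freqs[1] - freqs[0]
        lf[i] = np.trapezoid(psd[(freqs >= lf_band[0]) & (freqs <= lf_band[1])], dx=df)
        hf[i] = np.trapezoid(psd[(freqs >= hf_band[0]) & (freqs <= hf_band[1])], dx=df)
    half = window_s / 2.0
    edge = (tt[starts] < tt[0] + half) | (tt[starts] + window_s > tt[-1] - half)
    return HRVSpectrogram(
        times=centers,
        lf_power=lf,
        hf_power=hf,
        edge_flags=edge,
        params={
            "ar_order": ar_order,
            "window_s": window_s,
            "overlap_samples": overlap_samples,
            "nfft": nfft,
            "interp_rate": interp_rate,
            "lf_band": lf_band,
            "hf_band": hf_band,
        },
    )
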