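"""Inter-subject correlation and circular-shift permutation statistics.

Shared responses to a common naturalistic stimulus are quantified as
the mean pairwise Pearson correlation between subjects (ISC).  Because
physiological signals are strongly autocorrelated, significance is
assessed against surrogate data built by circularly shifting each
series by a random offset: rotation preserves a signal's own
autocorrelation exactly while destroying its alignment with the other
subjects (or the other modality).  P-values use the add-one estimator
(1 + #extreme)/(1 + n_permutations), which is never zero and is valid
for exchangeable nulls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ISCResult",
    "PermutationTestResult",
    "circular_shift",
    "pairwise_isc",
    "isc_permutation_test",
    "group_xmodal_test",
    "lagged_correlation",
    "fdr_correct",
    "align_modalities",
]


@dataclass
class ISCResult:
    """Pairwise correlation structure of a group of aligned series."""

    corr_matrix: np.ndarray
    mean_r: float
    n_pairs: int
    null_samples: np.ndarray | None = None
    p_value: float | None = None
    n_permutations: int = 0
    seed: int | None = None


@dataclass
class PermutationTestResult:
    """Observed group statistic against a circular-shift null."""

    observed: float
    p_value: float
    null_samples: np.ndarray = field(default_factory=lambda: np.empty(0))
    n_permutations: int = 0
    tail: str = "pos"
    seed: int | None = None
    per_subject_r: np.ndarray | None = None


def circular_shift(series: np.ndarray, shift: int) -> np.ndarray:
    """Rotate a series by ``shift`` samples (wraparound).

    ``circular_shift(x, 1)[0] == x[-1]``; the value multiset, mean,
    variance and circular autocorrelation are all preserved exactly.
    """
    x = np.asarray(series)
    if x.size < 2:
        raise ValueError("series must have at least 2 samples")
    return np.roll(x, shift)


def _standardize_rows(X: np.ndarray) -> np.ndarray:
    Z = X - X.mean(axis=1, keepdims=True)
    sd = Z.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(f"series {bad.tolist()} are constant; correlation undefined")
    return Z / sd[:, None]


def _windowed(X: np.ndarray, window: tuple[int, int] | None) -> np.ndarray:
    if window is None:
        return X
    lo, hi = window
    return X[:, lo:hi]


def pairwise_isc(
    signals: np.ndarray, window: tuple[int, int] | None = None
) -> ISCResult:
    """Inter-subject correlation of N aligned series.

    Returns the full N×N Pearson matrix and the mean over the N(N−1)/2
    unique pairs.  ``window`` restricts the analysis to a sample range
    (e.g. the second half of a stimulus).
    """
    X = np.atleast_2d(np.asarray(signals, dtype=float))
    X = _windowed(X, window)
    N, T = X.shape
    if N < 2:
        raise ValueError("at least 2 subjects are required")
    if T < 10:
        raise ValueError("series must have at least 10 samples")
    Z = _standardize_rows(X)
    corr = Z @ Z.T / T
    np.fill_diagonal(corr, 1.0)
    iu = np.tril_indices(N, k=-1)
    mean_r = float(corr[iu].mean())
    return ISCResult(corr_matrix=corr, mean_r=mean_r, n_pairs=iu[0].size)


def _mean_pair_r_shifted(Z: np.ndarray, shifts: np.ndarray) -> np.ndarray:
    """Mean pairwise correlation for a batch of per-subject shifts.

    Z is N×T standardized; ``shifts`` is B×N.  Uses the identity
    sum_{i<j} z_i·z_j = (||Σ z_i||² − N·T)/2, so each permutation costs
    O(N·T) instead of O(N²·T).
    """
    N, T = Z.shape
    idx = (np.arange(T)[None, None, :] - shifts[:, :, None]) % T
    shifted = Z[np.arange(N)[None, :, None], idx]  # B×N×T gather
    total = shifted.sum(axis=1)  # B×T
    ss = np.einsum("bt,bt->b", total, total)
    return (ss / T - N) / (N * (N - 1))


def isc_permutation_test(
    signals: np.ndarray,
    n_permutations: int = 5000,
    seed: int | None = None,
    window: tuple[int, int] | None = None,
    batch: int | None = None,
) -> ISCResult:
    """ISC with a circular-shift permutation null (one-sided, positive).

    Each permutation rotates every subject's series by an independent
    uniform offset in [1, T−1] — preserving per-subject autocorrelation
    while disrupting between-subject alignment — and recomputes the mean
    pairwise correlation.
    """
    if n_permutations < 100:
        warnings.warn("fewer than 100 permutations; p-value is coarse", RuntimeWarning)
    res = pairwise_isc(signals, window=window)
    X = _windowed(np.atleast_2d(np.asarray(signals, dtype=float)), window)
    Z = _standardize_rows(X)
    N, T = Z.shape
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    if batch is None:
        batch = max(1, int(2e7 // (N * T)))  # bound scratch memory
    done = 0
    while done < n_permutations:
        b = min(batch, n_permutations - done)
        shifts = rng.integers(1, T, size=(b, N))
        null[done:done + b] = _mean_pair_r_shifted(Z, shifts)
        done += b
    p = (1.0 + np.sum(null >= res.mean_r)) / (1.0 + n_permutations)
    return ISCResult(
        corr_matrix=res.corr_matrix,
        mean_r=res.mean_r,
        n_pairs=res.n_pairs,
        null_samples=null,
        p_value=float(p),
        n_permutations=n_permutations,
        seed=seed,
    )


def group_xmodal_test(
    signal_pairs: list[tuple[np.ndarray, np.ndarray]],
    n_permutations: int = 5000,
    seed: int | None = None,
    tail: str = "pos",
    window: tuple[int, int] | None = None,
) -> PermutationTestResult:
    """Group-level similarity of two recordings (e.g. nose IC vs GSR).

    The observed statistic is the group mean of the per-subject Pearson
    correlation between the two modalities.  The null randomly
    circularly shifts modality ``b`` relative to ``a``, independently
    per subject and per realization, preserving autocorrelation while
    destroying cross-modal alignment.  ``tail``: ``pos``, ``neg`` or
    ``two``.
    """
    if tail not in {"pos", "neg", "two"}:
        raise ValueError(f"unknown tail {tail!r}")
    if not signal_pairs:
        raise ValueError("at least one subject pair is required")
    za, zb = [], []
    for i, (a, b) in enumerate(signal_pairs):
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if a.shape != b.shape:
            raise ValueError(f"subject {i}: modality lengths differ")
        A = _windowed(a[None, :], window)[0]
        B = _windowed(b[None, :], window)[0]
        za.append(_standardize_rows(A[None, :])[0])
        zb.append(_standardize_rows(B[None, :])[0])
    ZA = np.stack(za)
    ZB = np.stack(zb)
    N, T = ZA.shape
    per_subject = np.einsum("nt,nt->n", ZA, ZB) / T
    observed = float(per_subject.mean())

    if n_permutations < 100:
        warnings.warn("fewer than 100 permutations; p-value is coarse", RuntimeWarning)
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    done = 0
    batch = max(1, int(2e7 // (N * T)))  # bound scratch memory
    rows = np.arange(N)[None, :, None]
    base = np.arange(T)[None, None, :]
    while done < n_permutations:
        b = min(batch, n_permutations - done)
        shifts = rng.integers(1, T, size=(b, N))
        idx = (base - shifts[:, :, None]) % T
        shifted = ZB[rows, idx]  # b×N×T gather
        null[done:done + b] = np.einsum("nt,bnt->b", ZA, shifted) / (N * T)
        done += b

    if tail == "pos":
        k = np.sum(null >= observed)
    elif tail == "neg":
        k = np.sum(null <= observed)
    else:
        k = np.sum(np.abs(null) >= abs(observed))
    p = float((1.0 + k) / (1.0 + n_permutations))
    return PermutationTestResult(
        observed=observed,
        p_value=p,
        null_samples=null,
        n_permutations=n_permutations,
        tail=tail,
        seed=seed,
        per_subject_r=per_subject,
    )


def lagged_correlation(a: np.ndarray, b: np.ndarray, lag_s: float, rate: float) -> float:
    """Pearson r between ``a[t]`` and ``b[t + lag]`` on the overlap.

    Positive ``lag_s`` treats ``b`` as the delayed response to ``a``
    (e.g. thermal responses lagging movie emotion by ~3 s); the overlap
    is truncated, never wrapped.  ``lag_s`` may be negative.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("series must have equal length")
    L = int(round(lag_s * rate))
    if abs(L) >= a.size:
        raise ValueError(f"lag of {L} samples exceeds series length {a.size}")
    if L > 0:
        aa, bb = a[:-L], b[L:]
    elif L < 0:
        aa, bb = a[-L:], b[:L]
    else:
        aa, bb = a, b
    return float(np.corrcoef(aa, bb)[0, 1])


def fdr_correct(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 1:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def align_modalities(
    series: list, target_rate: float
) -> list[np.ndarray]:
    """Resample heterogenous-rate series to a common rate and support.

    Each entry is a ``PhysioSeries``-like object (``values``, ``rate``,
    ``start_time``) or a ``(values, rate)`` / ``(values, rate,
    start_time)`` tuple.  Downsampling applies a polyphase anti-alias
    filter; all outputs are cropped to the overlapping time span and
    returned equal-length.
    """
    from fractions import Fraction

    from scipy.signal import resample_poly

    parsed = []
    for s in series:
        if hasattr(s, "values") and hasattr(s, "rate"):
            parsed.append((np.asarray(s.values, float), float(s.rate),
                           float(getattr(s, "start_time", 0.0))))
        else:
            v, r, *rest = s
            parsed.append((np.asarray(v, float), float(r),
                           float(rest[0]) if rest else 0.0))
    t0 = max(p[2] for p in parsed)
    t1 = min(p[2] + p[0].size / p[1] for p in parsed)
    if t1 <= t0:
        raise ValueError("series have no overlapping time support")

    out = []
    for v, r, s0 in parsed:
        if r != target_rate:
            frac = Fraction(target_rate / r).limit_denominator(10000)
            v = resample_poly(v, frac.numerator, frac.denominator)
            r = target_rate
        i0 = int(np.ceil((t0 - s0) * r))
        i1 = int(np.floor((t1 - s0) * r))
        out.append(v[i0:i1])
    n = min(x.size for x in out)
    return [x[:n] for x in out]
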