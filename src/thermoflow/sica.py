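"""Spatial independent component analysis of masked thermal video.

The T×P source matrix (rows: frames, columns: masked-pixel time series)
is mean-centred, reduced to its top-k principal components and whitened.
A symmetric fixed-point ICA (tanh or cubic contrast) then unmixes the
retained spatial modes into K spatial maps that are maximally
statistically independent across pixels; the associated mixing-matrix
columns are the component time courses.  Components are characterized
spatially (overlap with anatomical region templates) and spectrally
(fraction of power inside the normal respiratory band, 0.16–0.35 Hz).

Sign indeterminacy is resolved by orienting each component so the
skewness of its spatial map is positive; maps have unit variance over
pixels by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy import stats as spstats

from .io import SourceMatrix

__all__ = [
    "WhiteningModel",
    "ICADecomposition",
    "ComponentProfile",
    "whiten",
    "fastica",
    "decompose",
    "normalize_unit_interval",
    "component_spectrum",
    "band_fraction",
    "profile_component",
    "match_components",
    "RESPIRATORY_BAND",
]

#: Normal respiration frequency range (Hz).
RESPIRATORY_BAND = (0.16, 0.35)


@dataclass
class WhiteningModel:
    """PCA mean/projection used to whiten the source matrix.

    ``projection`` (k×P) maps a centred frame to whitened coordinates;
    ``back_projection`` (P×k) maps whitened time courses back so that
    ``whitened @ back_projection.T`` is the rank-k approximation of the
    centred data.
    """

    mean: np.ndarray
    projection: np.ndarray
    back_projection: np.ndarray
    k: int
    explained_variance_fraction: float


@dataclass
class ICADecomposition:
    """Result of spatial ICA.

    ``timecourses`` (T×K) are mixing-matrix columns; ``spatial_maps``
    (K×P) are unit-variance source rows.  ``mean_offset`` (T,) carries
    the spatially uniform (pixel-mean) part of the retained subspace,
    so that with K = k
    ``timecourses @ spatial_maps + mean_offset[:, None]`` equals the
    whitened-subspace data ``whitened @ back_projection.T`` exactly.
    """

    timecourses: np.ndarray
    spatial_maps: np.ndarray
    mean_offset: np.ndarray
    whitening: WhiteningModel
    converged: bool
    n_iter: int
    seed: int | None = None
    unmixing: np.ndarray | None = None

    @property
    def n_components(self) -> int:
        return self.spatial_maps.shape[0]


@dataclass
class ComponentProfile:
    """Spatial/spectral characterization of one component."""

    label: str
    respiratory_band_fraction: float
    compactness: float
    region_overlap: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# whitening


def whiten(data: SourceMatrix | np.ndarray, k: int) -> tuple[np.ndarray, WhiteningModel]:
    """Centre, reduce to the top-k PCs and whiten.

    Returns the T×k whitened time courses (sample covariance = I) and
    the model needed to map components back to pixel space.  ``k`` is
    reduced with a warning when the data are rank-deficient.
    """
    X = data.data if isinstance(data, SourceMatrix) else np.asarray(data, dtype=float)
    T, P = X.shape
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > min(T, P):
        raise ValueError(f"k={k} exceeds min(T, P)={min(T, P)}")
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    tol = s[0] * max(T, P) * np.finfo(float).eps
    rank = int((s > tol).sum())
    if rank < k:
        warnings.warn(
            f"data rank {rank} < requested k={k}; reducing k", RuntimeWarning
        )
        k = rank
    scale = np.sqrt(T - 1)
    Y = scale * U[:, :k]
    projection = scale * (Vt[:k].T / s[:k]).T  # k×P
    back_projection = (Vt[:k].T * s[:k]) / scale  # P×k
    evf = float((s[:k] ** 2).sum() / (s**2).sum())
    return Y, WhiteningModel(mean, projection, back_projection, k, evf)


# ---------------------------------------------------------------------------
# fixed-point ICA


def _sym_decorrelate(W: np.ndarray) -> np.ndarray:
    # W <- (W W^T)^{-1/2} W
    s, u = np.linalg.eigh(W @ W.T)
    s = np.clip(s, 1e-12, None)
    return (u / np.sqrt(s)) @ u.T @ W


def _contrast(name: str):
    if name == "tanh":

        def g(x):
            gx = np.tanh(x)
            return gx, 1.0 - gx**2

    elif name == "pow3":

        def g(x):
            return x**3, 3.0 * x**2

    else:
        raise ValueError(f"unknown contrast {name!r}")
    return g


def fastica(
    whitened: np.ndarray,
    whitening: WhiteningModel,
    K: int | None = None,
    contrast: str = "tanh",
    seed: int | None = None,
    tol: float = 1e-4,
    max_iter: int = 1000,
) -> ICADecomposition:
    """Symmetric fixed-point spatial ICA on whitened data.

    The spatial modes ``B = back_projection.T`` (k×P) are row-centred
    over pixels and sphered; the fixed-point iteration then estimates an
    orthonormal unmixing matrix W (K×k) maximizing non-Gaussianity of
    the spatial maps ``S = W Z`` under the chosen contrast.  Convergence
    is declared when successive unmixing matrices agree to ``tol`` under
    sign alignment.  Deterministic given ``seed``.
    """
    Y = np.asarray(whitened, dtype=float)
    k = whitening.k
    if K is None:
        K = k
    if K > k:
        raise ValueError(f"K={K} exceeds whitening dimension k={k}")
    if seed is None:
        raise ValueError("a seed is required for reproducible unmixing")

    B = whitening.back_projection.T  # k×P spatial modes
    P = B.shape[1]
    row_means = B.mean(axis=1)
    Bc = B - row_means[:, None]
    C = Bc @ Bc.T / P
    sC, uC = np.linalg.eigh(C)
    sC = np.clip(sC, 1e-12, None)
    sphere = (uC / np.sqrt(sC)) @ uC.T  # k×k
    Z = sphere @ Bc  # k×P, identity pixel covariance

    g = _contrast(contrast)
    rng = np.random.default_rng(seed)
    W = _sym_decorrelate(rng.standard_normal((K, k)))

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        gx, g_prime = g(W @ Z)
        W_new = (gx @ Z.T) / P - (g_prime.mean(axis=1))[:, None] * W
        W_new = _sym_decorrelate(W_new)
        lim = float(np.max(np.abs(np.abs(np.einsum("ij,ij->i", W_new, W)) - 1.0)))
        W = W_new
        if lim < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"fixed-point ICA did not converge in {max_iter} iterations",
            RuntimeWarning,
        )

    S = W @ Z  # K×P, unit variance rows (orthonormal W on sphered data)
    # deterministic sign: positive spatial-map skewness
    signs = np.sign(spstats.skew(S, axis=1))
    signs[signs == 0] = 1.0
    S = S * signs[:, None]
    W = W * signs[:, None]

    # time courses by least squares onto the maps (S S^T = P I_K):
    # Y @ Bc is the row-centred rank-k data (T×P), so A = (Y Bc) S^T / P
    A = (Y @ Bc) @ S.T / P
    mean_offset = Y @ row_means  # uniform-map part of the retained subspace
    return ICADecomposition(
        timecourses=A,
        spatial_maps=S,
        mean_offset=mean_offset,
        whitening=whitening,
        converged=converged,
        n_iter=it,
        seed=seed,
        unmixing=W,
    )


def decompose(
    data: SourceMatrix | np.ndarray,
    n_components: int = 50,
    k: int | None = None,
    contrast: str = "tanh",
    seed: int | None = None,
    tol: float = 1e-4,
    max_iter: int = 1000,
) -> ICADecomposition:
    """Whiten then unmix in one call (k defaults to ``n_components``)."""
    if k is None:
        k = n_components
    Y, model = whiten(data, k)
    if model.k < n_components:
        n_components = model.k
    return fastica(
        Y, model, K=n_components, contrast=contrast, seed=seed, tol=tol,
        max_iter=max_iter,
    )


# ---------------------------------------------------------------------------
# component characterization


def normalize_unit_interval(series: np.ndarray) -> np.ndarray:
    """Rescale a 1-D signal to [0, 1] via (x − min)/(max − min).

    A constant input maps to all 0.5 with a warning.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("series must be 1-D with at least 2 samples")
    lo, hi = x.min(), x.max()
    if hi == lo:
        warnings.warn("constant series; returning 0.5 everywhere", RuntimeWarning)
        return np.full_like(x, 0.5)
    return (x - lo) / (hi - lo)


def component_spectrum(
    timecourse: np.ndarray, rate: float, nperseg: int = 64
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided Welch power spectral density of a component time course."""
    x = np.asarray(timecourse, dtype=float)
    if rate <= 0:
        raise ValueError("rate must be positive")
    if x.size < 32:
        raise ValueError("time course too short for spectral estimation")
    nperseg = min(nperseg, x.size)
    freqs, power = sps.welch(
        x - x.mean(), fs=rate, nperseg=nperseg, window="hann", noverlap=nperseg // 2
    )
    return freqs, power


def band_fraction(
    freqs: np.ndarray,
    power: np.ndarray,
    band: tuple[float, float] = RESPIRATORY_BAND,
    floor: float = 0.01,
) -> float:
    """Fraction of spectral power inside ``band`` relative to all power
    above ``floor`` Hz."""
    freqs = np.asarray(freqs)
    power = np.asarray(power)
    total = power[freqs > floor]
    if total.sum() <= 0:
        return 0.0
    inside = power[(freqs >= band[0]) & (freqs <= band[1])]
    return float(inside.sum() / total.sum())


def profile_component(
    spatial_map: np.ndarray,
    timecourse: np.ndarray,
    region_templates: dict[str, np.ndarray],
    rate: float,
    overlap_threshold: float = 0.5,
    band: tuple[float, float] = RESPIRATORY_BAND,
) -> ComponentProfile:
    """Label a component from its spatial concentration and spectrum.

    The top decile of |map| defines the component's support; the overlap
    score per region is the overlap of that support with the region
    template, normalized by the smaller of the two (templates are
    boolean P-vectors over masked pixels; the min-normalization keeps
    the score meaningful for anatomical regions much smaller than a
    decile of the face).  The component is labelled with the best-
    overlapping region when the overlap exceeds ``overlap_threshold``;
    a nostril/mouth-region component additionally requires a
    respiratory-band-dominated spectrum before being called
    ``respiration``.  Anything unassigned is ``other``.
    """
    m = np.abs(np.asarray(spatial_map, dtype=float))
    if not region_templates:
        raise ValueError("at least one region template is required")
    for name, tmpl in region_templates.items():
        if not np.asarray(tmpl).any():
            raise ValueError(f"region template {name!r} is empty")
    cutoff = np.quantile(m, 0.9)
    support = m >= cutoff
    n_support = int(support.sum())
    overlaps = {}
    for name, tmpl in region_templates.items():
        tmpl = np.asarray(tmpl, bool)
        denom = min(n_support, int(tmpl.sum()))
        overlaps[name] = float((support & tmpl).sum() / denom)
    freqs, power = component_spectrum(timecourse, rate)
    rbf = band_fraction(freqs, power, band=band)

    # compactness: mean pairwise support spread is costly; use the share of
    # map energy carried by the support instead (1 = perfectly concentrated)
    compactness = float((m[support] ** 2).sum() / (m**2).sum())

    best = max(overlaps, key=overlaps.get)
    label = "other"
    if overlaps[best] > overlap_threshold:
        if best in {"nostril", "mouth", "respiration"}:
            label = "respiration" if rbf > 0.5 else "other"
        else:
            label = best
    return ComponentProfile(
        label=label,
        respiratory_band_fraction=rbf,
        compactness=compactness,
        region_overlap=overlaps,
    )


def match_components(
    true_maps: np.ndarray, est_maps: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Greedy absolute-correlation matching of estimated to true maps.

    Returns ``(assignment, r)`` where ``assignment[i]`` is the estimated
    component matched to true map ``i`` and ``r[i]`` the absolute Pearson
    correlation of the matched pair.  Handles ICA's permutation and sign
    indeterminacy before any recovery score is computed.
    """
    true_maps = np.atleast_2d(true_maps)
    est_maps = np.atleast_2d(est_maps)
    nt = true_maps.shape[0]
    tz = (true_maps - true_maps.mean(1, keepdims=True))
    tz /= np.linalg.norm(tz, axis=1, keepdims=True)
    ez = (est_maps - est_maps.mean(1, keepdims=True))
    ez /= np.linalg.norm(ez, axis=1, keepdims=True)
    corr = np.abs(tz @ ez.T)  # nt × ne
    assignment = np.full(nt, -1)
    scores = np.zeros(nt)
    c = corr.copy()
    for _ in range(min(nt, est_maps.shape[0])):
        i, j = np.unravel_index(np.nanargmax(c), c.shape)
        assignment[i] = j
        scores[i] = corr[i, j]
        c[i, :] = -np.inf
        c[:, j] = -np.inf
    return assignment, scores
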