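"""Whitening, fixed-point spatial ICA, and component characterization."""

import warnings

import numpy as np
import pytest

from thermoflow import (
    band_fraction,
    component_spectrum,
    decompose,
    fastica,
    match_components,
    normalize_unit_interval,
    profile_component,
    whiten,
)


def _mixed_data(rng, T=200, P=400, K=3):
    """Noiseless linear mixture with sparse disjoint spatial sources
    (heavy-tailed on a small support, as localized thermal maps are)."""
    S = np.zeros((K, P))
    width = P // (2 * K)
    for k in range(K):
        S[k, k * width:(k + 1) * width] = rng.laplace(size=width)
    A = rng.standard_normal((T, K))
    return A @ S, A, S


def test_whiten_identity_covariance(rng):
    X = rng.standard_normal((500, 2)) @ np.array([[2.0, 0.5], [0.5, 1.0]])
    Y, model = whiten(X, k=2)
    cov = Y.T @ Y / (Y.shape[0] - 1)
    assert np.allclose(cov, np.eye(2), atol=1e-6)
    assert model.explained_variance_fraction == pytest.approx(1.0)


def test_whiten_rank_deficient_reduces_k(rng):
    x = rng.standard_normal(100)
    X = np.column_stack([x, 2 * x, -x])
    with pytest.warns(RuntimeWarning, match="reducing k"):
        Y, model = whiten(X, k=2)
    assert model.k == 1
    assert Y.shape == (100, 1)


def test_whiten_k_too_large(rng):
    with pytest.raises(ValueError):
        whiten(rng.standard_normal((10, 5)), k=6)


def test_whiten_reconstruction_error_equals_discarded_variance(rng):
    X = rng.standard_normal((120, 30)) * np.linspace(5, 0.1, 30)
    Xc = X - X.mean(axis=0)
    s = np.linalg.svd(Xc, compute_uv=False)
    k = 10
    Y, model = whiten(X, k=k)
    resid = Xc - Y @ model.back_projection.T
    assert np.linalg.norm(resid) ** 2 == pytest.approx((s[k:] ** 2).sum(), rel=1e-8)


def test_fastica_recovers_disjoint_sources(rng):
    X, A, S = _mixed_data(rng)
    Y, model = whiten(X, k=3)
    dec = fastica(Y, model, seed=0)
    _, r = match_components(S, dec.spatial_maps)
    assert r.min() > 0.99


def test_fastica_reconstructs_whitened_subspace(rng):
    X, _, _ = _mixed_data(rng)
    X = X + 0.01 * rng.standard_normal(X.shape)
    Y, model = whiten(X, k=5)
    dec = fastica(Y, model, seed=1)
    rec = dec.timecourses @ dec.spatial_maps + dec.mean_offset[:, None]
    assert np.abs(rec - Y @ model.back_projection.T).max() < 1e-6


def test_fastica_unmixing_orthonormal_on_gaussian_data(rng):
    X = rng.standard_normal((300, 60))
    Y, model = whiten(X, k=8)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # may not converge on pure noise
        dec = fastica(Y, model, seed=2, max_iter=200)
    W = dec.unmixing
    assert np.allclose(W @ W.T, np.eye(W.shape[0]), atol=1e-8)


def test_fastica_deterministic_and_seed_equivalent():
    X, _, S = _mixed_data(np.random.default_rng(55))
    Y, model = whiten(X, k=3)
    d1 = fastica(Y, model, seed=7)
    d2 = fastica(Y, model, seed=7)
    assert np.array_equal(d1.spatial_maps, d2.spatial_maps)
    assert np.array_equal(d1.timecourses, d2.timecourses)
    d3 = fastica(Y, model, seed=8)
    _, r = match_components(d1.spatial_maps, d3.spatial_maps)
    assert r.min() > 0.999  # same solution up to permutation/sign


def test_fastica_requires_seed(rng):
    X, _, _ = _mixed_data(rng)
    Y, model = whiten(X, k=3)
    with pytest.raises(ValueError, match="seed"):
        fastica(Y, model, seed=None)


def test_fastica_matches_sklearn_oracle(rng):
    """Independent cross-check: scikit-learn's FastICA on the same data
    finds the same sources (up to permutation and sign)."""
    from sklearn.decomposition import FastICA

    X, _, S = _mixed_data(rng, T=300, P=300)
    X = X + 0.001 * rng.standard_normal(X.shape)
    Y, model = whiten(X, k=3)
    dec = fastica(Y, model, seed=3)
    sk = FastICA(n_components=3, random_state=0, whiten="unit-variance")
    S_sk = sk.fit_transform(X.T).T  # sources over pixels
    _, r = match_components(S_sk, dec.spatial_maps)
    assert r.min() > 0.99


def test_spatial_maps_unit_variance(rng):
    X, _, _ = _mixed_data(rng)
    Y, model = whiten(X, k=3)
    dec = fastica(Y, model, seed=4)
    assert np.allclose(dec.spatial_maps.std(axis=1), 1.0, atol=1e-8)


def test_normalize_unit_interval():
    assert np.allclose(normalize_unit_interval([2, 4, 6]), [0, 0.5, 1])
    with pytest.warns(RuntimeWarning, match="constant"):
        out = normalize_unit_interval([3.0, 3.0, 3.0])
    assert np.allclose(out, 0.5)
    x = np.random.default_rng(0).normal(size=50)
    y = normalize_unit_interval(x)
    assert y.min() == 0.0 and y.max() == 1.0


def test_component_spectrum_localizes_sine():
    rate = 5.0
    t = np.arange(600) / rate
    f, p = component_spectrum(np.sin(2 * np.pi * 0.25 * t), rate)
    assert abs(f[np.argmax(p)] - 0.25) <= (f[1] - f[0]) / 2 + 1e-12
    assert band_fraction(f, p) > 0.8


def test_component_spectrum_white_noise_spread(rng):
    f, p = component_spectrum(rng.standard_normal(2000), 5.0)
    # no single bin dominates a flat spectrum
    assert p.max() / p.sum() < 0.1


def test_component_spectrum_too_short():
    with pytest.raises(ValueError):
        component_spectrum(np.zeros(10), 5.0)


@pytest.fixture(scope="module")
def vec_templates(scene):
    idx = np.argwhere(scene.face_mask)
    return {
        name: tmpl[idx[:, 0], idx[:, 1]]
        for name, tmpl in scene.templates.items()
    }


def test_profile_nose_component(scene, vec_templates, rng):
    m = vec_templates["nose"].astype(float) + 0.05 * rng.standard_normal(
        vec_templates["nose"].size
    )
    tc = np.cumsum(rng.standard_normal(300))
    p = profile_component(m, tc, vec_templates, rate=5.0)
    assert p.label == "nose"
    assert p.region_overlap["nose"] > 0.9


def test_profile_respiration_component(scene, vec_templates, rng):
    m = vec_templates["nostril"].astype(float) + 0.05 * rng.standard_normal(
        vec_templates["nostril"].size
    )
    t = np.arange(300) / 5.0
    tc = np.sin(2 * np.pi * 0.3 * t)
    p = profile_component(m, tc, vec_templates, rate=5.0)
    assert p.label == "respiration"
    assert p.respiratory_band_fraction > 0.5


def test_profile_diffuse_component_is_other(vec_templates, rng):
    m = rng.standard_normal(vec_templates["nose"].size)
    tc = rng.standard_normal(300)
    p = profile_component(m, tc, vec_templates, rate=5.0)
    assert p.label == "other"


def test_labeling_accuracy_over_random_draws(scene, vec_templates, rng):
    """Template-based labeling reproduces ground truth on noisy synthetic
    components in at least 95% of draws."""
    t = np.arange(300) / 5.0
    hits = 0
    n = 100
    for i in range(n):
        kind = ("nose", "cheeks", "respiration")[i % 3]
        tmpl = vec_templates["nostril" if kind == "respiration" else kind]
        m = tmpl.astype(float) + 0.1 * rng.standard_normal(tmpl.size)
        if kind == "respiration":
            tc = np.sin(2 * np.pi * rng.uniform(0.2, 0.3) * t)
        else:
            tc = np.cumsum(rng.standard_normal(t.size))
        p = profile_component(m, tc, vec_templates, rate=5.0)
        hits += p.label == kind
    assert hits / n >= 0.95


def test_empty_template_rejected(vec_templates, rng):
    bad = dict(vec_templates, empty=np.zeros_like(vec_templates["nose"]))
    with pytest.raises(ValueError, match="empty"):
        profile_component(
            rng.standard_normal(bad["nose"].size), rng.standard_normal(300),
            bad, rate=5.0,
        )


def test_decompose_source_recovery_degrades_gracefully(scene):
    """Matched spatial recovery is high at SNR 10 and monotone in SNR."""
    from thermoflow import build_face_mask, simulate_thermal_video, vectorize

    mins = []
    for snr in (2, 5, 10):
        video, truth = simulate_thermal_video(
            scene=scene, T=300, seed=31, motion_amplitude=0.0,
            source_amp=0.5, noise_sigma=0.5 / snr,
        )
        mask = build_face_mask(video.frames.mean(axis=0), threshold=28.0)
        dec = decompose(vectorize(video, mask), n_components=8, seed=0)
        idx = np.argwhere(mask.mask)
        tv = truth.spatial_maps[:, idx[:, 0], idx[:, 1]]
        _, r = match_components(tv, dec.spatial_maps)
        mins.append(r.min())
    assert mins[-1] > 0.95
    assert mins[0] <= mins[1] + 0.02 and mins[1] <= mins[2] + 0.02
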