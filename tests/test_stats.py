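"""ISC, circular-shift permutation nulls, lagged correlation and FDR."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thermoflow import (
    align_modalities,
    circular_shift,
    fdr_correct,
    group_xmodal_test,
    isc_permutation_test,
    lagged_correlation,
    pairwise_isc,
)
from tests.conftest import ar1


# ---------------------------------------------------------------------------
# circular shift


def test_circular_shift_examples():
    assert np.array_equal(circular_shift([1, 2, 3, 4], 1), [4, 1, 2, 3])
    assert np.array_equal(circular_shift([1, 2, 3, 4], 4), [1, 2, 3, 4])


@settings(deadline=None, max_examples=25)
@given(
    st.lists(st.floats(-10, 10), min_size=4, max_size=64),
    st.integers(-100, 100),
)
def test_circular_shift_preserves_moments_and_acf(values, shift):
    x = np.asarray(values)
    y = circular_shift(x, shift)
    assert sorted(x) == sorted(y)
    assert x.mean() == pytest.approx(y.mean())
    # circular autocorrelation is shift-invariant
    acf_x = np.real(np.fft.ifft(np.abs(np.fft.fft(x - x.mean())) ** 2))
    acf_y = np.real(np.fft.ifft(np.abs(np.fft.fft(y - y.mean())) ** 2))
    assert np.allclose(acf_x, acf_y, atol=1e-8)


# ---------------------------------------------------------------------------
# pairwise ISC


def test_identical_series_have_unit_isc(rng):
    x = rng.standard_normal(100)
    res = pairwise_isc(np.stack([x, x]))
    assert res.mean_r == pytest.approx(1.0)


def test_seventeen_subjects_give_136_pairs(rng):
    res = pairwise_isc(rng.standard_normal((17, 50)))
    assert res.n_pairs == 136


def test_isc_mean_matches_brute_force(rng):
    X = rng.standard_normal((6, 80))
    res = pairwise_isc(X)
    rs = [
        np.corrcoef(X[i], X[j])[0, 1]
        for i in range(6) for j in range(i + 1, 6)
    ]
    assert res.mean_r == pytest.approx(np.mean(rs), abs=1e-12)
    assert np.allclose(res.corr_matrix, res.corr_matrix.T)
    assert np.allclose(np.diag(res.corr_matrix), 1.0)


def test_constructed_correlations_average_correctly(rng):
    """Mixing a common factor with known loadings lands near the target
    mean pairwise correlation."""
    T = 20000
    z = rng.standard_normal(T)
    a = np.sqrt(0.5) * z + np.sqrt(0.5) * rng.standard_normal(T)
    b = np.sqrt(0.5) * z + np.sqrt(0.5) * rng.standard_normal(T)
    c = rng.standard_normal(T)
    res = pairwise_isc(np.stack([a, b, c]))
    # pair r values ~ (0.5, 0, 0): mean ~ 1/6
    assert res.mean_r == pytest.approx(1 / 6, abs=0.05)


def test_constant_series_named_in_error(rng):
    X = rng.standard_normal((3, 50))
    X[1] = 2.0
    with pytest.raises(ValueError, match=r"\[1\]"):
        pairwise_isc(X)


# ---------------------------------------------------------------------------
# permutation tests


def test_identical_signals_give_minimal_p(rng):
    x = ar1(rng, 200)
    res = isc_permutation_test(np.stack([x, x, x]), n_permutations=199, seed=0)
    assert res.p_value == pytest.approx(1 / 200)


def test_isc_test_deterministic_given_seed(rng):
    X = ar1(rng, 150, size=5)
    r1 = isc_permutation_test(X, n_permutations=200, seed=9)
    r2 = isc_permutation_test(X, n_permutations=200, seed=9)
    assert np.array_equal(r1.null_samples, r2.null_samples)
    assert r1.p_value == r2.p_value


def test_isc_null_matches_batched_computation(rng):
    """The vectorized null equals a brute-force per-permutation loop."""
    X = ar1(rng, 60, size=4)
    res = isc_permutation_test(X, n_permutations=150, seed=5, batch=7)
    rng2 = np.random.default_rng(5)
    null = []
    for _ in range(150):
        shifts = rng2.integers(1, 60, size=4)
        Xs = np.stack([np.roll(x, s) for x, s in zip(X, shifts)])
        null.append(pairwise_isc(Xs).mean_r)
    assert np.allclose(res.null_samples, null, atol=1e-12)


def test_isc_type_one_error_calibrated(rng):
    """Empirical rejection rate under independent AR(1) nulls stays inside
    the binomial 95% interval around 0.05."""
    runs, rej = 120, 0
    for i in range(runs):
        X = ar1(rng, 400, size=8)
        res = isc_permutation_test(X, n_permutations=200, seed=i)
        rej += res.p_value <= 0.05
    lo, hi = 0.05 - 1.96 * np.sqrt(0.05 * 0.95 / runs), \
        0.05 + 1.96 * np.sqrt(0.05 * 0.95 / runs)
    assert lo <= rej / runs <= hi


def test_xmodal_perfect_anticorrelation(rng):
    pairs = [(x, -x) for x in ar1(rng, 150, size=4)]
    res = group_xmodal_test(pairs, n_permutations=199, seed=1, tail="neg")
    assert res.observed == pytest.approx(-1.0)
    assert res.p_value == pytest.approx(1 / 200)


def test_xmodal_type_one_error_calibrated(rng):
    runs, rej = 120, 0
    for i in range(runs):
        pairs = [(ar1(rng, 400), ar1(rng, 400)) for _ in range(6)]
        res = group_xmodal_test(pairs, n_permutations=200, seed=i, tail="pos")
        rej += res.p_value <= 0.05
    lo, hi = 0.05 - 1.96 * np.sqrt(0.05 * 0.95 / runs), \
        0.05 + 1.96 * np.sqrt(0.05 * 0.95 / runs)
    assert lo <= rej / runs <= hi


def test_window_argument_restricts_analysis(rng):
    a = ar1(rng, 400)
    b = np.concatenate([a[:200], ar1(rng, 200)])
    full = group_xmodal_test([(a, b)], n_permutations=100, seed=0)
    first = group_xmodal_test([(a, b)], n_permutations=100, seed=0,
                              window=(0, 200))
    assert first.observed > full.observed


# ---------------------------------------------------------------------------
# lagged correlation / FDR / alignment


def test_lagged_correlation_exact_delay(rng):
    a = ar1(rng, 500)
    L = 15  # 3 s at 5 Hz
    b = np.concatenate([np.zeros(L), a[:-L]])  # b lags a by 3 s
    assert lagged_correlation(a, b, 3.0, 5.0) == pytest.approx(1.0, abs=1e-9)
    assert lagged_correlation(a, b, 0.0, 5.0) < 1.0


def test_lagged_correlation_null_bound(rng):
    T = 4000
    a, b = rng.standard_normal(T), rng.standard_normal(T)
    for lag in (-2.0, 0.0, 3.0):
        assert abs(lagged_correlation(a, b, lag, 5.0)) < 3 / np.sqrt(T)


def test_lagged_correlation_lag_too_large(rng):
    with pytest.raises(ValueError):
        lagged_correlation(np.zeros(10), np.zeros(10), 3.0, 5.0)


def test_fdr_bh_hand_computed_example():
    assert np.allclose(fdr_correct([0.01, 0.02]), [0.02, 0.02])
    assert np.allclose(fdr_correct([0.5]), [0.5])
    assert np.allclose(fdr_correct([1.0, 1.0, 1.0]), 1.0)
    q = fdr_correct([0.01, 0.04, 0.03, 0.005])
    assert (q >= [0.01, 0.04, 0.03, 0.005]).all()
    with pytest.raises(ValueError):
        fdr_correct([0.5, 1.5])


def test_align_modalities_resampling(rng):
    t_hi = np.arange(int(60 * 2000)) / 2000
    t_lo = np.arange(int(60 * 5)) / 5
    sine_hi = np.sin(2 * np.pi * 0.05 * t_hi)
    sine_lo = np.sin(2 * np.pi * 0.05 * t_lo)
    a, b = align_modalities([(sine_hi, 2000.0), (sine_lo, 5.0)], target_rate=5.0)
    assert a.size == b.size
    assert np.corrcoef(a, b)[0, 1] > 0.999


def test_align_modalities_disjoint_support():
    with pytest.raises(ValueError, match="overlap"):
        align_modalities([(np.zeros(50), 5.0, 0.0), (np.zeros(50), 5.0, 100.0)],
                         target_rate=5.0)


def test_align_modalities_same_rate_crops(rng):
    x = rng.standard_normal(100)
    y = rng.standard_normal(80)
    a, b = align_modalities([(x, 5.0), (y, 5.0)], target_rate=5.0)
    assert a.size == b.size == 80
    assert np.array_equal(a, x[:80])
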