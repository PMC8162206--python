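import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from arspec import (
    ARModel,
    ArspecError,
    ConvergenceError,
    DivergenceWarning,
    RankDeficientError,
    SignalRecord,
    SinusoidComponent,
    build_design_system,
    characteristic_roots,
    extrapolate,
    fit_ar_bp,
    fit_ar_lms,
    generate_msw,
    implied_frequencies,
    select_order,
)
from conftest import random_mixture


def normal_equations_oracle(x: np.ndarray, p: int) -> np.ndarray:
    """Independent brute-force AR fit: build the lagged system with explicit
    loops and solve the normal equations directly."""
    L = len(x)
    rows = []
    b = []
    for t in range(p, L):
        rows.append([x[t - j] for j in range(1, p + 1)])
        b.append(x[t])
    A = np.array(rows)
    b = np.array(b)
    return np.linalg.solve(A.T @ A, A.T @ b)


class TestDesignSystem:
    def test_lag_ordering_on_small_example(self):
        sig = SignalRecord([1, 2, 3, 4, 5], fs=1)
        sys = build_design_system(sig, p=2)
        np.testing.assert_array_equal(sys.matrix, [[2, 1], [3, 2], [4, 3]])
        np.testing.assert_array_equal(sys.target, [3, 4, 5])

    def test_square_system_at_minimum_length(self):
        sys = build_design_system(SignalRecord([1, 2, 3, 4], fs=1), p=2)
        assert sys.matrix.shape == (2, 2)
        assert sys.target.shape == (2,)

    def test_too_short_signal_rejected_naming_minimum(self):
        with pytest.raises(ArspecError, match="L >= 2p = 4"):
            build_design_system(SignalRecord([1, 2, 3], fs=1), p=2)

    def test_intercept_appends_ones_column(self):
        sys = build_design_system(SignalRecord([1, 2, 3, 4, 5], fs=1), p=2,
                                  include_intercept=True)
        assert sys.matrix.shape == (3, 3)
        np.testing.assert_array_equal(sys.matrix[:, 2], [1, 1, 1])


class TestFitArLms:
    def test_arithmetic_progression_satisfies_order2_recurrence(self):
        model = fit_ar_lms(SignalRecord([1, 2, 3, 4, 5], fs=1), p=2)
        np.testing.assert_allclose(model.coefficients, [2, -1], atol=1e-9)
        assert model.training_rss <= 1e-16 * 55

    def test_geometric_series_is_ar1(self):
        model = fit_ar_lms(SignalRecord([1, 2, 4, 8, 16], fs=1), p=1)
        np.testing.assert_allclose(model.coefficients, [2], atol=1e-9)
        assert model.training_rss < 1e-12

    def test_single_sinusoid_recurrence_coefficients(self):
        x = np.cos(np.pi * np.arange(12) / 3)
        model = fit_ar_lms(SignalRecord(x, fs=6), p=2)
        np.testing.assert_allclose(model.coefficients, [1, -1], atol=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_normal_equations_oracle(self, seed):
        rng = np.random.default_rng(seed)
        L = int(rng.integers(12, 31))
        p = int(rng.integers(1, 5))
        x = rng.normal(size=L)
        model = fit_ar_lms(SignalRecord(x, fs=1), p)
        expected = normal_equations_oracle(x, p)
        np.testing.assert_allclose(model.coefficients, expected, atol=1e-9)

    def test_zero_signal_rejected_as_rank_deficient(self):
        with pytest.raises(RankDeficientError):
            fit_ar_lms(SignalRecord(np.zeros(20), fs=1), p=2)

    def test_intercept_recovers_nonzero_mean_process(self):
        # x[t] = 5 + 0.5 * (x[t-1] - 5): AR(1) around mean 5
        x = np.empty(40)
        x[0] = 7.0
        for t in range(1, 40):
            x[t] = 2.5 + 0.5 * x[t - 1]
        model = fit_ar_lms(SignalRecord(x, fs=1), p=1, include_intercept=True)
        assert model.coefficients[0] == pytest.approx(0.5, abs=1e-9)
        assert model.intercept == pytest.approx(2.5, abs=1e-8)


class TestFitArBp:
    def test_zero_epochs_returns_initial_weights(self):
        sig = SignalRecord([1, 2, 3, 4, 5], fs=1)
        model = fit_ar_bp(sig, p=2, epochs=0, init="zeros")
        np.testing.assert_array_equal(model.coefficients, [0, 0])
        assert model.training_rss == pytest.approx(9 + 16 + 25)

    def test_single_gradient_step_hand_computed(self):
        sig = SignalRecord([1, 2, 3, 4, 5], fs=1)
        model = fit_ar_bp(sig, p=2, learning_rate=0.01, epochs=1, init="zeros")
        expected = 0.01 * (2 / 3) * np.array([38.0, 26.0])
        np.testing.assert_allclose(model.coefficients, expected, atol=1e-12)

    def test_converges_to_closed_form_solution(self):
        sig = SignalRecord([1, 2, 3, 4, 5], fs=1)
        model = fit_ar_bp(sig, p=2, learning_rate=0.05, epochs=200_000)
        np.testing.assert_allclose(model.coefficients, [2, -1], atol=1e-3)

    def test_divergence_raises(self):
        sig = SignalRecord(np.arange(1.0, 21.0), fs=1)
        with pytest.raises(ConvergenceError, match="diverged"):
            fit_ar_bp(sig, p=2, learning_rate=10.0, epochs=1000)

    def test_random_init_is_seed_deterministic(self):
        sig, _ = random_mixture(1, 1000.0, 100, seed=3)
        a = fit_ar_bp(sig, p=2, epochs=10, init="random", seed=5)
        b = fit_ar_bp(sig, p=2, epochs=10, init="random", seed=5)
        np.testing.assert_array_equal(a.coefficients, b.coefficients)


class TestExtrapolate:
    def test_identity_recurrence_holds_last_value(self):
        model = ARModel(order=1, coefficients=[1.0])
        ext = extrapolate(model, SignalRecord([5, 4, 3], fs=1), n_extra=4)
        np.testing.assert_allclose(ext.samples, [5, 4, 3, 3, 3, 3, 3])

    def test_arithmetic_continuation(self):
        model = ARModel(order=2, coefficients=[2.0, -1.0])
        ext = extrapolate(model, SignalRecord([1, 2, 3, 4, 5], fs=1), n_extra=3)
        np.testing.assert_allclose(ext.samples[5:], [6, 7, 8], atol=1e-12)

    def test_prefix_is_bit_identical(self):
        sig, _ = random_mixture(2, 1000.0, 100, seed=0)
        model = fit_ar_lms(sig, 4)
        ext = extrapolate(model, sig, 50)
        assert np.array_equal(ext.samples[:100], sig.samples)

    def test_sinusoid_analytic_continuation(self):
        x = np.cos(np.pi * np.arange(12) / 3)
        sig = SignalRecord(x, fs=6)
        model = fit_ar_lms(sig, p=2)
        ext = extrapolate(model, sig, 600)
        truth = np.cos(np.pi * np.arange(612) / 3)
        np.testing.assert_allclose(ext.samples, truth, atol=1e-6)

    def test_intercept_carries_into_prediction(self):
        model = ARModel(order=1, coefficients=[0.0], intercept=2.5)
        ext = extrapolate(model, SignalRecord([1.0, 1.0], fs=1), n_extra=3)
        np.testing.assert_allclose(ext.samples[2:], [2.5, 2.5, 2.5])

    def test_negative_horizon_rejected(self):
        model = ARModel(order=1, coefficients=[1.0])
        with pytest.raises(ArspecError):
            extrapolate(model, SignalRecord([1.0], fs=1), n_extra=-1)

    def test_unstable_root_emits_divergence_warning(self):
        model = ARModel(order=1, coefficients=[1.1])
        with pytest.warns(DivergenceWarning):
            extrapolate(model, SignalRecord([1.0], fs=1), n_extra=2)

    @given(prefix_len=st.integers(0, 30), seed=st.integers(0, 50))
    @settings(max_examples=25, deadline=None)
    def test_prediction_depends_only_on_last_p_samples(self, prefix_len, seed):
        rng = np.random.default_rng(seed)
        core = rng.normal(size=10)
        model = ARModel(order=3, coefficients=rng.uniform(-0.4, 0.4, size=3))
        short = extrapolate(model, SignalRecord(core, fs=1), 20)
        padded = np.concatenate([rng.normal(size=prefix_len), core])
        long = extrapolate(model, SignalRecord(padded, fs=1), 20)
        np.testing.assert_allclose(short.samples[-20:], long.samples[-20:],
                                   atol=1e-12)


class TestCharacteristicRoots:
    def test_sinusoid_pair_on_unit_circle(self):
        model = ARModel(order=2, coefficients=[1.0, -1.0])
        roots = np.sort_complex(characteristic_roots(model))
        expected = np.sort_complex(np.array([np.exp(1j * np.pi / 3),
                                             np.exp(-1j * np.pi / 3)]))
        np.testing.assert_allclose(roots, expected, atol=1e-12)
        assert implied_frequencies(model, fs=6.0)[0] == pytest.approx(1.0)

    def test_ar1_root(self):
        model = ARModel(order=1, coefficients=[0.5])
        np.testing.assert_allclose(characteristic_roots(model), [0.5])

    def test_perfect_square_double_root(self):
        model = ARModel(order=2, coefficients=[1.0, -0.25])
        np.testing.assert_allclose(characteristic_roots(model), [0.5, 0.5], atol=1e-6)


class TestExactRecurrence:
    @pytest.mark.parametrize("n_tones,seed", [(1, 0), (2, 1), (3, 2), (2, 3)])
    def test_noiseless_mixture_fits_exactly_at_twice_tone_count(self, n_tones, seed):
        sig, comps = random_mixture(n_tones, 1000.0, 200, seed)
        model = fit_ar_lms(sig, 2 * n_tones)
        assert model.training_rss <= 1e-12 * np.sum(sig.samples**2)
        moduli = np.abs(characteristic_roots(model))
        np.testing.assert_allclose(moduli, 1.0, atol=1e-6)
        implied = implied_frequencies(model, sig.fs)[::2]  # one per conjugate pair
        np.testing.assert_allclose(implied, sorted(c.frequency for c in comps),
                                   atol=1e-6 * sig.fs)


class TestSelectOrder:
    def test_two_tone_mixture_needs_order_four(self):
        sig, _ = random_mixture(2, 1000.0, 200, seed=4)
        assert select_order(sig, max_order=8) == 4

    def test_noisy_signal_returns_max_order(self):
        sig = generate_msw([SinusoidComponent(50, 1)], 1000, 200, noise_sigma=0.5,
                           seed=0)
        assert select_order(sig, max_order=6) == 6
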