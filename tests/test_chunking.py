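import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import acf_brute_force
from srtlearn.binding_sim import BindingConfig, simulate_binding, theoretical_acf
from srtlearn.chunking import (
    AcfNull,
    AcfProfile,
    acf31,
    build_null,
    chunk_size,
    preprocess_probe,
)
from srtlearn.exceptions import DegenerateInputError, InsufficientDataError


class TestPreprocess:
    def test_perfect_line_detrends_to_zero(self):
        t = np.arange(100, dtype=float)
        out = preprocess_probe(250.0 + 1.5 * t)
        assert out.size == 68
        np.testing.assert_allclose(out, 0.0, atol=1e-9)

    def test_constant_plus_spike_preserved_and_zero_mean(self):
        x = np.full(96, 300.0)
        x[60] = 400.0
        out = preprocess_probe(x)
        assert abs(out.mean()) < 1e-9
        assert np.argmax(out) == 60 - 32
        assert out.max() > 80.0

    def test_first_cycle_dropped_and_mean_removed(self):
        rng = np.random.default_rng(0)
        x = rng.normal(350, 30, 256)
        out = preprocess_probe(x)
        assert out.size == 224
        assert abs(out.mean()) < 1e-9

    def test_missing_imputed_at_mean(self):
        x = np.full(96, 300.0)
        x[50] = np.nan
        out = preprocess_probe(x)
        assert np.isfinite(out).all()
        assert out[50 - 32] == pytest.approx(0.0, abs=1e-9)

    def test_mostly_missing_warns_but_proceeds(self):
        x = np.full(96, 300.0)
        x[32:70] = np.nan
        with pytest.warns(RuntimeWarning):
            out = preprocess_probe(x)
        assert out.size == 64

    def test_too_short_rejected(self):
        with pytest.raises(InsufficientDataError):
            preprocess_probe(np.ones(63))


class TestAcf31:
    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 100), n=st.integers(70, 500))
    def test_matches_double_loop_oracle(self, seed, n):
        x = np.random.default_rng(seed).normal(0, 10, n)
        x -= x.mean()
        prof = acf31(x)
        np.testing.assert_allclose(prof.rho, acf_brute_force(x, 31), atol=1e-12)

    def test_white_noise_has_no_structure(self):
        x = np.random.default_rng(1).normal(0, 1, 10_000)
        assert np.abs(acf31(x - x.mean()).rho).max() < 0.05

    def test_ar1_matches_closed_form(self):
        """Long AR(1)+noise series agrees with the analytic ACF."""
        y = simulate_binding(
            BindingConfig(alpha=0.75, sigma_p_ms=10, sigma_e_ms=10, n_blocks=1,
                          n_trials=100_000, seed=4)
        )[0]
        prof = acf31(y - y.mean())
        assert prof.rho[0] == pytest.approx(theoretical_acf(0.75, 10, 10, 1), abs=0.01)
        assert prof.rho[1] == pytest.approx(theoretical_acf(0.75, 10, 10, 2), abs=0.01)

    def test_alternating_series_sign_pattern(self):
        x = np.tile([1.0, -1.0], 50)
        prof = acf31(x)
        assert prof.rho[0] < 0 < prof.rho[1]

    def test_bounded_by_one(self):
        x = np.random.default_rng(5).normal(size=200).cumsum()  # strongly correlated
        assert np.abs(acf31(x - x.mean()).rho).max() <= 1.0

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateInputError):
            acf31(np.zeros(100))


class TestBuildNull:
    def test_two_profile_moments(self):
        a = AcfProfile(rho=np.full(31, 0.1), n_trials_used=224)
        b = AcfProfile(rho=np.full(31, 0.3), n_trials_used=224)
        null = build_null([a, b])
        assert null.mu[0] == pytest.approx(0.2)
        assert null.sigma[0] == pytest.approx(0.1414, abs=1e-4)
        assert null.n_subjects == 2

    def test_single_subject_rejected(self):
        with pytest.raises(InsufficientDataError):
            build_null([AcfProfile(rho=np.zeros(31), n_trials_used=224)])

    def test_null_cohort_mean_near_zero(self):
        rng = np.random.default_rng(6)
        null = build_null([acf31(rng.normal(0, 1, 224)) for _ in range(23)])
        assert np.all(np.abs(null.mu) < 3 * null.sigma / np.sqrt(23) + 0.05)


class TestChunkSize:
    def _null(self, sigma=0.05, n=23):
        return AcfNull(mu=np.zeros(31), sigma=np.full(31, sigma), n_subjects=n)

    def test_profile_equal_to_null_mean_gives_zero(self):
        prof = AcfProfile(rho=np.zeros(31), n_trials_used=224)
        assert chunk_size(prof, self._null()).size == 0

    def test_counts_consecutive_significant_lags(self):
        rho = np.zeros(31)
        rho[:4] = [0.5, 0.4, 0.3, 0.25]  # all >> 3.59 * sigma
        prof = AcfProfile(rho=rho, n_trials_used=224)
        est = chunk_size(prof, self._null(sigma=0.05))
        assert est.size == 4

    def test_gap_stops_the_count(self):
        rho = np.zeros(31)
        rho[[0, 1, 3]] = 0.5  # lag 3 not significant -> size 2
        prof = AcfProfile(rho=rho, n_trials_used=224)
        assert chunk_size(prof, self._null()).size == 2

    def test_negative_correlation_does_not_count(self):
        rho = np.zeros(31)
        rho[0] = -0.9
        prof = AcfProfile(rho=rho, n_trials_used=224)
        assert chunk_size(prof, self._null()).size == 0

    def test_monotone_in_effect_size(self):
        """Raising every rho (null fixed) can never shrink the estimate."""
        rng = np.random.default_rng(2)
        null = self._null(sigma=0.06)
        base = np.clip(0.3 * 0.8 ** np.arange(1, 32) + rng.normal(0, 0.02, 31), -0.9, 0.9)
        sizes = []
        for bump in (0.0, 0.05, 0.1, 0.2):
            prof = AcfProfile(rho=np.clip(base + bump, -1, 1), n_trials_used=224)
            sizes.append(chunk_size(prof, null).size)
        assert all(s2 >= s1 for s1, s2 in zip(sizes, sizes[1:]))

    def test_degenerate_null_sigma_rejected(self):
        prof = AcfProfile(rho=np.zeros(31), n_trials_used=224)
        null = AcfNull(mu=np.zeros(31), sigma=np.zeros(31), n_subjects=5)
        with pytest.raises(DegenerateInputError):
            chunk_size(prof, null)

    def test_z_reference_flag(self):
        rho = np.zeros(31)
        rho[0] = 0.2
        prof = AcfProfile(rho=rho, n_trials_used=224)
        null = self._null(sigma=0.055, n=5)
        # t with 4 df is stricter than z at the same corrected level
        assert chunk_size(prof, null, reference="z").size >= chunk_size(prof, null).size


class TestCalibration:
    def test_null_family_wise_rate(self):
        """Chunk size >= 1 under the exchangeable null stays near alpha (50 reps)."""
        rng = np.random.default_rng(11)
        hits = 0
        reps = 50
        for _ in range(reps):
            null = build_null([acf31(rng.normal(0, 1, 1024)) for _ in range(23)])
            est = chunk_size(acf31(rng.normal(0, 1, 1024)), null)
            hits += est.size >= 1
        assert hits / reps <= 0.05 + 1.96 * np.sqrt(0.05 * 0.95 / reps) + 1e-9

    def test_day1_like_profiles_give_zero_chunks(self):
        """Uncoupled (alpha ~ 0) cohorts should produce size 0 nearly always."""
        rng = np.random.default_rng(13)
        zeros = 0
        for _ in range(20):
            null = build_null([acf31(rng.normal(0, 1, 224)) for _ in range(23)])
            est = chunk_size(acf31(rng.normal(0, 1, 224)), null)
            zeros += est.size == 0
        assert zeros >= 18  # >= 90% of seeds
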