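import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import circatemp as ct
from circatemp.cosinor import _design, select_evening_acrophase
from circatemp.series import N_PROFILE_BINS, DayProfile

from conftest import profile_from_coeffs


def brute_force_amplitude(params, grid_seconds=1.0):
    """Independent oracle: half range of the curve on a 1-s grid."""
    t = np.arange(0.0, 24.0, grid_seconds / 3600.0)
    y = _design(t) @ np.asarray(params)
    return (y.max() - y.min()) / 2.0


class TestFit:
    def test_flat_profile_gives_zero_amplitude_and_no_phases(self, flat_profile):
        fit = ct.fit_cosinor(flat_profile)
        assert fit.M == pytest.approx(36.0, abs=1e-12)
        assert np.allclose([fit.a1, fit.b1, fit.a2, fit.b2], 0, atol=1e-12)
        assert fit.amplitude == pytest.approx(0.0, abs=1e-9)
        assert fit.acrophases == [] and fit.bathyphase is None

    def test_single_harmonic_recovers_analytic_phase_and_amplitude(self):
        # 35 + 1.0·cos(2π(clock − 3)/24): peak 03:00, trough 15:00
        truth = ct.RhythmTruth(35.0, 1.0, 3.0, noise_sd=0.0)
        coeffs = truth.cosinor_coefficients()
        prof = profile_from_coeffs(**{k: coeffs[k] for k in ("M", "a1", "b1", "a2", "b2")})
        fit = ct.fit_cosinor(prof)
        assert fit.M == pytest.approx(35.0, abs=1e-10)
        assert fit.amplitude == pytest.approx(1.0, abs=1e-8)
        assert fit.acrophase == pytest.approx(3.0, abs=1e-6)
        assert fit.bathyphase == pytest.approx(15.0, abs=1e-6)

    def test_two_harmonic_recovery_and_amplitude_oracle(self, rng):
        truth = ct.RhythmTruth(34.5, 0.7, 2.75, amp12=0.5, phase12=9.0, noise_sd=0.0)
        c = truth.cosinor_coefficients()
        prof = profile_from_coeffs(c["M"], c["a1"], c["b1"], c["a2"], c["b2"])
        fit = ct.fit_cosinor(prof)
        for k in ("M", "a1", "b1", "a2", "b2"):
            assert getattr(fit, k) == pytest.approx(c[k], abs=1e-8)
        oracle = brute_force_amplitude(fit.params)
        assert fit.amplitude == pytest.approx(oracle, abs=1e-6)

    def test_missing_bins_ignored_but_sparse_coverage_rejected(self):
        prof = profile_from_coeffs(35.0, 0.1, 0.2, 0.3, 0.4)
        vals = prof.values.copy()
        vals[::3] = np.nan
        fit = ct.fit_cosinor(DayProfile(vals, prof.counts))
        assert fit.n_bins_used == int(np.sum(~np.isnan(vals)))
        sparse = np.full(N_PROFILE_BINS, np.nan)
        sparse[:10] = 36.0  # < 12 h span
        with pytest.raises(ValueError):
            ct.fit_cosinor(DayProfile(sparse, np.ones(N_PROFILE_BINS, dtype=int)))


class TestDerivedQuantities:
    def test_amplitude_bounded_by_sum_of_harmonic_amplitudes(self, rng):
        for _ in range(30):
            params = np.concatenate([[35.0], rng.uniform(-1, 1, 4)])
            prof = profile_from_coeffs(*params)
            fit = ct.fit_cosinor(prof)
            r12 = np.hypot(fit.a1, fit.b1)
            r24 = np.hypot(fit.a2, fit.b2)
            assert fit.amplitude <= r12 + r24 + 1e-9

    def test_amplitude_attains_bound_when_single_harmonic(self):
        # the bound A <= r12 + r24 is tight when one harmonic vanishes
        prof24 = profile_from_coeffs(35.0, 0.0, 0.0, 0.3, 0.7)
        fit24 = ct.fit_cosinor(prof24)
        assert fit24.amplitude == pytest.approx(np.hypot(0.3, 0.7), abs=1e-6)
        prof12 = profile_from_coeffs(35.0, 0.4, 0.5, 0.0, 0.0)
        fit12 = ct.fit_cosinor(prof12)
        assert fit12.amplitude == pytest.approx(np.hypot(0.4, 0.5), abs=1e-6)

    def test_two_acrophases_about_12h_apart_evening_one_reported(self):
        # 12-h dominant pattern: peaks near 02:45 and 14:45
        truth = ct.RhythmTruth(34.3, 0.2, 2.75, amp12=0.7, phase12=2.75, noise_sd=0.0)
        c = truth.cosinor_coefficients()
        prof = profile_from_coeffs(c["M"], c["a1"], c["b1"], c["a2"], c["b2"])
        fit = ct.fit_cosinor(prof)
        assert len(fit.acrophases) == 2
        gap = abs(fit.acrophases[0] - fit.acrophases[1])
        assert min(gap, 24 - gap) == pytest.approx(12.0, abs=1.0)
        assert fit.acrophase <= 8.0 or fit.acrophase > 20.0

    def test_bathyphase_at_analytic_minimum(self):
        truth = ct.RhythmTruth(36.8, 0.4, 15.5, noise_sd=0.0)  # trough at 03:30
        c = truth.cosinor_coefficients()
        prof = profile_from_coeffs(c["M"], c["a1"], c["b1"], c["a2"], c["b2"], channel="core")
        fit = ct.fit_cosinor(prof)
        assert fit.bathyphase == pytest.approx(3.5, abs=1e-6)
        phases = ct.extract_phases(fit, "core")
        assert phases["bathyphase"] == fit.bathyphase

    def test_evening_window_selection(self):
        assert select_evening_acrophase([2.75, 14.33]) == pytest.approx(2.75)
        assert select_evening_acrophase([21.0, 9.5]) == pytest.approx(21.0)
        assert select_evening_acrophase([5.0]) == pytest.approx(5.0)
        assert select_evening_acrophase([]) is None


class TestInvariants:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        shift=st.integers(min_value=0, max_value=287),
        phase=st.floats(min_value=0.0, max_value=23.9),
    )
    def test_phase_equivariance_under_circular_shift(self, shift, phase):
        # fixed 12-vs-24 h phase offset keeps the curve asymmetric, so the
        # global minimum is unique and shifts continuously
        truth = ct.RhythmTruth(35.0, 0.8, phase, amp12=0.25, phase12=(phase + 5.21) % 24)
        c = truth.cosinor_coefficients()
        prof = profile_from_coeffs(c["M"], c["a1"], c["b1"], c["a2"], c["b2"])
        base = ct.fit_cosinor(prof)
        shifted = DayProfile(np.roll(prof.values, shift), prof.counts)
        fit = ct.fit_cosinor(shifted)
        delta = shift * 5 / 60.0
        d = (fit.bathyphase - base.bathyphase - delta) % 24.0
        assert min(d, 24 - d) < 1e-4

    def test_mesor_invariance_under_constant_offset(self):
        truth = ct.RhythmTruth(35.0, 0.8, 3.0, amp12=0.3, phase12=7.0)
        c = truth.cosinor_coefficients()
        prof = profile_from_coeffs(c["M"], c["a1"], c["b1"], c["a2"], c["b2"])
        fit0 = ct.fit_cosinor(prof)
        fit1 = ct.fit_cosinor(DayProfile(prof.values + 2.5, prof.counts))
        assert fit1.M == pytest.approx(fit0.M + 2.5, abs=1e-10)
        assert fit1.amplitude == pytest.approx(fit0.amplitude, abs=1e-9)
        assert fit1.acrophase == pytest.approx(fit0.acrophase, abs=1e-6)

    def test_fitted_mean_equals_mesor(self):
        truth = ct.RhythmTruth(35.0, 0.8, 3.0, amp12=0.3, phase12=7.0)
        c = truth.cosinor_coefficients()
        prof = profile_from_coeffs(c["M"], c["a1"], c["b1"], c["a2"], c["b2"])
        fit = ct.fit_cosinor(prof)
        assert fit.fitted.mean() == pytest.approx(fit.M, abs=1e-10)


class TestBootstrap:
    def _subject(self, seed, noise_sd=0.2):
        truth = ct.RhythmTruth(35.0, 0.8, 3.0, amp12=0.3, phase12=7.0,
                               noise_sd=noise_sd, noise_autocorr=0.5)
        s = ct.generate_temperature_series(truth, n_days=7, resolution=5, seed=seed)
        b5 = ct.bin_5min(s)
        return ct.day_profile(b5), b5

    def test_noiseless_input_gives_zero_width_intervals(self):
        prof, b5 = self._subject(seed=1, noise_sd=0.0)
        ci = ct.bootstrap_ci(prof, b5, n_boot=50, seed=2)
        for key, (lo, hi) in ci.items():
            # phases are located on a flat extremum: localisation noise ~1e-6 h
            tol = 1e-4 if key in ("acrophase", "bathyphase") else 1e-9
            assert hi - lo == pytest.approx(0.0, abs=tol)

    def test_fixed_seed_reproducible_and_covers_point_estimate(self):
        prof, b5 = self._subject(seed=3)
        ci_a = ct.bootstrap_ci(prof, b5, n_boot=100, seed=7)
        ci_b = ct.bootstrap_ci(prof, b5, n_boot=100, seed=7)
        assert ci_a == ci_b
        fit = ct.fit_cosinor(prof)
        lo, hi = ci_a["M"]
        assert lo <= fit.M <= hi

    def test_single_day_rejected(self):
        truth = ct.RhythmTruth(35.0, 0.8, 3.0, noise_sd=0.1)
        s = ct.generate_temperature_series(truth, n_days=1, resolution=5, seed=4)
        prof = ct.day_profile(ct.bin_5min(s))
        with pytest.raises(ValueError, match="2 contributing days"):
            ct.bootstrap_ci(prof, ct.bin_5min(s), n_boot=10, seed=5)
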