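"""MF-DFA chain: profile, detrended residuals, moments, spectrum."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hrvchaos as hc
from hrvchaos.core import DegenerateInputError, HrvChaosError
from hrvchaos.mfdfa import (
    MfdfaConfig,
    compute_profile,
    default_q_grid,
    default_scale_grid,
    fluctuation_function,
    generalized_hurst,
    local_rms,
    run_mfdfa,
    singularity_spectrum,
    spectrum_width,
    tau_from_h,
)


class TestProfile:
    def test_hand_example(self):
        np.testing.assert_allclose(compute_profile(np.array([1.0, 2.0, 3.0])), [-1, -1, 0])

    def test_constant_series_gives_zero_profile(self):
        np.testing.assert_array_equal(compute_profile(np.array([5.0] * 4)), np.zeros(4))

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=200))
    def test_last_element_telescopes_to_zero(self, values):
        x = np.asarray(values)
        profile = compute_profile(x)
        scale = max(1.0, np.abs(x).max())
        assert abs(profile[-1]) < 1e-9 * x.size * scale


class TestLocalRms:
    def test_linear_bin_detrends_to_zero(self):
        profile = 3.0 * np.arange(16.0) - 2.0
        assert local_rms(profile, s=8, v=1, m=1) == pytest.approx(0.0, abs=1e-18)
        assert local_rms(profile, s=8, v=2, m=1) == pytest.approx(0.0, abs=1e-18)

    def test_mean_subtraction_hand_example(self):
        # one bin of [0, 1, 0, -1], m = 0: mean 0, sum of squares / 4
        assert local_rms(np.array([0.0, 1.0, 0.0, -1.0]), s=4, v=1, m=0) == pytest.approx(0.5)

    def test_matches_normal_equations_oracle(self):
        """Independent least-squares via explicit normal equations on random bins."""
        rng = np.random.default_rng(12)
        for _ in range(100):
            s = int(rng.integers(4, 40))
            profile = rng.standard_normal(s * int(rng.integers(1, 4)))
            v = int(rng.integers(1, profile.size // s + 1))
            seg = profile[(v - 1) * s : v * s]
            i = np.arange(1.0, s + 1.0)
            design = np.column_stack([i, np.ones(s)])
            beta = np.linalg.solve(design.T @ design, design.T @ seg)
            expected = np.mean((seg - design @ beta) ** 2)
            assert local_rms(profile, s, v, m=1) == pytest.approx(expected, rel=1e-10)

    def test_bin_index_and_scale_validation(self):
        profile = np.arange(20.0)
        with pytest.raises(HrvChaosError):
            local_rms(profile, s=5, v=5, m=1)
        with pytest.raises(HrvChaosError):
            local_rms(profile, s=2, v=1, m=1)


class TestFluctuationFunction:
    def test_white_noise_scaling_exponent_half(self):
        cfg = MfdfaConfig(q_grid=np.array([2.0]))
        surface = fluctuation_function(hc.generate_fgn(0.5, 2**13, 9), cfg)
        h, _, _ = generalized_hurst(surface, cfg.scale_grid)
        assert h[0] == pytest.approx(0.5, abs=0.1)

    def test_equal_bins_collapse_all_q(self):
        """If every bin has the same residual c, F_q(s) = sqrt(c) for all q."""
        # a profile that repeats the same pattern in every bin of length 4
        pattern = np.array([0.0, 1.0, 0.0, -1.0])
        profile = np.tile(pattern, 16)
        from hrvchaos.mfdfa import _bin_squared_residuals, _fq_from_f2

        f2 = _bin_squared_residuals(profile, 4, 0, reverse=False)
        assert np.ptp(f2) == pytest.approx(0.0, abs=1e-15)
        q = np.array([-5.0, -1.0, 0.0, 2.0, 5.0])
        fq = _fq_from_f2(f2, q, 4)
        np.testing.assert_allclose(fq, np.sqrt(f2[0]), rtol=1e-12)

    def test_generalized_mean_monotone_in_q(self):
        cfg = MfdfaConfig(q_grid=np.array([-5.0, -2.0, 0.0, 2.0, 5.0]))
        surface = fluctuation_function(hc.generate_bpm_like(n=2048, seed=3), cfg)
        assert np.all(np.diff(surface, axis=0) >= -1e-12)

    def test_degenerate_bin_with_negative_q_raises(self):
        x = np.zeros(2048)
        x[:100] = np.sin(np.arange(100.0))  # rest constant -> zero-residual bins
        with pytest.raises(DegenerateInputError, match="negative moments"):
            fluctuation_function(x, MfdfaConfig(q_grid=np.array([-2.0])))

    def test_series_too_short_for_max_scale(self):
        with pytest.raises(HrvChaosError, match="too short"):
            fluctuation_function(hc.generate_fgn(0.5, 512, 0), MfdfaConfig())


class TestScalingFits:
    def test_exact_power_law_recovered(self):
        scales = default_scale_grid()
        surface = np.vstack([scales**0.7, 2.0 * scales**0.7])
        h, stderr, r2 = generalized_hurst(surface, scales)
        np.testing.assert_allclose(h, 0.7, rtol=1e-12)
        np.testing.assert_allclose(r2, 1.0, rtol=1e-12)

    def test_too_few_scales_raise(self):
        with pytest.raises(HrvChaosError):
            generalized_hurst(np.array([[1.0, 2.0, 4.0]]), np.array([16, 32, 64]))

    def test_tau_of_monofractal_is_linear(self):
        q = np.linspace(-5, 5, 101)  # contains q = 2 exactly
        tau = tau_from_h(np.full(q.size, 0.5), q)
        np.testing.assert_allclose(tau, 0.5 * q - 1.0)
        assert tau[np.argmin(np.abs(q - 2.0))] == pytest.approx(0.0, abs=1e-12)

    def test_monofractal_spectrum_is_a_point(self):
        q = default_q_grid()
        alpha, f_alpha = singularity_spectrum(np.full(q.size, 0.42), q)
        np.testing.assert_allclose(alpha, 0.42, atol=1e-12)
        np.testing.assert_allclose(f_alpha, 1.0, atol=1e-12)
        assert spectrum_width(alpha) == pytest.approx(0.0, abs=1e-12)

    def test_linear_hq_spectrum_apex_at_q_zero(self):
        q = np.linspace(-5, 5, 101)  # contains q = 0 exactly
        alpha, f_alpha = singularity_spectrum(0.8 - 0.05 * q, q)
        assert f_alpha[np.argmin(np.abs(q))] == pytest.approx(1.0, abs=1e-9)
        assert np.all(f_alpha <= 1.0 + 1e-9)

    def test_width_arithmetic(self):
        assert spectrum_width(np.array([0.3, 0.5, 0.9])) == pytest.approx(0.6)


class TestRunMfdfa:
    def test_cascade_width_large_white_noise_width_small(self, dyadic_scales):
        cfg = MfdfaConfig(scale_grid=dyadic_scales)
        cascade_width = run_mfdfa(hc.generate_binomial_cascade(0.75, 13), cfg).width
        noise_width = run_mfdfa(hc.generate_fgn(0.5, 2**13, 0), cfg).width
        assert cascade_width > 0.5
        assert noise_width < 0.3

    def test_deterministic(self):
        ts = hc.generate_bpm_like(n=2048, seed=8)
        a, b = run_mfdfa(ts), run_mfdfa(ts)
        np.testing.assert_array_equal(a.fq_surface, b.fq_surface)
        assert a.width == b.width

    def test_short_series_warns(self):
        with pytest.warns(UserWarning, match="unreliable"):
            run_mfdfa(hc.generate_fgn(0.5, 600, 1), MfdfaConfig(scale_grid=np.array([8, 16, 24, 32, 48])))

    def test_spectrum_apex_near_one_for_cascade(self, cascade_a06, dyadic_scales):
        res = run_mfdfa(cascade_a06, MfdfaConfig(scale_grid=dyadic_scales))
        assert res.f_alpha.max() == pytest.approx(1.0, abs=0.05)

    def test_config_rejects_scales_below_fit_order(self):
        with pytest.raises(HrvChaosError):
            MfdfaConfig(scale_grid=np.array([2, 4, 8]), detrend_order=1)
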