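import numpy as np
import pytest

from laminarkit.errors import DesignError, NormalizationError
from laminarkit.funcsignal import (
    DepthResponseProfile,
    PhaseEncodedSeries,
    average_phase_runs,
    calibrated_depth_profile,
    canonical_hrf,
    ecm_rlc,
    fit_prf_1d,
    fourier_amplitude,
    load_series_h5,
    noise_ceiling,
    peak_decay_metrics,
    save_series_h5,
)
from laminarkit.laminar import LayerCompartments


def make_series(samples, direction="forward", brightness=100.0):
    samples = np.atleast_2d(samples)
    n = samples.shape[1]
    return PhaseEncodedSeries(
        samples,
        tr=2.0,
        n_cycles=20,
        cycle_length=n * 2.0 / 20,
        direction=direction,
        mean_brightness=brightness,
    )


class TestPhaseEncodedSeriesType:
    def test_design_arithmetic_enforced(self):
        with pytest.raises(DesignError):
            PhaseEncodedSeries(np.zeros((1, 100)), 2.0, 20, 25.6)

    def test_positive_tr(self):
        with pytest.raises(ValueError):
            PhaseEncodedSeries(np.zeros((1, 10)), 0.0, 2, 10.0)

    def test_rest_cropping(self):
        s = PhaseEncodedSeries(
            np.arange(160.0)[None, :], 2.0, 8, 32.0, rest_pre_s=32.0,
            rest_post_s=32.0,
        )
        cropped = s.stimulation_window()
        assert cropped.n_timepoints == 128
        assert cropped.samples[0, 0] == 16.0

    def test_h5_roundtrip(self, tmp_path):
        s = make_series(np.random.default_rng(0).normal(100, 1, (3, 256)))
        p = tmp_path / "series.h5"
        save_series_h5(s, p)
        back = load_series_h5(p)
        assert np.allclose(back.samples, s.samples)
        assert back.n_cycles == s.n_cycles


class TestAveragePhaseRuns:
    def test_constructed_mirror_pair_recovers_forward(self):
        rng = np.random.default_rng(3)
        fwd = make_series(rng.normal(100, 5, (4, 256)))
        # reverse run = time-reversal of the forward run pre-shifted by 2 TRs
        rev = make_series(np.roll(fwd.samples, -2, axis=1)[:, ::-1], "reverse")
        out = average_phase_runs(fwd, rev)
        assert np.allclose(out.samples, fwd.samples)
        assert out.direction == "forward"

    def test_all_zero_runs(self):
        fwd = make_series(np.zeros((2, 256)))
        rev = make_series(np.zeros((2, 256)), "reverse")
        assert np.allclose(average_phase_runs(fwd, rev).samples, 0.0)

    def test_shift_is_two_samples_at_tr2(self):
        fwd = make_series(np.zeros((1, 256)))
        rev_samples = np.zeros((1, 256))
        rev_samples[0, 100] = 1.0
        rev = make_series(rev_samples, "reverse")
        out = average_phase_runs(fwd, rev)
        # reversal maps 100 -> 155, then +2 shift -> 157
        assert out.samples[0, 157] == pytest.approx(0.5)

    def test_direction_and_shape_checked(self):
        fwd = make_series(np.zeros((1, 256)))
        with pytest.raises(ValueError):
            average_phase_runs(fwd, fwd)
        rev_short = PhaseEncodedSeries(
            np.zeros((1, 128)), 2.0, 20, 12.8, direction="reverse"
        )
        with pytest.raises(ValueError):
            average_phase_runs(fwd, rev_short)

    def test_variance_halving_on_independent_noise(self):
        rng = np.random.default_rng(11)
        ratios = []
        for _ in range(200):
            fwd = make_series(rng.normal(0, 1, (1, 64)))
            rev = make_series(rng.normal(0, 1, (1, 64)), "reverse")
            out = average_phase_runs(fwd, rev)
            ratios.append(out.samples.var())
        assert np.mean(ratios) == pytest.approx(0.5, abs=0.05)


class TestFourierAmplitude:
    def test_cosine_amplitude_exact(self):
        n, cycles, b = 256, 20, 100.0
        t = np.arange(n)
        x = b + 1.0 * np.cos(2 * np.pi * cycles * t / n)  # peak-to-peak 2
        amp, phase, f = fourier_amplitude(make_series(x, brightness=b))
        assert amp[0] == pytest.approx(2.0, abs=1e-6)
        assert f[0] > 1e3

    def test_all_zero_series(self):
        amp, _, f = fourier_amplitude(make_series(np.zeros(256)))
        assert amp[0] == 0.0
        assert f[0] == 0.0

    def test_drift_below_cutoff_excluded(self):
        # 0.003 Hz drift: ~1.5 cycles over 512 s -> below-cutoff bins only
        n = 256
        t = np.arange(n) * 2.0
        drift = 5.0 * np.cos(2 * np.pi * (1 / (n * 2.0)) * t)  # bin 1, ~0.002 Hz
        amp, _, f = fourier_amplitude(make_series(100.0 + drift))
        assert amp[0] == pytest.approx(0.0, abs=1e-9)
        assert np.isfinite(f[0])

    def test_zero_brightness_rejected(self):
        with pytest.raises(ValueError):
            fourier_amplitude(make_series(np.ones(256), brightness=0.0))

    def test_too_few_cycles_rejected(self):
        s = PhaseEncodedSeries(np.ones((1, 64)), 2.0, 1, 128.0)
        with pytest.raises(ValueError):
            fourier_amplitude(s)

    def test_harmonics_excluded_from_noise_set(self):
        # energy at the second harmonic must not depress the F-ratio
        n, cycles = 256, 20
        t = np.arange(n)
        noise = np.random.default_rng(9).normal(0, 0.1, n)
        base = np.cos(2 * np.pi * cycles * t / n) + noise
        with_h = base + 5.0 * np.cos(2 * np.pi * 2 * cycles * t / n)
        _, _, f0 = fourier_amplitude(make_series(100 + base))
        _, _, f1 = fourier_amplitude(make_series(100 + with_h))
        assert f1[0] == pytest.approx(f0[0], rel=1e-9)


class TestCalibratedDepthProfile:
    def test_monotone_task_normalizes_to_unit_interval(self):
        task = np.linspace(0.5, 2.5, 21)
        rest = np.linspace(1.0, 2.0, 21) + np.sin(np.arange(21))
        prof = calibrated_depth_profile(task, rest)
        assert prof.normalized[0] == pytest.approx(0.0)
        assert prof.normalized[-1] == pytest.approx(1.0)

    def test_identical_profiles_calibrate_to_constant(self):
        task = np.linspace(0.5, 2.5, 21) ** 1.3
        prof = calibrated_depth_profile(task, task.copy())
        assert np.allclose(prof.calibrated, 1.0)

    def test_constant_rest_raises(self):
        with pytest.raises(NormalizationError):
            calibrated_depth_profile(np.linspace(0, 1, 21), np.full(21, 2.0))

    def test_subtract_mode(self):
        task = np.linspace(0.5, 2.5, 21)
        prof = calibrated_depth_profile(task, task.copy(), mode="subtract")
        assert np.allclose(prof.calibrated, 0.0)

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            calibrated_depth_profile(np.ones(20), np.ones(20))


class TestPeakDecayMetrics:
    COMPS = LayerCompartments(6, 12, 6 / 18, 12 / 18)

    def _profile(self, calibrated):
        return DepthResponseProfile(
            np.zeros(21), np.zeros(21), np.zeros(21), np.asarray(calibrated)
        )

    def test_flat_profile_gives_zero_metrics(self):
        peak, decay = peak_decay_metrics(self._profile(np.ones(21)), self.COMPS)
        assert peak == 0.0
        assert decay == 0.0

    def test_triangular_bump_matches_analytic_area(self):
        cal = np.zeros(21)
        for i in range(6, 13):
            cal[i] = 1.0 - abs(i - 9) / 3.0
        peak, decay = peak_decay_metrics(self._profile(cal), self.COMPS)
        # triangle base 6 depth steps = 0.3 depth fraction, height 1
        assert peak == pytest.approx(0.15)
        assert decay == pytest.approx(0.0)

    def test_superficial_exclusion_retains_17_depths(self):
        # a large bump confined to the most superficial 20% must not count
        cal = np.ones(21)
        cal[:4] = 50.0
        peak, _ = peak_decay_metrics(self._profile(cal), self.COMPS)
        assert peak == pytest.approx(0.0)

    def test_decay_positive_for_center_peak(self):
        # middle elevated above the median, inner flank dipping below it
        cal = np.full(21, 0.6)
        cal[6:13] = 1.0
        cal[15:] = 0.2
        peak, decay = peak_decay_metrics(self._profile(cal), self.COMPS)
        assert peak > 0
        assert decay > 0


class TestPRF:
    def _design(self):
        space = np.linspace(-1, 1, 41)
        n_t = 128
        slots = (np.arange(n_t) // 8) % 4
        centers = np.linspace(-0.75, 0.75, 4)
        ap = np.exp(
            -0.5 * ((space[None, :] - centers[slots][:, None]) / 0.15) ** 2
        )
        return ap, space

    def _timecourse(self, mu, sigma, ap, space):
        hrf = canonical_hrf(2.0)
        rf = np.exp(-0.5 * ((space - mu) / sigma) ** 2)
        drive = ap @ rf
        return np.convolve(drive, hrf)[: len(drive)]

    def test_noiseless_parameter_recovery(self):
        ap, space = self._design()
        tc = self._timecourse(0.3, 0.2, ap, space)
        fit = fit_prf_1d(tc, ap, space)
        assert abs(fit.mu - 0.3) <= 0.02
        assert abs(fit.sigma - 0.2) / 0.2 <= 0.10
        assert fit.beta > 0
        assert fit.r2 > 0.95

    def test_search_bounds_exceed_stimulus_space(self):
        ap, space = self._design()
        tc = self._timecourse(0.95, 0.3, ap, space)
        fit = fit_prf_1d(tc, ap, space)
        assert -1.25 <= fit.mu <= 1.25

    def test_negative_beta_fit_on_inverted_response(self):
        ap, space = self._design()
        tc = -self._timecourse(0.0, 0.3, ap, space)
        fit = fit_prf_1d(tc, ap, space)
        # summaries discard beta <= 0; the fit itself reports it
        assert fit.beta <= 1e-6

    def test_nonfinite_timecourse_rejected(self):
        ap, space = self._design()
        tc = np.full(ap.shape[0], np.nan)
        with pytest.raises(ValueError):
            fit_prf_1d(tc, ap, space)

    def test_degenerate_design_flagged(self):
        space = np.linspace(-1, 1, 41)
        ap = np.zeros((64, 41))
        fit = fit_prf_1d(np.random.default_rng(0).normal(size=64), ap, space)
        assert fit.degenerate

    def test_nr2_uses_ceiling(self):
        ap, space = self._design()
        tc = self._timecourse(0.1, 0.25, ap, space)
        fit = fit_prf_1d(tc, ap, space, ceiling=0.8)
        assert fit.nr2 == pytest.approx(fit.r2 / 0.8)


class TestNoiseCeiling:
    def test_identical_halves_ceiling_one(self):
        x = np.random.default_rng(0).normal(size=50)
        assert noise_ceiling(x, x.copy()) == pytest.approx(1.0)

    def test_half_correlation_formula(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=500)
        b = 0.5 * a + rng.normal(size=500)
        r = np.corrcoef(a, b)[0, 1]
        assert noise_ceiling(a, b) == pytest.approx(2 * r / (1 + r))

    def test_r_half_05_gives_two_thirds(self):
        # construct halves with exact r = 0.5
        a = np.array([1.0, -1.0, 1.0, -1.0])
        b = np.array([1.0, -1.0, 0.0, 0.0])
        r = np.corrcoef(a, b)[0, 1]
        assert r == pytest.approx(np.sqrt(0.5))
        a2 = np.array([1.0, 1.0, -1.0, -1.0, 1.0, -1.0])
        b2 = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        assert np.corrcoef(a2, b2)[0, 1] == pytest.approx(1 / 3)
        # direct formula evaluation at r = 0.5
        assert 2 * 0.5 / 1.5 == pytest.approx(2 / 3)

    def test_independent_noise_halves_near_zero(self):
        rng = np.random.default_rng(2)
        vals = [
            noise_ceiling(rng.normal(size=100), rng.normal(size=100))
            for _ in range(200)
        ]
        assert np.mean(vals) < 0.15

    def test_constant_half_rejected(self):
        with pytest.raises(ValueError):
            noise_ceiling(np.ones(10), np.arange(10.0))


class TestEcmRlc:
    def test_shared_timecourse_gives_equal_centralities(self):
        base = np.sin(np.arange(100) / 5.0)
        x = np.tile(base, (5, 1)) + 0  # identical rows
        c = ecm_rlc(x)
        assert np.allclose(c, c[0])
        assert np.linalg.norm(c) == pytest.approx(1.0)

    def test_matches_dense_eigendecomposition_oracle(self):
        rng = np.random.default_rng(4)
        hub_drive = rng.normal(size=400)
        x = np.vstack(
            [hub_drive]
            + [0.6 * hub_drive + 0.8 * rng.normal(size=400) for _ in range(5)]
        )
        c = ecm_rlc(x)
        a = np.corrcoef(x)
        np.fill_diagonal(a, 0.0)
        a = np.maximum(a, 0.0)
        w, v = np.linalg.eigh(a)
        principal = np.abs(v[:, np.argmax(w)])
        assert np.allclose(c, principal / np.linalg.norm(principal), atol=1e-8)
        assert np.argmax(c) == 0  # hub wins

    def test_anticorrelated_pair_rectified_to_zero(self):
        rng = np.random.default_rng(5)
        s = rng.normal(size=300)
        n = rng.normal(size=300)
        # vertex 1 is the exact negative of vertex 0: its connections to both
        # others are rectified to zero, leaving it isolated
        x = np.vstack([s, -s, 0.5 * s + n])
        c = ecm_rlc(x)
        assert c[1] == pytest.approx(0.0, abs=1e-6)
        assert c[0] > 0.5

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(6, 200))
        x[1] += 0.5 * x[0]
        perm = rng.permutation(6)
        c = ecm_rlc(x)
        cp = ecm_rlc(x[perm])
        assert np.allclose(cp, c[perm], atol=1e-8)

    def test_uniform_on_zero_adjacency(self):
        # three exactly mutually anticorrelated-or-zero series are hard to
        # construct; orthogonal sign patterns give zero correlations
        x = np.array(
            [
                [1.0, 1.0, -1.0, -1.0],
                [1.0, -1.0, 1.0, -1.0],
                [1.0, -1.0, -1.0, 1.0],
            ]
        )
        with pytest.warns(UserWarning):
            c = ecm_rlc(x)
        assert np.allclose(c, 1 / np.sqrt(3))

    def test_minimum_vertices(self):
        with pytest.raises(ValueError):
            ecm_rlc(np.random.default_rng(0).normal(size=(2, 50)))

    def test_constant_row_rejected(self):
        x = np.random.default_rng(0).normal(size=(4, 50))
        x[2] = 3.0
        with pytest.raises(ValueError):
            ecm_rlc(x)
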