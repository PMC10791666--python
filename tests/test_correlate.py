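"""FSC/SFSC estimators, corrections, SSNR and resolution."""

import numpy as np
import pytest

import sfsc
from sfsc import (
    Measurement,
    SimulationParams,
    correct_variance,
    efsc_analytic,
    esfsc_analytic_1d,
    fsc,
    resolution_at_threshold,
    simulate,
    ssnr_direct,
    ssnr_from_curve,
)
from sfsc.correlate import CorrelationCurve


class TestFSC:
    def test_self_correlation_is_one(self, rng):
        m = Measurement(rng.standard_normal((16, 16)), 1.0)
        c = fsc(m, m)
        v = c.profile.value[np.asarray(c.profile.defined)]
        np.testing.assert_allclose(v, 1.0, atol=1e-12)

    def test_negated_copy_gives_minus_one(self, rng):
        m = Measurement(rng.standard_normal((16, 16)), 1.0)
        neg = Measurement(-m.data, 1.0)
        c = fsc(m, neg)
        v = c.profile.value[np.asarray(c.profile.defined)]
        np.testing.assert_allclose(v, -1.0, atol=1e-12)

    def test_independent_noise_near_zero(self):
        # null distribution: |FSC| <~ 4/sqrt(n_r) per shell
        for seed in range(5):
            g = np.random.default_rng(seed)
            a = Measurement(g.standard_normal((32, 32, 32)), 1.0)
            b = Measurement(g.standard_normal((32, 32, 32)), 1.0)
            p = fsc(a, b).profile.complete_shells()
            assert (np.abs(p.value) <= 4 / np.sqrt(p.n_indices)).all()

    def test_symmetry_and_scale_invariance(self, rng):
        a = Measurement(rng.standard_normal((16, 16)), 1.0)
        b = Measurement(rng.standard_normal((16, 16)), 1.0)
        c1 = fsc(a, b).profile.value
        c2 = fsc(b, a).profile.value
        c3 = fsc(Measurement(5.0 * a.data, 1.0), b).profile.value
        np.testing.assert_allclose(c1, c2, atol=1e-12)
        np.testing.assert_allclose(c1, c3, atol=1e-12)

    def test_shape_mismatch_errors(self, rng):
        a = Measurement(rng.standard_normal((16, 16)), 1.0)
        b = Measurement(rng.standard_normal((8, 8)), 1.0)
        with pytest.raises(ValueError, match="mismatch"):
            fsc(a, b)


class TestSFSC:
    def test_noiseless_band_limited_is_one(self):
        t = np.arange(64)
        img = (np.cos(2 * np.pi * 3 * t / 64)[:, None]
               + np.sin(2 * np.pi * 2 * t / 64)[None, :])
        c = sfsc.sfsc(Measurement(img, 1.0))
        p = c.profile
        assert p.value[2] == pytest.approx(1.0, abs=1e-9)
        assert p.value[3] == pytest.approx(1.0, abs=1e-9)

    def test_white_noise_mean_near_zero(self):
        vals = []
        for seed in range(20):
            m = Measurement(np.random.default_rng(seed).standard_normal((64, 64)), 1.0)
            vals.append(sfsc.sfsc(m).profile.value)
        mean = np.nanmean(vals, axis=0)
        sem = np.nanstd(vals, axis=0, ddof=1) / np.sqrt(len(vals))
        p = sfsc.sfsc(m).profile
        sel = p.complete & p.defined & (p.shell >= 1)
        assert (np.abs(mean[sel]) <= 3 * sem[sel] + 0.01).all()

    def test_scale_invariance(self, small_phantom):
        m = small_phantom.measurement
        c1 = sfsc.sfsc(m).profile.value
        c2 = sfsc.sfsc(Measurement(7.0 * m.data, m.voxel_size)).profile.value
        np.testing.assert_allclose(c1, c2, atol=1e-10)

    def test_per_axis_curves_recorded(self, small_phantom):
        c = sfsc.sfsc(small_phantom.measurement)
        assert len(c.metadata["per_axis"]) == 2
        assert c.metadata["phase_correction"] is True

    def test_shell_labels_match_original_frequency_axis(self, small_phantom):
        gt = small_phantom
        c = sfsc.sfsc(gt.measurement)
        # shell r of the SFSC sits at the same physical frequency as
        # shell r of the full-grid FSC
        f = fsc(gt.measurement, gt.measurement)
        n = min(len(c.profile), len(f.profile))
        np.testing.assert_allclose(
            c.profile.frequency[:n], f.profile.frequency[:n], rtol=1e-12
        )


class TestVarianceCorrection:
    def make(self, values):
        values = np.asarray(values, dtype=float)
        n = len(values)
        prof = sfsc.RadialProfile(
            shell=np.arange(n), frequency=np.arange(n) / n,
            value=values.copy(), n_indices=np.full(n, 8),
            complete=np.ones(n, bool))
        return CorrelationCurve(prof, "sfsc_raw", {})

    def test_fixed_points_and_third(self):
        c = correct_variance(self.make([0.0, 1.0, 1.0 / 3.0]))
        assert c.value[0] == pytest.approx(0.0)
        assert c.value[1] == pytest.approx(1.0)
        assert c.value[2] == pytest.approx(0.5)

    def test_negative_values_pass_through_formula(self):
        c = correct_variance(self.make([-1.0 / 3.0]))
        assert c.value[0] == pytest.approx(-1.0)

    def test_monotone_on_interval(self):
        v = np.linspace(-0.9, 1.0, 50)
        c = correct_variance(self.make(v)).value[:50]
        assert (np.diff(c) > 0).all()

    def test_double_application_guarded(self):
        c = correct_variance(self.make([0.5]))
        with pytest.raises(ValueError):
            correct_variance(c)


class TestAnalyticCurves:
    def test_efsc_substitutions(self, small_phantom):
        lam, sig = small_phantom.lambda2, small_phantom.sigma2
        lam.value[:3] = [1.0, 2.0, 1.0]
        sig.value[:3] = [1.0, 1.0, 0.0]
        e = efsc_analytic(lam, sig).profile.value
        assert e[0] == pytest.approx(0.5)
        assert e[1] == pytest.approx(2.0 / 3.0)
        assert e[2] == pytest.approx(1.0)

    def test_esfsc_1d_regimes(self):
        n = 8
        lam = np.zeros(n); sig = np.ones(n)
        # rapid decay + white noise: matches lambda^2/(lambda^2 + 2 sigma^2)
        lam[0] = 2.0
        assert esfsc_analytic_1d(lam, sig, n)[0] == pytest.approx(0.5)
        # flat signal: numerator cancels -> 0 (underestimate regime)
        lam2 = np.ones(n)
        assert esfsc_analytic_1d(lam2, sig, n)[1] == pytest.approx(0.0)
        # colored noise, no signal: overestimate regime
        lam3 = np.zeros(n)
        sig3 = np.concatenate([np.full(4, 2.0), np.ones(4)])
        assert esfsc_analytic_1d(lam3, sig3, n)[0] == pytest.approx(1.0 / 3.0)

    def test_esfsc_1d_matches_monte_carlo(self):
        # oracle equivalence: Eq-10 style expectation vs empirical mean of
        # the raw 1-D SFSC numerator/denominator ratio
        n = 32
        idx = sfsc.build_shell_index((n,))
        lam = np.exp(-0.5 * (np.arange(idx.n_shells) / 6.0) ** 2)
        sig = np.full(idx.n_shells, 0.3)
        lam_k = lam[idx.radii]
        sig_k = sig[idx.radii]
        expected = esfsc_analytic_1d(lam_k, sig_k, n)
        nums, dens = [], []
        for seed in range(4000):
            g = np.random.default_rng(seed)
            x = sfsc.gaussian_field(idx, lam, g)
            e = sfsc.gaussian_field(idx, sig, g)
            m = Measurement(x.data + e.data, 1.0)
            pair = sfsc.split_axis(m, 0)
            fe = np.fft.fft(pair.even.data)
            fo = sfsc.phase_correct_odd(pair)
            nums.append((np.conj(fe) * fo).real)
            dens.append((np.abs(fe) ** 2 + np.abs(fo) ** 2) / 2)
        ratio = np.mean(nums, axis=0) / np.mean(dens, axis=0)
        # compare on the positive-frequency half, away from DC
        np.testing.assert_allclose(ratio[1:8], expected[1:8], atol=0.05)


class TestSSNR:
    def make_curve(self, values, kind="sfsc_corrected"):
        m = Measurement(np.random.default_rng(0).standard_normal((8, 8)), 1.0)
        base = sfsc.sfsc(m)
        prof = base.profile
        prof.value[:] = np.nan
        prof.value[: len(values)] = values
        prof.defined = np.isfinite(prof.value)
        return CorrelationCurve(prof, kind, {})

    def test_transform_values(self):
        c = ssnr_from_curve(self.make_curve([0.5, 0.0, 1.0 / 7.0]))
        assert c.value[0] == pytest.approx(1.0)
        assert c.value[1] == pytest.approx(0.0)
        assert c.value[2] == pytest.approx(1.0 / 6.0)

    def test_saturation_and_clamping(self):
        c = ssnr_from_curve(self.make_curve([1.0, -0.2]))
        assert np.isinf(c.value[0])
        assert c.value[1] == 0.0
        assert c.metadata["negative_shells_clamped"] == 1

    def test_direct_estimator(self, small_phantom):
        ps = small_phantom.lambda2
        ps2 = sfsc.RadialProfile(ps.shell.copy(), ps.frequency.copy(),
                                 np.full(len(ps), 2.0), ps.n_indices.copy(),
                                 ps.complete.copy(), np.ones(len(ps), bool))
        s2 = sfsc.RadialProfile(ps.shell.copy(), ps.frequency.copy(),
                                np.ones(len(ps)), ps.n_indices.copy(),
                                ps.complete.copy(), np.ones(len(ps), bool))
        c = ssnr_direct(ps2, s2)
        np.testing.assert_allclose(c.value, 1.0)
        # PS below the noise level clamps to zero
        low = sfsc.RadialProfile(ps.shell.copy(), ps.frequency.copy(),
                                 np.full(len(ps), 0.5), ps.n_indices.copy(),
                                 ps.complete.copy(), np.ones(len(ps), bool))
        np.testing.assert_allclose(ssnr_direct(low, s2).value, 0.0)

    def test_direct_matches_generative_ssnr(self):
        # mean over seeds of (PS - sigma2)/sigma2 converges to lambda2/sigma2
        gts = [simulate(SimulationParams((64, 64), 1.0, 60.0, 0.0, 2.0, s))
               for s in range(20)]
        gt = gts[0]
        n_total = 64 * 64
        est = []
        for g in gts:
            ps = sfsc.power_spectrum(g.measurement)
            nm = g.noise_model()
            est.append(ssnr_direct(ps, nm.sigma2).profile.value)
        mean = np.mean(est, axis=0)
        truth = gt.lambda2.value / gt.sigma2.value
        band = slice(1, 32)
        # per-shell sampling error ~ truth/sqrt(n_r*seeds/2): small shells
        # are noisy, so allow a relative term on top of the absolute one
        np.testing.assert_allclose(mean[band], truth[band],
                                   atol=0.3, rtol=0.15)


class TestResolution:
    def linear_curve(self, n_shells, crossing, voxel=1.0, n=100):
        shells = np.arange(n_shells)
        value = np.clip(1.0 - shells / (2 * crossing) * (1 - 1 / 7) * 2, -0.2, 1.0)
        # construct a curve crossing 1/7 exactly at `crossing`
        value = 1.0 - (1.0 - 1.0 / 7.0) * shells / crossing
        prof = sfsc.RadialProfile(
            shell=shells, frequency=shells / (n * voxel), value=value,
            n_indices=np.full(n_shells, 10), complete=np.ones(n_shells, bool),
        )
        return CorrelationCurve(prof, "sfsc_corrected", {"voxel_size": voxel})

    def test_exact_crossing(self):
        c = self.linear_curve(30, crossing=10.0)
        res = resolution_at_threshold(c, 1.0 / 7.0)
        assert res.crossing_shell == pytest.approx(10.0)
        assert res.resolution == pytest.approx(100.0 / 10.0)

    def test_never_below_returns_nyquist_flagged(self):
        c = self.linear_curve(30, crossing=10.0)
        c.profile.value[:] = 1.0
        res = resolution_at_threshold(c, 1.0 / 7.0, voxel_size=0.81)
        assert res.at_nyquist
        assert res.resolution == pytest.approx(1.62)

    def test_below_at_first_shell_errors(self):
        c = self.linear_curve(30, crossing=10.0)
        c.profile.value[:] = 0.0
        with pytest.raises(ValueError, match="no resolvable"):
            resolution_at_threshold(c, 1.0 / 7.0)

    def test_threshold_bounds(self):
        c = self.linear_curve(30, crossing=10.0)
        with pytest.raises(ValueError):
            resolution_at_threshold(c, 1.5)
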