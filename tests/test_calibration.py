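"""Hill calibration: forward/inverse model, fitting, measurable range, and
the image-to-concentration pipeline."""

import numpy as np
import pytest
from scipy import stats

import flimcal as fc
from flimcal.calibration import FLAG_BELOW, FLAG_MASKED, FLAG_OK, FLAG_SATURATED


class TestHillModel:
    def test_half_saturation(self):
        p = fc.HillParams(200.0, 1.5, 0.1, 0.9)
        assert fc.hill_fraction(200.0, p) == pytest.approx(0.5)

    def test_zero_concentration_limit(self):
        p = fc.HillParams(200.0, 1.5, 0.1, 0.9)
        assert fc.hill_fraction(0.0, p) == pytest.approx(0.1)

    def test_saturation_limit(self):
        p = fc.HillParams(200.0, 1.5)
        assert fc.hill_fraction(1e9 * 200.0, p) == pytest.approx(1.0, abs=1e-9)

    def test_strictly_increasing(self):
        p = fc.HillParams(200.0, 1.5)
        L = np.logspace(-1, 6, 500)
        assert np.all(np.diff(fc.hill_fraction(L, p)) > 0)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            fc.HillParams(-1.0, 1.5)
        with pytest.raises(ValueError):
            fc.HillParams(200.0, 1.5, 0.7, 0.6)


class TestHillInverse:
    def test_midpoint_inverts_to_kd(self):
        p = fc.HillParams(209.0, 1.53, 0.05, 0.95)
        L, flag = fc.concentration_from_fraction(0.5, p)
        assert L == pytest.approx(209.0) and flag == FLAG_OK

    def test_below_range_flag(self):
        p = fc.HillParams(209.0, 1.53, 0.1, 0.9)
        L, flag = fc.concentration_from_fraction(0.05, p)
        assert L == 0.0 and flag == FLAG_BELOW

    def test_saturated_flag(self):
        p = fc.HillParams(209.0, 1.53)
        L, flag = fc.concentration_from_fraction(1.0, p)
        assert np.isinf(L) and flag == FLAG_SATURATED

    def test_round_trip_inside_open_interval(self):
        p = fc.HillParams(209.0, 1.53, 0.02, 0.98)
        f = np.linspace(0.03, 0.97, 300)
        L, flags = fc.concentration_from_fraction(f, p)
        assert np.all(flags == FLAG_OK)
        np.testing.assert_allclose(fc.hill_fraction(L, p), f, rtol=1e-9)

    def test_inverse_strictly_increasing(self):
        p = fc.HillParams(209.0, 1.53)
        f = np.linspace(0.01, 0.99, 200)
        L, _ = fc.concentration_from_fraction(f, p)
        assert np.all(np.diff(L) > 0)


class TestFitHill:
    def test_noiseless_series_recovered_exactly(self, endpoints_37c):
        truth = fc.HillParams(200.0, 1.5, 0.0, 1.0)
        series = fc.synthetic.gen_calibration_series(
            truth, endpoints_37c, phasor_noise_sd=0.0, replicates=1, seed=0
        )
        res = fc.fit_hill(series, ends=endpoints_37c)
        assert res.params.Kd_nM == pytest.approx(200.0, rel=1e-6)
        assert res.params.hill_n == pytest.approx(1.5, rel=1e-6)
        assert res.residual_norm < 1e-7

    def test_noiseless_fit_residual_is_numerically_zero(self, endpoints_37c):
        truth = fc.HillParams(350.0, 1.2)
        series = fc.synthetic.gen_calibration_series(
            truth, endpoints_37c, phasor_noise_sd=0.0, replicates=2, seed=0
        )
        res = fc.fit_hill(series, ends=endpoints_37c, pin_extremes=True)
        assert res.residual_norm < 1e-10

    def test_underdetermined_series_rejected(self, endpoints_37c):
        import pandas as pd

        df = pd.DataFrame({
            "replicate": [0, 0, 0],
            "free_ca_nM": [0.0, 0.0, 100.0],
            "g": [0.6, 0.6, 0.7],
            "s": [0.45, 0.45, 0.40],
        })
        series = fc.CalibrationSeries(df)
        with pytest.raises(ValueError, match="underdetermined"):
            fc.fit_hill(series, ends=endpoints_37c)

    def test_ci_brackets_point_estimate(self, endpoints_37c, hill_37c):
        series = fc.synthetic.gen_calibration_series(
            hill_37c, endpoints_37c, phasor_noise_sd=0.003, seed=11
        )
        res = fc.fit_hill(series, ends=endpoints_37c)
        lo, hi = res.ci95["Kd_nM"]
        assert lo < res.params.Kd_nM < hi

    def test_parameter_recovery_across_seeds(self, endpoints_37c, hill_37c):
        """Median recovery error over seeded noisy simulations stays small."""
        kd_err, n_err = [], []
        for seed in range(30):
            series = fc.synthetic.gen_calibration_series(
                hill_37c, endpoints_37c, phasor_noise_sd=0.003, seed=seed
            )
            res = fc.fit_hill(series, ends=endpoints_37c)
            kd_err.append(abs(res.params.Kd_nM - hill_37c.Kd_nM) / hill_37c.Kd_nM)
            n_err.append(abs(res.params.hill_n - hill_37c.hill_n))
        assert np.median(kd_err) < 0.05
        assert np.median(n_err) < 0.1


class TestMeasurableRange:
    def _result(self, hill):
        ends = fc.synthetic.paper_like_endpoints("37C")
        return fc.CalibrationResult(hill, {}, ends, 0.0, True)

    def test_identical_replicates_degenerate(self):
        res = self._result(fc.HillParams(209.0, 1.53))
        (lo, hi), degen = fc.measurable_range(res, [0.1, 0.1, 0.1], [0.9, 0.9, 0.9])
        assert degen and lo == 0.0 and np.isinf(hi)

    def test_matches_brute_force_t_interval(self, rng):
        hill = fc.HillParams(209.0, 1.53)
        res = self._result(hill)
        low = 0.02 + 0.01 * rng.standard_normal(3)
        high = 0.97 + 0.01 * rng.standard_normal(3)
        (lo, hi), degen = fc.measurable_range(res, low, high)
        assert not degen
        # independent computation: mean +/- t * sd / sqrt(n) through the inverse
        tq = stats.t.ppf(0.975, 2)
        f_lo = low.mean() + tq * low.std(ddof=1) / np.sqrt(3)
        f_hi = high.mean() - tq * high.std(ddof=1) / np.sqrt(3)
        exp_lo = 209.0 * (f_lo / (1 - f_lo)) ** (1 / 1.53)
        exp_hi = 209.0 * (f_hi / (1 - f_hi)) ** (1 / 1.53)
        assert lo == pytest.approx(exp_lo, rel=1e-9)
        assert hi == pytest.approx(exp_hi, rel=1e-9)

    def test_wider_replicate_scatter_narrows_the_range(self):
        hill = fc.HillParams(209.0, 1.53)
        res = self._result(hill)
        widths = []
        for sd in (0.002, 0.01, 0.03, 0.06):
            low = np.array([0.03 - sd, 0.03, 0.03 + sd])
            high = np.array([0.97 - sd, 0.97, 0.97 + sd])
            (lo, hi), _ = fc.measurable_range(res, low, high)
            widths.append(np.log(hi) - np.log(lo))
        assert all(a > b for a, b in zip(widths, widths[1:]))

    def test_needs_two_replicates(self):
        res = self._result(fc.HillParams(209.0, 1.53))
        with pytest.raises(ValueError):
            fc.measurable_range(res, [0.1], [0.9, 0.91])


class TestConcentrationMap:
    def test_uniform_apo_image_maps_to_zero_with_below_flags(self, calib_37c):
        e = calib_37c.endpoints
        G = np.full((8, 8), e.phasor_min.G)
        S = np.full((8, 8), e.phasor_min.S)
        ca, flags = fc.phasor_image_to_ca_map(G, S, calib_37c)
        assert np.all(ca == 0.0) and np.all(flags == FLAG_BELOW)

    def test_image_at_kd_fraction_recovers_kd(self, calib_37c, rng):
        f_at_kd = fc.hill_fraction(209.0, calib_37c.params)
        g0, s0 = fc.mix_phasor(np.full((64, 64), f_at_kd), calib_37c.endpoints)
        noise = 0.003
        ca, flags = fc.phasor_image_to_ca_map(
            g0 + rng.normal(0, noise, g0.shape),
            s0 + rng.normal(0, noise, s0.shape),
            calib_37c,
        )
        assert np.median(ca) == pytest.approx(209.0, rel=0.05)

    def test_masked_pixel_is_nan_neighbors_unaffected(self, calib_37c):
        f = fc.hill_fraction(209.0, calib_37c.params)
        g0, s0 = fc.mix_phasor(np.full((4, 4), f), calib_37c.endpoints)
        mask = np.ones((4, 4), bool)
        mask[1, 2] = False
        ca, flags = fc.phasor_image_to_ca_map(g0, s0, calib_37c, mask=mask)
        assert np.isnan(ca[1, 2]) and flags[1, 2] == FLAG_MASKED
        assert np.isfinite(ca[0, 2]) and flags[0, 2] == FLAG_OK

    def test_pipeline_is_permutation_equivariant(self, calib_37c, rng):
        g = rng.uniform(0.55, 0.8, 100)
        s = rng.uniform(0.3, 0.5, 100)
        perm = rng.permutation(100)
        ca, flags = fc.phasor_image_to_ca_map(g, s, calib_37c)
        ca_p, flags_p = fc.phasor_image_to_ca_map(g[perm], s[perm], calib_37c)
        np.testing.assert_array_equal(ca[perm], ca_p)
        np.testing.assert_array_equal(flags[perm], flags_p)

    def test_shape_mismatch_rejected(self, calib_37c):
        with pytest.raises(ValueError, match="shape"):
            fc.phasor_image_to_ca_map(np.zeros((4, 4)), np.zeros((4, 5)), calib_37c)


class TestEndpointsFromTimelapse:
    def test_pure_apo_then_pure_sat_recovers_endpoints(self, calib_37c, rng):
        e = calib_37c.endpoints
        noise = 0.002
        shape = (40, 40)
        g = np.stack([
            np.full(shape, e.phasor_min.G), np.full(shape, e.phasor_min.G),
            np.full(shape, e.phasor_max.G),
        ]) + rng.normal(0, noise, (3, *shape))
        s = np.stack([
            np.full(shape, e.phasor_min.S), np.full(shape, e.phasor_min.S),
            np.full(shape, e.phasor_max.S),
        ]) + rng.normal(0, noise, (3, *shape))
        est = fc.estimate_extremes_from_timelapse(g, s, R=e.R, n_baseline=2)
        assert est.phasor_min.distance(e.phasor_min) < 3 * noise
        assert est.phasor_max.distance(e.phasor_max) < 3 * noise

    def test_recovered_endpoints_lie_near_the_mixing_line(self, calib_37c, rng):
        e = calib_37c.endpoints
        noise = 0.004
        shape = (32, 32)
        frames = [fc.mix_phasor(np.full(shape, f), e) for f in (0.05, 0.3, 0.98)]
        g = np.stack([fr[0] for fr in frames]) + rng.normal(0, noise, (3, *shape))
        s = np.stack([fr[1] for fr in frames]) + rng.normal(0, noise, (3, *shape))
        est = fc.estimate_extremes_from_timelapse(g, s, R=e.R)
        for p in (est.phasor_min, est.phasor_max):
            a = fc.project_line_fraction(p, e)
            foot = fc.PhasorPoint(e.phasor_min.G + a * e.dG_max,
                                  e.phasor_min.S + a * e.dS_max)
            assert p.distance(foot) < 2 * noise

    def test_constant_timelapse_is_degenerate(self):
        g = np.full((3, 10, 10), 0.65)
        s = np.full((3, 10, 10), 0.42)
        with pytest.raises(ValueError, match="degenerate"):
            fc.estimate_extremes_from_timelapse(g, s, R=0.836)

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError, match="2 frames"):
            fc.estimate_extremes_from_timelapse(
                np.zeros((1, 4, 4)), np.zeros((1, 4, 4)), R=0.836
            )
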