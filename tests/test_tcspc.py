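"""Time-domain decay model: density normalization, chi-squared fitting,
empirical-lifetime estimation, time-domain phasors, and foreground masking."""

import numpy as np
import pytest
from scipy.integrate import quad

import flimcal as fc
from flimcal.phasor import ModulationSettings
from flimcal.tcspc import ArrivalHistogram, DecayModel


def exact_histogram(model, t_max, n_bins, scale=1.0):
    """Noise-free histogram: density sampled at bin centers times bin width."""
    edges = np.linspace(0, t_max, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    counts = fc.decay_pdf(centers, model, t_max) * (t_max / n_bins) * scale
    return ArrivalHistogram(centers, counts)


class TestDecayPdf:
    def test_pure_uniform_is_flat(self):
        m = DecayModel(eps=1.0, f1=0.0, f2=0.0, tau1_ns=1.0, tau2_ns=1.0,
                       sigma_ns=0.1, mu_ns=1.0)
        t = np.linspace(0, 20, 50)
        np.testing.assert_allclose(fc.decay_pdf(t, m, 20.0), 1 / 20.0)

    def test_normalizes_over_the_window(self):
        m = DecayModel(eps=0.01, f1=0.59, f2=0.40, tau1_ns=1.0, tau2_ns=3.0,
                       sigma_ns=0.05, mu_ns=2.0)
        integral, _ = quad(lambda t: fc.decay_pdf(t, m, 50.0), 0, 50, limit=200)
        assert integral == pytest.approx(1.0, abs=1e-6)

    def test_narrow_irf_limit_recovers_pure_exponential(self):
        tau = 2.0
        m = DecayModel.mono(tau, sigma_ns=1e-6, mu_ns=0.0)
        t = np.linspace(0.01, 15, 400)
        np.testing.assert_allclose(
            fc.decay_pdf(t, m, 1e6), np.exp(-t / tau) / tau, atol=1e-6
        )

    def test_stable_at_large_sigma_over_tau(self):
        # sigma/tau = 10 must not overflow or go negative
        m = DecayModel.mono(0.05, sigma_ns=0.5, mu_ns=5.0)
        p = fc.decay_pdf(np.linspace(0, 25, 2500), m, 25.0)
        assert np.all(np.isfinite(p)) and np.all(p >= 0)

    def test_zero_tau_with_weight_rejected(self):
        with pytest.raises(ValueError):
            DecayModel(eps=0.0, f1=1.0, f2=0.0, tau1_ns=0.0, tau2_ns=1.0,
                       sigma_ns=0.1, mu_ns=1.0)

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError):
            DecayModel(eps=0.1, f1=0.5, f2=0.5, tau1_ns=1.0, tau2_ns=2.0,
                       sigma_ns=0.1, mu_ns=1.0)


class TestFitDecay:
    def test_recovers_two_component_truth(self):
        truth = DecayModel(eps=0.01, f1=0.54, f2=0.45, tau1_ns=0.8, tau2_ns=3.2,
                           sigma_ns=0.1, mu_ns=1.0)
        hist = fc.synthetic.gen_tcspc_histogram(truth, 1_000_000, 25.0, 0.01, seed=7)
        model, diag = fc.fit_decay(hist)
        assert diag["converged"]
        assert model.tau1_ns == pytest.approx(truth.tau1_ns, rel=0.05)
        assert model.tau2_ns == pytest.approx(truth.tau2_ns, rel=0.05)
        assert model.eps == pytest.approx(truth.eps, abs=0.005)

    def test_pure_uniform_histogram_yields_eps_one(self):
        m = DecayModel(eps=1.0, f1=0.0, f2=0.0, tau1_ns=1.0, tau2_ns=1.0,
                       sigma_ns=0.1, mu_ns=1.0)
        hist = fc.synthetic.gen_tcspc_histogram(m, 50_000, 25.0, 0.05, seed=3)
        model, _ = fc.fit_decay(hist)
        assert model.eps > 0.98
        assert model.f1 + model.f2 < 0.02

    def test_mono_truth_under_two_component_model(self):
        truth = DecayModel.mono(2.0, sigma_ns=0.1, mu_ns=1.0, eps=0.005)
        hist = fc.synthetic.gen_tcspc_histogram(truth, 500_000, 25.0, 0.01, seed=5)
        model, _ = fc.fit_decay(hist)
        # the two recovered constants bracket (or equal) the single truth
        assert model.tau1_ns <= 2.0 * 1.02 and model.tau2_ns >= 2.0 * 0.98
        assert model.f1 + model.f2 == pytest.approx(truth.f1, abs=0.01)

    def test_too_few_photons_rejected(self):
        truth = DecayModel.mono(2.0, 0.1, 1.0)
        hist = fc.synthetic.gen_tcspc_histogram(truth, 500, 25.0, 0.05, seed=0)
        with pytest.raises(ValueError, match="photons"):
            fc.fit_decay(hist)

    def test_canonical_ordering(self):
        truth = DecayModel(eps=0.01, f1=0.3, f2=0.69, tau1_ns=0.7, tau2_ns=3.0,
                           sigma_ns=0.08, mu_ns=1.0)
        hist = fc.synthetic.gen_tcspc_histogram(truth, 200_000, 25.0, 0.02, seed=9)
        model, _ = fc.fit_decay(hist)
        assert model.tau1_ns <= model.tau2_ns


class TestEmpiricalLifetime:
    def test_pure_uniform_noise_gives_zero(self):
        m = DecayModel(eps=1.0, f1=0.0, f2=0.0, tau1_ns=1.0, tau2_ns=1.0,
                       sigma_ns=0.1, mu_ns=0.0)
        hist = exact_histogram(m, 20.0, 400)
        assert fc.empirical_lifetime(hist, m) == pytest.approx(0.0, abs=1e-9)

    def test_matches_truncated_exponential_closed_form(self):
        tau, t_max = 2.5, 25.0
        m = DecayModel.mono(tau, sigma_ns=0.05, mu_ns=1.0)
        hist = exact_histogram(m, t_max, 25_000)
        # window truncation pulls the mean below tau by
        # t_max * e^(-t_max/tau) / (1 - e^(-t_max/tau))
        q = np.exp(-t_max / tau)
        expected = tau - t_max * q / (1 - q)
        assert fc.empirical_lifetime(hist, m) == pytest.approx(expected, abs=1e-3)

    def test_long_window_limit_is_tau(self):
        tau = 0.5
        m = DecayModel.mono(tau, sigma_ns=0.01, mu_ns=0.2)
        hist = exact_histogram(m, 100 * tau, 100_000)
        assert fc.empirical_lifetime(hist, m) == pytest.approx(tau, abs=1e-6)

    def test_invariant_to_count_rescaling(self):
        m = DecayModel.mono(2.0, 0.05, 1.0, eps=0.01)
        h1 = exact_histogram(m, 25.0, 2500, scale=1.0)
        h2 = exact_histogram(m, 25.0, 2500, scale=7.3)
        assert fc.empirical_lifetime(h1, m) == pytest.approx(
            fc.empirical_lifetime(h2, m), abs=1e-12
        )

    def test_empty_histogram_rejected(self):
        hist = ArrivalHistogram(np.array([0.5, 1.5]), np.array([0, 0]))
        with pytest.raises(ValueError, match="empty"):
            fc.empirical_lifetime(hist, DecayModel.mono(2.0, 0.1, 1.0))


class TestIntensityWeightedLifetime:
    def test_hand_arithmetic_example(self):
        frames = fc.FrameSeries(np.array([1.0, 3.0]), np.array([2.0, 4.0]))
        assert fc.intensity_weighted_lifetime(frames) == pytest.approx(3.5)

    def test_equal_intensities_reduce_to_arithmetic_mean(self):
        frames = fc.FrameSeries(np.full(5, 2.0), np.array([1.0, 2.0, 3.0, 4.0, 5.0]))
        assert fc.intensity_weighted_lifetime(frames) == pytest.approx(3.0)

    def test_single_frame(self):
        frames = fc.FrameSeries(np.array([10.0]), np.array([2.7]))
        assert fc.intensity_weighted_lifetime(frames) == pytest.approx(2.7)

    def test_all_zero_intensities_rejected(self):
        frames = fc.FrameSeries(np.zeros(3), np.ones(3))
        with pytest.raises(ValueError):
            fc.intensity_weighted_lifetime(frames)


class TestPhasorFromHistogram:
    MOD = ModulationSettings(40.0)

    def test_delta_at_zero_time_gives_unit_phasor(self):
        centers = np.arange(0.005, 25.0, 0.01)
        counts = np.zeros(centers.size)
        i = 100
        counts[i] = 1000
        p = fc.phasor_from_histogram(ArrivalHistogram(centers, counts),
                                     self.MOD, zero_time_ns=centers[i])
        assert p.G == pytest.approx(1.0) and p.S == pytest.approx(0.0, abs=1e-12)

    def test_mono_exponential_matches_closed_form(self):
        tau = 2.5
        w = self.MOD.omega_rad_per_ns
        t_max = 100 * tau
        centers = np.arange(0.0005, t_max, 0.001)
        counts = np.exp(-centers / tau)
        p = fc.phasor_from_histogram(ArrivalHistogram(centers, counts), self.MOD)
        assert p.G == pytest.approx(1 / (1 + (w * tau) ** 2), abs=1e-4)
        assert p.S == pytest.approx(w * tau / (1 + (w * tau) ** 2), abs=1e-4)

    def test_uniform_over_full_period_vanishes(self):
        period = 2 * np.pi / self.MOD.omega_rad_per_ns
        centers = (np.arange(1000) + 0.5) * (period / 1000)
        p = fc.phasor_from_histogram(ArrivalHistogram(centers, np.ones(1000)), self.MOD)
        assert abs(p.G) < 1e-5 and abs(p.S) < 1e-5

    def test_linearity_of_mixtures(self):
        centers = np.arange(0.005, 50.0, 0.01)
        c1 = np.exp(-centers / 1.0)
        c2 = np.exp(-centers / 4.0)
        p1 = fc.phasor_from_histogram(ArrivalHistogram(centers, c1), self.MOD)
        p2 = fc.phasor_from_histogram(ArrivalHistogram(centers, c2), self.MOD)
        pm = fc.phasor_from_histogram(ArrivalHistogram(centers, c1 + c2), self.MOD)
        w1 = c1.sum() / (c1.sum() + c2.sum())
        assert pm.G == pytest.approx(w1 * p1.G + (1 - w1) * p2.G, abs=1e-9)
        assert pm.S == pytest.approx(w1 * p1.S + (1 - w1) * p2.S, abs=1e-9)


class TestForegroundMask:
    def test_separates_two_intensity_populations(self, rng):
        img = rng.uniform(5, 15, (40, 40))
        bright = np.zeros((40, 40), bool)
        bright[10:30, 5:25] = True
        img[bright] += 100
        mask, thr = fc.foreground_mask(img)
        np.testing.assert_array_equal(mask, bright)

    def test_all_zero_image_warns_and_masks_nothing(self):
        with pytest.warns(UserWarning, match="constant"):
            mask, _ = fc.foreground_mask(np.zeros((8, 8)))
        assert not mask.any()

    def test_quantile_method_invariant_to_monotone_rescaling(self, rng):
        img = rng.uniform(0, 5, (30, 30))
        m1, _ = fc.foreground_mask(img, method="quantile", quantile=0.7)
        m2, _ = fc.foreground_mask(np.expm1(img) * 3.0, method="quantile", quantile=0.7)
        np.testing.assert_array_equal(m1, m2)
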