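"""Correlator grid, noise model scaling laws, and measurement synthesis."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from layerdcs import (NoiseContext, ValidationError, add_noise, build_scheme,
                      bundle_detectors, decay_rate, g2_layered,
                      scale_intensity, sigma_g2, toy_exponential_curve)

from conftest import homogeneous_cw_oracle, homogeneous_head


class TestCorrelatorScheme:
    def test_default_grid(self, scheme):
        assert scheme.tau[0] == pytest.approx(2e-7)
        assert scheme.n_bins == 16 * 20 == len(scheme.tau)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(base=st.floats(1e-8, 1e-5), bins=st.integers(2, 32),
           stages=st.integers(1, 12))
    def test_multi_tau_structure(self, base, bins, stages):
        s = build_scheme(base, bins, stages)
        assert np.all(np.diff(s.tau) > 0)
        widths = s.bin_width.reshape(stages, bins)
        assert np.allclose(widths, widths[:, :1])
        # each stage doubles the accumulator width
        assert np.allclose(widths[:, 0], base * 2.0 ** np.arange(stages))
        assert np.all(s.bin_index >= 1.0 - 1e-12)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValidationError):
            build_scheme(base_bin_width=0.0)


class TestDecayRate:
    def test_recovers_single_exponential_rate(self, scheme):
        for gamma0 in (1e3, 1e4, 1e5):
            curve = toy_exponential_curve(gamma0, 0.5, scheme)
            assert decay_rate(curve, 0.5) == pytest.approx(gamma0, rel=0.01)
            assert decay_rate(curve, 0.5, method="ls_fit") == pytest.approx(
                gamma0, rel=1e-4)

    def test_doubling_flow_doubles_rate(self, scheme):
        """Homogeneous medium: Gamma is proportional to the flow index."""
        rates = []
        for bfi in (1e-8, 2e-8):
            g2 = g2_layered(homogeneous_head(bfi=bfi), 2.0, scheme.tau)
            rates.append(decay_rate(g2, 0.5))
        assert rates[1] / rates[0] == pytest.approx(2.0, rel=0.05)

    def test_faster_decay_at_larger_separation(self, median_head, scheme):
        g_near = decay_rate(g2_layered(median_head, 0.5, scheme.tau), 0.5)
        g_far = decay_rate(g2_layered(median_head, 2.5, scheme.tau), 0.5)
        assert g_far > g_near

    def test_error_when_curve_never_decays(self):
        short = build_scheme(n_stages=1)
        curve = toy_exponential_curve(1.0, 0.5, short)  # no decay in range
        with pytest.raises(ValidationError, match="extend"):
            decay_rate(curve, 0.5)


class TestSigmaModel:
    CTX = dict(intensity=20e3, avg_time=10.0, beta=0.5, gamma=1e4)

    def test_averaging_time_scaling_is_exact(self, scheme):
        """sigma scales as t^(-1/2): t=4 s equals t=1 s divided by 2."""
        s1 = sigma_g2(NoiseContext(**{**self.CTX, "avg_time": 1.0}), scheme)
        s4 = sigma_g2(NoiseContext(**{**self.CTX, "avg_time": 4.0}), scheme)
        assert np.array_equal(s4, s1 / 2.0)

    def test_positive_and_finite_everywhere(self, scheme):
        s = sigma_g2(NoiseContext(**self.CTX), scheme)
        assert np.all(s > 0) and np.all(np.isfinite(s))

    def test_shot_noise_vanishes_at_high_intensity(self, scheme):
        """<n> -> infinity leaves only the correlated-decay term."""
        ctx = NoiseContext(**{**self.CTX, "intensity": 1e9 / scheme.bin_width[0]})
        got = sigma_g2(ctx, scheme)
        gam, beta = self.CTX["gamma"], self.CTX["beta"]
        T, tau, m = scheme.bin_width, scheme.tau, scheme.bin_index
        e2t, e2tau = np.exp(-2 * gam * T), np.exp(-2 * gam * tau)
        want = np.sqrt(T / self.CTX["avg_time"]) * np.sqrt(
            beta ** 2 * ((1 + e2t) * (1 + e2tau) + 2 * m * (1 - e2t) * e2tau)
            / (1 - e2t))
        # the reference intensity fixes <n> = 1e9 only in the first stage;
        # compare there
        first = slice(0, 16)
        assert np.allclose(got[first], want[first], rtol=1e-6)


class TestAddNoiseAndBundling:
    def test_seeded_reproducibility(self, scheme, degen_sample):
        clean = g2_layered(degen_sample.head, 1.5, scheme.tau)
        sigma = np.full(scheme.n_bins, 0.01)
        a = add_noise(clean, sigma, seed=123)
        b = add_noise(clean, sigma, seed=123)
        c = add_noise(clean, sigma, seed=124)
        assert np.array_equal(a.values, b.values)
        assert not np.array_equal(a.values, c.values)

    def test_empirical_std_matches_sigma(self, scheme, degen_sample):
        clean = g2_layered(degen_sample.head, 1.5, scheme.tau)
        ctx = NoiseContext(intensity=2e4, avg_time=10.0, beta=0.5,
                           gamma=decay_rate(clean, 0.5))
        sigma = sigma_g2(ctx, scheme)
        reals = np.array([add_noise(clean, sigma, seed=(7, i)).values
                          for i in range(1000)])
        emp = reals.std(axis=0, ddof=1)
        assert np.max(np.abs(emp / sigma - 1.0)) < 0.15
        assert np.median(np.abs(emp / sigma - 1.0)) < 0.05
        # mean consistent with the clean curve (CLT bound, 3 sigma)
        dev = np.abs(reals.mean(axis=0) - clean.values)
        assert np.all(dev < 3.0 * sigma / math.sqrt(1000) + 1e-12)

    def test_bundle_identity_and_variance_reduction(self, scheme, degen_sample):
        clean = g2_layered(degen_sample.head, 2.5, scheme.tau)
        sigma = np.full(scheme.n_bins, 0.02)
        single = add_noise(clean, sigma, seed=0)
        assert np.array_equal(bundle_detectors([single]).values, single.values)
        bins = [5, 50, 150]
        singles, bundles = [], []
        for trial in range(500):
            reals = [add_noise(clean, sigma, seed=(trial, k)) for k in range(7)]
            singles.append(reals[0].values[bins])
            bundles.append(bundle_detectors(reals).values[bins])
        ratio = (np.std(bundles, axis=0, ddof=1)
                 / np.std(singles, axis=0, ddof=1))
        assert np.all(np.abs(ratio * math.sqrt(7) - 1.0) < 0.10)

    def test_bundle_rejects_mismatched_grids(self, scheme, degen_sample):
        a = g2_layered(degen_sample.head, 1.5, scheme.tau)
        b = g2_layered(degen_sample.head, 2.5, scheme.tau)
        with pytest.raises(ValidationError):
            bundle_detectors([a, b])


class TestIntensityScaling:
    def test_reference_is_exact(self, degen_sample):
        assert scale_intensity(degen_sample.head, 2.5) == 20e3

    def test_monotone_with_separation(self, degen_sample):
        assert scale_intensity(degen_sample.head, 0.5) > scale_intensity(degen_sample.head, 2.5)

    def test_homogeneous_ratio_matches_closed_form(self):
        head = homogeneous_head(mua=0.1, musp=10.0)
        got = scale_intensity(head, 1.0) / 20e3
        want = (homogeneous_cw_oracle(0.1, 10.0, 1.4, 1.0)
                / homogeneous_cw_oracle(0.1, 10.0, 1.4, 2.5))
        assert got == pytest.approx(want, rel=1e-3)
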