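"""Chi-squared cost, bounded inversion, and cost-map diagnostics."""

import numpy as np
import pytest

from layerdcs import (CorrelationCurve, FitConfig, NoiseContext, add_noise,
                      chi_squared, cost_map, decay_rate,
                      fit_flows, g2_layered, percent_error, sigma_g2, ValidationError)


@pytest.fixture(scope="module")
def worked_curves(degen_sample, scheme):
    return [g2_layered(degen_sample.head, r, scheme.tau) for r in degen_sample.sds]


class TestChiSquared:
    def test_self_consistency_is_exact(self, degen_sample, worked_curves):
        """Clean curves from the assumed head at the true flows cost zero."""
        chi2 = chi_squared(worked_curves, (degen_sample.sbfi_true, degen_sample.cbfi_true),
                           degen_sample.head)
        assert chi2 < 1e-12

    def test_additivity_over_curves(self, degen_sample, worked_curves):
        cand = (1e-8, 3e-8)
        total = chi_squared(worked_curves, cand, degen_sample.head)
        parts = [chi_squared([c], cand, degen_sample.head) for c in worked_curves]
        assert total == pytest.approx(sum(parts), rel=1e-12)

    def test_matches_naive_double_loop(self, degen_sample):
        """Brute-force residual summation oracle on a 5-bin toy curve."""
        tau = np.array([1e-6, 3e-6, 1e-5, 3e-5, 1e-4])
        obs = [CorrelationCurve(sds=r, tau=tau,
                                values=1.0 + 0.4 * np.exp(-tau / 2e-5),
                                kind="intensity") for r in (1.0, 2.0)]
        cand = (5e-9, 4e-8)
        want = 0.0
        model_head = degen_sample.head.with_flows([cand[0], 0.0, cand[1]])
        for curve in obs:
            model = g2_layered(model_head, curve.sds, curve.tau).values
            for k in range(len(tau)):
                want += (curve.values[k] - model[k]) ** 2
        got = chi_squared(obs, cand, degen_sample.head)
        assert got == pytest.approx(want, rel=1e-12)

    def test_rejects_field_curves(self, degen_sample, scheme):
        from layerdcs import g1_layered
        g1 = g1_layered(degen_sample.head, 1.5, scheme.tau)
        with pytest.raises(ValidationError):
            chi_squared([g1], (1e-8, 1e-8), degen_sample.head)


class TestPercentError:
    @pytest.mark.parametrize("est,truth,want", [
        (2.0e-8, 2.0e-8, 0.0),
        (2.5e-9, 2.0e-8, -87.5),       # published magnitude rounds to 88
        (2.2e-8, 5.2e-8, -57.692307),  # published value rounds to -58
    ])
    def test_signed_percentage(self, est, truth, want):
        assert percent_error(est, truth) == pytest.approx(want, abs=1e-6)

    def test_nonpositive_truth_rejected(self):
        with pytest.raises(ValidationError):
            percent_error(1e-8, 0.0)


class TestFitFlows:
    def test_init_at_truth_stays_at_truth(self, degen_sample, worked_curves):
        cfg = FitConfig(init=(degen_sample.sbfi_true, degen_sample.cbfi_true))
        res = fit_flows(worked_curves, degen_sample.head, cfg,
                        truth=(degen_sample.sbfi_true, degen_sample.cbfi_true))
        assert abs(res.percent_error_cbfi) < 0.1
        assert abs(res.percent_error_sbfi) < 0.1

    def test_chi2_never_exceeds_init_cost(self, degen_sample, worked_curves, scheme):
        ctx = NoiseContext(intensity=2e4, avg_time=10.0, beta=0.5,
                           gamma=decay_rate(worked_curves[1], 0.5))
        sigma = sigma_g2(ctx, scheme)
        noisy = [add_noise(c, sigma, seed=(9, i))
                 for i, c in enumerate(worked_curves)]
        cfg = FitConfig()
        res = fit_flows(noisy, degen_sample.head, cfg)
        chi2_init = chi_squared(noisy, cfg.init, degen_sample.head)
        assert res.chi2 <= chi2_init
        assert res.n_eval <= 2 * cfg.max_eval

    def test_bounds_respected_for_all_starts(self, degen_sample, worked_curves):
        cfg = FitConfig(multistart=4, seed=3)
        res = fit_flows([worked_curves[1]], degen_sample.head, cfg)
        lo, hi = cfg.bounds
        for sbfi, cbfi, _ in res.starts:
            assert lo <= sbfi <= hi
            assert lo <= cbfi <= hi

    def test_empty_observed_rejected(self, degen_sample):
        with pytest.raises(ValidationError):
            fit_flows([], degen_sample.head)


class TestCostMap:
    def test_argmin_consistent_with_fit(self, degen_sample, worked_curves):
        sbfi_grid = np.geomspace(2e-9, 2e-8, 7)
        cbfi_grid = np.geomspace(7e-9, 6e-8, 7)
        short = [CorrelationCurve(sds=c.sds, tau=c.tau[:140],
                                  values=c.values[:140], kind="intensity")
                 for c in worked_curves]
        cmap = cost_map(short, degen_sample.head, sbfi_grid, cbfi_grid)
        assert np.all(np.isfinite(cmap.chi2_surface))
        # truth lies on neither grid exactly; the argmin must be the nearest
        # grid node to the global minimum recovered by the optimizer
        res = fit_flows(worked_curves, degen_sample.head, FitConfig(),
                        truth=(degen_sample.sbfi_true, degen_sample.cbfi_true))
        i = np.argmin(np.abs(np.log(sbfi_grid) - np.log(res.sbfi_est)))
        j = np.argmin(np.abs(np.log(cbfi_grid) - np.log(res.cbfi_est)))
        assert cmap.argmin == (pytest.approx(sbfi_grid[i]),
                               pytest.approx(cbfi_grid[j]))

    def test_valley_shape_distinguishes_separation_choices(self, degen_sample, scheme):
        """Close separations leave a flat CBFi valley; a small+large pair
        confines the low-cost region near the truth.  The low-cost set is
        measured against the published contour-display floor for clean cost
        maps (log10 chi2 = -2.5), profiling the best SBFi at every CBFi."""
        from scipy.optimize import minimize_scalar

        tau = scheme.tau[:140]
        cbfi_grid = np.geomspace(2e-9, 2e-7, 17)   # 0.1x .. 10x truth
        floor = 10.0 ** -2.5
        spans = {}
        for config in ((0.5, 1.0), (1.0, 3.0)):
            curves = [g2_layered(degen_sample.head, r, tau) for r in config]
            profile = []
            for cbfi in cbfi_grid:
                best = minimize_scalar(
                    lambda ls: chi_squared(curves, (10 ** ls, cbfi), degen_sample.head),
                    bounds=(-11, -6), method="bounded",
                    options={"xatol": 1e-8})
                profile.append(best.fun)
            sel = cbfi_grid[np.asarray(profile) < floor]
            spans[config] = sel.max() / sel.min()
        assert spans[(0.5, 1.0)] > 10.0
        assert spans[(1.0, 3.0)] < 2.0

    def test_rejects_nonpositive_grids(self, degen_sample, worked_curves):
        with pytest.raises(ValidationError):
            cost_map(worked_curves, degen_sample.head, np.array([0.0, 1e-8]),
                     np.array([1e-8]))
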