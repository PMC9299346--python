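# layerdcs

Simulation and inversion toolkit for **diffuse correlation spectroscopy
(DCS)** measurements of cerebral blood flow through a layered head.

DCS infers microvascular blood flow from the temporal decorrelation of
multiply scattered coherent near-infrared light. Because light must cross
scalp and skull to reach the brain, single-layer analyses confound scalp
and cerebral hemodynamics. The three-layer head model (scalp / zero-flow
skull / brain) removes the extracerebral contribution by fitting a layered
solution of the correlation diffusion equation — but the resulting
two-parameter inverse problem is ill-conditioned, and its uniqueness,
noise robustness, and sensitivity to mis-assumed tissue properties all
depend strongly on the chosen source–detector separation(s) (SDS). This
package provides everything needed to study that dependence *in silico*:

- **`layerdcs.model`** — analytical N-layer correlation-diffusion forward
  model: normalized field autocorrelation g1(r, τ), intensity
  autocorrelation g2 = 1 + β·g1² (Siegert, β = 0.5), and CW reflectance,
  via a stable closed-form Hankel-space solution with an
  extrapolated-zero boundary.
- **`layerdcs.noise`** — multi-tau correlator timing grid and the
  single-exponential correlation noise model σ(τ; I, t, β, Γ, T, m);
  seeded noise synthesis, detector bundling, intensity scaling across
  separations (20 kHz reference at 2.5 cm).
- **`layerdcs.montecarlo`** — seeded photon transport on a three-layer
  slab recording per-layer pathlengths and momentum transfer, with
  absorption applied analytically so one run serves every flow
  combination; G1 from photon records with Brownian dynamics
  ⟨Δr²(τ)⟩ = 6Dτ.
- **`layerdcs.fitting`** — simultaneous scalp/cerebral blood-flow-index
  (SBFi/CBFi) estimation by bounded Nelder–Mead minimization of the
  unweighted χ² over separations and delay bins, bounds
  [1e−11, 1e−6] cm²/s, with multistart degeneracy diagnosis, percent
  errors, and cost maps.
- **`layerdcs.study`** — the full experiment designs: the 38,016-curve
  physiological grid, uniqueness / accuracy / MC-accuracy / sensitivity
  experiments, and 6×6 mean/std heatmap summaries over the SDS grid.
- **`layerdcs.fixtures`** — deterministic worked-example configurations
  and toy curves used by the tests and reproduction scripts.

## Worked example

Simulate clean g2 curves for a published three-layer sample
(μa = 0.1/0.1/0.15 cm⁻¹, μs′ = 10/10/4 cm⁻¹, L = 0.35/0.73 cm,
SBFi = 6.7e−9, CBFi = 2.0e−8 cm²/s) and fit them back:

```python
from layerdcs import FitConfig, build_scheme, nonuniqueness_sample, fit_flows, g2_layered

fx = nonuniqueness_sample()
scheme = build_scheme()                      # multi-tau grid, tau_1 = 200 ns
curves = [g2_layered(fx.head, r, scheme.tau) for r in (1.5, 3.0)]

res = fit_flows(curves, fx.head, FitConfig(), truth=(fx.sbfi_true, fx.cbfi_true))
print(f"SBFi={res.sbfi_est:.3e}  CBFi={res.cbfi_est:.3e}  "
      f"err={res.percent_error_cbfi:+.3f}%")
# SBFi=6.700e-09  CBFi=2.000e-08  err=-0.000%

single = fit_flows([curves[1]], fx.head, FitConfig(multistart=5, seed=1))
for sbfi, cbfi, chi2 in single.starts:
    print(f"SBFi={sbfi:.3e}  CBFi={cbfi:.3e}  chi2={chi2:.2e}")
# SBFi=6.700e-09  CBFi=2.000e-08  chi2=3.54e-18
# ...
# SBFi=1.028e-08  CBFi=4.760e-10  chi2=8.34e-06
```

Fitting both separations recovers the true flow indices exactly (CBFi
error −0.000%). Fitting the 3.0 cm curve alone finds, from some starts, a
*degenerate* solution whose CBFi is off by −98% yet whose curve differs
from the data by an RMS of only 2.8e−4 per bin (0.06% of the g2
amplitude): with one separation the solution is not unique, which is why
two separations are required in practice.

A thin CLI wraps the same library calls:

```bash
layerdcs fixtures --out out/                      # worked-example curve CSVs
layerdcs simulate --head head.txt --sds 1.0 --sds 2.5 --out curves.csv
layerdcs study accuracy --seed 0 --samples 50 --noise-seeds 3 --out out/
layerdcs study uniqueness --full --out out/       # full 6336-sample grid (hours)
```

## Reproduction script

`scripts/acceptance.py` recomputes the published worked-example numbers
from scratch — the clean dual-SDS CBFi percent error for the printed
sample, and the CBFi/SBFi percent errors when the analytical model is fit
to layered-slab Monte Carlo curves at 0.5 + 1.0 cm (median optics,
≥1e5 detected photons at each fitted detector):

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The Monte Carlo leg launches several million photons and takes ~15 min on
one core. See `docs/methods.md` for the models, numerical tolerances, and
the reduced-design sizes used in the tests.
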