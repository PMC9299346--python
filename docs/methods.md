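# Methods

`layerdcs` simulates and inverts continuous-wave diffuse correlation
spectroscopy (DCS) measurements on a layered head. This note documents the
models, the numerical choices, what the synthetic data do and do not
emulate, and the known limitations.

## Forward model: correlation diffusion in a layered medium

The measured quantity in DCS is the normalized intensity autocorrelation
g2(r, τ) of multiply scattered coherent light at source–detector separation
r. It relates to the electric-field autocorrelation through the Siegert
relation g2 = 1 + β|g1|², with the coherence factor β fixed at 0.5
throughout (single-mode fiber detection with two polarization states).

G1(r, τ) obeys a correlation diffusion equation: a photon-diffusion
equation in which dynamic scattering adds a delay-dependent effective
absorption. For Brownian motion of scatterers with effective diffusion
coefficient D_i (the blood flow index, cm²/s), the mean-square displacement
is ⟨Δr²(τ)⟩ = 6 D_i τ and

    μa_eff,i(τ) = μa_i + 2 μs′_i k0_i² D_i τ,        k0_i = 2π n_i / λ.

The head is a stack of plane-parallel layers (scalp, skull, brain in the
three-layer configuration; the implementation is N-layer generic and a
single layer reproduces the semi-infinite medium). After a zeroth-order
Hankel transform over the radial coordinate, the depth equation is solved
in closed form: the semi-infinite substrate contributes a boundary
admittance Γ_N = D_N^p α_N that is propagated upward through each finite
layer with the tanh-form recursion

    Γ_i = b_i (b_i tanh(α_i l_i) + Γ_{i+1}) / (b_i + Γ_{i+1} tanh(α_i l_i)),

where α_i² = 3 μs′_i μa_eff,i(τ) + s², b_i = D_i^p α_i, and
D_i^p = 1/(3 μs′_i) is the photon diffusion coefficient. The top layer
carries an isotropic point source at z0 = 1/(μs′_1 + μa_1) and an
extrapolated-zero boundary at −z_b, z_b = 2 D_1^p (1+R_eff)/(1−R_eff), with
R_eff computed from hemispheric moments of the unpolarized Fresnel
reflectance (R_eff ≈ 0.493 for n = 1.4 against air). The surface fluence in
Hankel space then has a closed form in which every exponential has a
negative argument, so the expression is numerically stable at arbitrary
spatial frequency. During development this closed form was verified to
machine precision against a brute-force linear-system solution of the
layered depth problem.

The detected quantity is taken proportional to the surface fluence; g1 is
G1(τ)/G1(0), and the CW reflectance used for intensity scaling is G1(0).

**Wavelength.** The operating wavelength is a free parameter; the default
is λ = 785 nm, the most common CW-DCS wavelength. Flow indices always
appear in the product k0² D τ, so a different assumed wavelength rescales
the recovered flow indices but leaves percent errors against a same-model
truth unchanged.

### Inverse Hankel transform

G1(r) = (1/2π) ∫ Φ(s) J0(sr) s ds is evaluated with composite
Gauss–Legendre panels of width min(π/r, 2) cm⁻¹ (resolving both the Bessel
oscillation and the envelope scale set by the source depth), refined by
node doubling to a relative tolerance of 1e−8 and truncated when the τ=0
envelope falls below 1e−12 of its peak. Once the envelope has fallen below
1e−8 of its peak the panels widen 4×: that tail contributes < 1e−8 of the
integral and no longer needs the oscillation resolved. The node/weight grid
depends only on the static optics, so it is cached and reused across all
delay times and candidate flow indices of a fit.

Accuracy against the closed-form homogeneous solution is ≤ 1e−5 relative
wherever g1 > 1e−6. Below g1 ≈ 1e−7 the oscillatory integral is evaluated
by cancellation of ~12 significant digits and the relative error grows;
comparisons in the tests are therefore restricted to g1 above 1e−6, which
is far below any measurable correlation signal.

## Correlator and noise model

The timing grid is a generic multi-tau scheme: stage k holds
`bins_per_stage` accumulators of width `base_bin_width`·2^k (defaults 16
and 200 ns over 20 stages), standing in for the vendor correlator whose
exact register layout is not public. The per-bin standard deviation of g2
follows the classic single-exponential correlation-noise model,

    σ(τ_m) = √(T_m/t) [ β²((1+e^{−2ΓT_m})(1+e^{−2Γτ_m})
              + 2m(1−e^{−2ΓT_m})e^{−2Γτ_m})/(1−e^{−2ΓT_m})
              + 2⟨n⟩⁻¹β(1+e^{−2Γτ_m}) + ⟨n⟩⁻²(1+βe^{−Γτ_m}) ]^{1/2},

with T_m the bin width, m = τ_m/T_m the channel index, ⟨n⟩ = I·T_m the
photons per bin, t the averaging time, and Γ the field decay rate of the
curve being corrupted. Γ is estimated parameter-free as the reciprocal of
the (log-interpolated) delay where √((g2−1)/β) crosses 1/e. Noise is added
as independent zero-mean Gaussians per bin; inter-bin covariance, dead
time, afterpulsing, and dark counts of real correlators are not modeled.
Detected intensity is 20 kHz at 2.5 cm and scales across separations with
the CW reflectance ratio. An 8-detector budget is emulated: either all
eight at one separation or 1 + 7 across a pair, with co-located detectors
averaged (noise std shrinks by √k, which the tests verify empirically).

## Slab Monte Carlo

Photons are transported through the same layer stack with scattering-only
sampling (step lengths from μs_i = μs′_i/(1−g), Henyey–Greenstein phase
function with g = 0.89), Fresnel reflection at the tissue–air surface
(n = 1.4 vs 1.0), index-matched internal interfaces, and termination on
escape or at the lateral/depth bounds (10 cm, emulating a 20 cm sample
cube). Absorption is never sampled: each detected photon records its
per-layer pathlength L_i and momentum transfer Y_i = Σ(1−cosθ), and the
field autocorrelation is evaluated analytically,

    G1(τ) = (1/Np) Σ_n exp(−2 Σ_i Y_ni k0_i² D_i τ) · exp(−Σ_i μa_i L_ni),

so one transport run serves every flow combination and any absorption
perturbation. Detection uses annular rings (default half-width 0.5 mm)
around each nominal separation: for a pencil beam the geometry is
azimuthally symmetric, so the annulus is statistically equivalent to the
discrete small detectors it replaces while detecting far more photons.
Runs are seeded and chunked; records persist to HDF5.

The MC g2 decays measurably *later* than the layered diffusion solution at
all separations (half-decay ratios ~1.01–1.08 at desk-scale statistics):
the transport-versus-diffusion discrepancy that drives the small-separation
bias of the analytical inversion.

## Inversion

χ² is the unweighted sum of squared g2 residuals over all fitted
separations and included delay bins. Delay bins enter the cost up to the
last bin where the nominal clean model satisfies g2 − 1 > 1e−3·β at the
largest fitted separation (later bins are statistically flat; configurable
to all bins). The two flow indices are optimized in log10 space, mapped
into the bounds [1e−11, 1e−6] cm²/s by a sinusoidal transform, with
Nelder–Mead (cost tolerance 1e−12, simplex tolerance 1e−8 in the
transformed coordinates ≈ 1e−7 relative on the flows, at most 2000
evaluations). Initialization defaults to (1e−8, 1e−8) cm²/s; optional
multistart draws log-uniform starts over the bounds and retains every
solution for degeneracy diagnosis. Inside the optimizer loop the model is
evaluated on a coarse internal log-τ grid (12 points/decade) and
cubic-splined onto the correlator bins; the resulting ~1e−5 interpolation
error shifts the minimum by < 1e−4 relative, and the reported χ² is always
recomputed with the exact model. `chi_squared` itself always evaluates
exactly, so clean self-consistency (χ² = 0 at the generating flows) holds
bitwise.

**Degeneracy phenomenology.** With a single separation the cost surface has
a long, nearly flat valley trading SBFi against CBFi: multistart fitting of
a clean 3.0 cm curve returns solutions with |CBFi error| near 100% whose
per-bin RMS residual is ~3e−4 — 0.06% of the g2 amplitude, far below any
achievable measurement noise. "Near-zero cost" is therefore operationalized
in the tests as per-bin RMS < 1e−3·β, the same indistinguishability scale
the τ-inclusion rule uses. Where such a valley meets systematically shifted
data (the MC curves at small separations), its minimum can sit at the
parameter bound: the fit of MC data at (0.5, 1.0) cm recovers SBFi within a
few percent but drives CBFi to the lower bound (error ≈ −100%), a stronger
version of the large published underestimate; a profile scan of χ²(CBFi)
shows the cost decreasing monotonically toward zero flow with a total
variation of only ~3×, so the precise stopping point inside this valley is
an artifact of optimizer tolerances, not a property of the data.

## Study designs and reduced modes

The full design enumerates 8 head parameters × 11 values (others at their
median; the repeated all-median head is kept, matching the printed
38,016-curve arithmetic) × 12 CBFi ∈ [2e−8, 9e−8] cm²/s × 6 SBFi/CBFi
ratios evenly spaced in [1/8, 1/3] × 6 separations. Separation
configurations are the 6 singles plus the 30 ordered pairs (collapsible to
15 unordered pairs for heatmap triangles). Noise sub-seeds derive from a
`SeedSequence` keyed on (sample, configuration, averaging time, repeat,
detector), making every experiment reproducible from one master seed and
resumable from keyed CSV storage.

The full all-configuration, all-averaging-time study is hours of compute
and sits behind explicit flags (`--full`); tests and the acceptance
reproduction use documented reduced designs: subsampled sample grids, the
median-head 72-flow grid, three representative configurations for the
averaging-time trend, and Monte Carlo photon budgets of 1e6–6e6 launched
photons (≥1e5 detected at the fitted 0.5/1.0 cm detectors; a 1e5-photon
requirement at 3.0 cm would need ~1e8 launches and is out of desk scale).
A green reduced-design test establishes the direction and ordering of
effects at the stated sizes, not the exact magnitudes of the full design.

## Known limitations

- Plane-parallel layers only: no curvature, no CSF layer, no lateral
  heterogeneity.
- Gaussian, inter-bin-independent noise; real multi-tau correlators have
  correlated bins.
- The diffusion forward model uses the surface fluence as the detected
  quantity; alternative partial-current conventions would change the
  MC-versus-analytical mismatch in detail (not in sign).
- β is fixed and known; fitting β or the optical properties is out of
  scope.
- The published degenerate-fit coordinates at a single separation (and the
  interior stall point of the flat MC valley) depend on unprinted
  implementation details of the original study and are reproduced as
  phenomena, not as exact numbers.
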