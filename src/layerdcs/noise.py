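"""Multi-tau correlator grid, g2 noise model, and measurement synthesis.

The measurement chain emulated here is a continuous-wave DCS system with a
hardware multi-tau correlator: delay bins widen geometrically stage by
stage, and the statistical error of each g2 bin follows the classic
single-exponential shot-noise model parameterized by the detected photon
rate, the averaging time, the coherence factor beta, and the curve decay
rate Gamma.  Noise realizations are additive, Gaussian, independent across
bins, and fully seeded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model import (CorrelationCurve, HeadModel, ValidationError,
                    cw_reflectance)

__all__ = [
    "CorrelatorScheme", "NoiseContext", "build_scheme", "decay_rate",
    "sigma_g2", "add_noise", "scale_intensity", "bundle_detectors",
]


@dataclass(frozen=True)
class CorrelatorScheme:
    """Multi-tau correlator timing grid.

    ``base_bin_width`` is the sampling time of stage 0; each later stage
    doubles the bin width.  ``tau`` holds the delay of every bin,
    ``bin_width`` its accumulator width, and ``bin_index`` the dimensionless
    channel index m = tau / T entering the noise model.
    """

    base_bin_width: float = 200e-9
    bins_per_stage: int = 16
    n_stages: int = 20
    tau: np.ndarray = field(init=False, repr=False, compare=False)
    bin_width: np.ndarray = field(init=False, repr=False, compare=False)
    bin_index: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.base_bin_width <= 0:
            raise ValidationError("base_bin_width must be positive")
        if self.bins_per_stage < 1 or self.n_stages < 1:
            raise ValidationError("bins_per_stage and n_stages must be >= 1")
        widths = np.repeat(self.base_bin_width * 2.0 ** np.arange(self.n_stages),
                           self.bins_per_stage)
        tau = np.cumsum(widths)
        object.__setattr__(self, "tau", tau)
        object.__setattr__(self, "bin_width", widths)
        object.__setattr__(self, "bin_index", tau / widths)

    @property
    def n_bins(self) -> int:
        return self.bins_per_stage * self.n_stages


def build_scheme(base_bin_width: float = 200e-9, bins_per_stage: int = 16,
                 n_stages: int = 20) -> CorrelatorScheme:
    """Construct the multi-tau timing grid (defaults: 200 ns, 16 x 20)."""
    return CorrelatorScheme(base_bin_width=base_bin_width,
                            bins_per_stage=bins_per_stage, n_stages=n_stages)


@dataclass(frozen=True)
class NoiseContext:
    """Inputs of the g2 noise model for one detector at one separation."""

    intensity: float          # detected photon rate I, photons/s
    avg_time: float           # total averaging time t, s
    beta: float = 0.5         # coherence factor
    gamma: float = 0.0        # field decay rate Gamma, s^-1

    def __post_init__(self) -> None:
        if self.intensity <= 0:
            raise ValidationError("intensity must be positive")
        if self.avg_time <= 0:
            raise ValidationError("avg_time must be positive")
        if not 0.0 < self.beta <= 1.0:
            raise ValidationError("beta must be in (0, 1]")
        if self.gamma <= 0:
            raise ValidationError("gamma must be positive")


def decay_rate(clean_g2: CorrelationCurve, beta: float,
               method: str = "one_over_e") -> float:
    """Decay rate Gamma of a clean g2 curve, s^-1.

    The default (parameter-free) estimator is 1/tau_e where tau_e is the
    (log-interpolated) delay at which the normalized field correlation
    sqrt((g2 - 1)/beta) falls to 1/e.  ``method="ls_fit"`` instead
    least-squares fits a single exponential exp(-Gamma tau) to the field
    correlation over the decaying bins.
    """
    if clean_g2.kind != "intensity":
        raise ValidationError("decay_rate expects an intensity (g2) curve")
    g1 = np.sqrt(np.clip((clean_g2.values - 1.0) / beta, 0.0, None))
    if method == "ls_fit":
        from scipy.optimize import curve_fit

        keep = g1 > 0.01
        if keep.sum() < 3:
            raise ValidationError("too few decaying bins for a LS fit")
        guess = decay_rate(clean_g2, beta, method="one_over_e")
        popt, _ = curve_fit(lambda t, g: np.exp(-g * t),
                            clean_g2.tau[keep], g1[keep], p0=[guess])
        return float(popt[0])
    if method != "one_over_e":
        raise ValidationError(f"unknown decay_rate method {method!r}")
    target = math.exp(-1.0)
    below = np.nonzero(g1 <= target)[0]
    if below.size == 0:
        raise ValidationError(
            "g2 never decays below 1/e within the tau grid; extend the "
            "correlator range to cover the full decay")
    j = below[0]
    if j == 0:
        return 1.0 / clean_g2.tau[0]
    # interpolate log(tau) against g1 across the crossing
    t0, t1 = clean_g2.tau[j - 1], clean_g2.tau[j]
    f0, f1 = g1[j - 1], g1[j]
    w = (f0 - target) / (f0 - f1)
    tau_e = math.exp((1.0 - w) * math.log(t0) + w * math.log(t1))
    return 1.0 / tau_e


def sigma_g2(ctx: NoiseContext, scheme: CorrelatorScheme) -> np.ndarray:
    """Per-bin standard deviation sigma(tau) of the measured g2.

    Single-exponential correlation noise model: with T the bin width, m the
    channel index, <n> = I*T the photons per bin, t the averaging time,

        sigma(tau) = sqrt(T/t) * [ beta^2 ((1+e^{-2 G T})(1+e^{-2 G tau})
                      + 2 m (1-e^{-2 G T}) e^{-2 G tau}) / (1-e^{-2 G T})
                      + 2 <n>^-1 beta (1+e^{-2 G tau})
                      + <n>^-2 (1+beta e^{-G tau}) ]^{1/2}
    """
    tau = scheme.tau
    big_t = scheme.bin_width
    m = scheme.bin_index
    gam = ctx.gamma
    beta = ctx.beta
    n_mean = ctx.intensity * big_t

    e2t = np.exp(-2.0 * gam * big_t)
    e2tau = np.exp(-2.0 * gam * tau)
    etau = np.exp(-gam * tau)
    correlated = beta ** 2 * ((1.0 + e2t) * (1.0 + e2tau)
                              + 2.0 * m * (1.0 - e2t) * e2tau) / (1.0 - e2t)
    shot1 = 2.0 * beta * (1.0 + e2tau) / n_mean
    shot2 = (1.0 + beta * etau) / n_mean ** 2
    return np.sqrt(big_t / ctx.avg_time) * np.sqrt(correlated + shot1 + shot2)


def add_noise(clean: CorrelationCurve, sigma: np.ndarray,
              seed) -> CorrelationCurve:
    """Add independent zero-mean Gaussian noise of std sigma(tau) per bin.

    ``seed`` may be an int or a ``numpy.random.SeedSequence``-compatible
    object; identical seeds give identical realizations.
    """
    sigma = np.asarray(sigma, dtype=float)
    if sigma.shape != clean.tau.shape:
        raise ValidationError("sigma must be aligned with the curve bins")
    rng = np.random.default_rng(seed)
    noisy = clean.values + rng.normal(0.0, 1.0, size=sigma.shape) * sigma
    return CorrelationCurve(sds=clean.sds, tau=clean.tau, values=noisy,
                            kind=clean.kind, sigma=sigma,
                            intensity=clean.intensity)


def scale_intensity(head: HeadModel, sds: float,
                    reference: tuple[float, float] = (2.5, 20e3)) -> float:
    """Detected photon rate at ``sds`` scaled from a reference separation.

    The reference (default 20 kHz at 2.5 cm) is scaled by the ratio of CW
    reflectances (unnormalized field correlation at zero delay), so larger
    separations detect proportionally fewer photons.
    """
    ref_sds, ref_rate = reference
    if sds == ref_sds:
        return float(ref_rate)
    return float(ref_rate) * cw_reflectance(head, sds) / cw_reflectance(head, ref_sds)


def bundle_detectors(noisy_curves: list[CorrelationCurve]) -> CorrelationCurve:
    """Average k independent detector curves recorded at the same separation.

    The pointwise mean of k realizations carries an effective noise std of
    sigma/sqrt(k).
    """
    if not noisy_curves:
        raise ValidationError("bundle_detectors needs at least one curve")
    first = noisy_curves[0]
    for c in noisy_curves[1:]:
        if c.sds != first.sds or not np.array_equal(c.tau, first.tau):
            raise ValidationError("bundled curves must share sds and tau grid")
    k = len(noisy_curves)
    mean = np.mean([c.values for c in noisy_curves], axis=0)
    sigma = None
    if first.sigma is not None:
        sigma = first.sigma / math.sqrt(k)
    return CorrelationCurve(sds=first.sds, tau=first.tau, values=mean,
                            kind=first.kind, sigma=sigma,
                            intensity=first.intensity)
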