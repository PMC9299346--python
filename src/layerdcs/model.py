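"""Analytical layered forward model for diffuse correlation spectroscopy.

Solves the correlation diffusion equation (CDE) for a stack of plane-parallel
tissue layers on a semi-infinite substrate and returns the normalized
electric-field autocorrelation function g1(r, tau), its Siegert-related
intensity autocorrelation g2(r, tau), and the CW reflectance used for
intensity scaling across source-detector separations.

All lengths are in cm, times in s, and blood flow indices (effective Brownian
diffusion coefficients of the moving scatterers) in cm^2/s.

Model
-----
In each layer the field autocorrelation G1 obeys a modified Helmholtz
equation with a delay-dependent effective absorption

    mua_eff_i(tau) = mua_i + 2 * musp_i * k0_i^2 * D_i * tau,

where D_i is the layer blood flow index and the mean-square displacement of
moving scatterers is Brownian, <dr^2(tau)> = 6 * D_i * tau.  After a Hankel
transform over the radial coordinate the depth equation is one-dimensional
and is solved in closed form with a bottom-up admittance recursion:

    Gamma_N = Dp_N * alpha_N                       (semi-infinite substrate)
    Gamma_i = b_i (b_i t_i + Gamma_{i+1}) / (b_i + Gamma_{i+1} t_i),
              b_i = Dp_i * alpha_i,  t_i = tanh(alpha_i * l_i),

with alpha_i^2 = 3 * musp_i * mua_eff_i + s^2 and photon diffusion
coefficient Dp_i = 1/(3 musp_i).  The top layer carries an isotropic point
source at depth z0 = 1/(musp_1 + mua_1) and an extrapolated-zero boundary at
-zb; the surface fluence in Hankel space then has the closed, overflow-free
form implemented in :func:`_phi_surface`.  The inverse Hankel transform is
evaluated with adaptive Gauss-Legendre panels refined to a relative
tolerance of 1e-8 and truncated when the integrand envelope falls below
1e-12 of its peak.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Sequence

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.integrate import quad
from scipy.special import j0


class ValidationError(ValueError):
    """Raised when domain objects violate their physical invariants."""


class QuadratureError(RuntimeError):
    """Raised when the inverse Hankel transform fails to converge."""


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TissueLayer:
    """One tissue layer of a layered head model.

    Parameters
    ----------
    mua : float
        Absorption coefficient, cm^-1.
    musp : float
        Reduced scattering coefficient, cm^-1.
    thickness : float
        Layer thickness, cm.  ``math.inf`` marks the terminal
        (semi-infinite) layer.
    bfi : float
        Blood flow index: effective Brownian diffusion coefficient of the
        moving scatterers, cm^2/s.
    refractive_index : float
        Refractive index n (dimensionless).
    anisotropy : float
        Scattering anisotropy g (dimensionless); used only by the Monte
        Carlo transport, not by the diffusion solution.
    """

    mua: float
    musp: float
    thickness: float = math.inf
    bfi: float = 0.0
    refractive_index: float = 1.4
    anisotropy: float = 0.89

    def __post_init__(self) -> None:
        if not self.mua > 0:
            raise ValidationError(f"mua must be > 0, got {self.mua}")
        if not self.musp > 0:
            raise ValidationError(f"musp must be > 0, got {self.musp}")
        if not self.thickness > 0:
            raise ValidationError(f"thickness must be > 0, got {self.thickness}")
        if self.bfi < 0:
            raise ValidationError(f"bfi must be >= 0, got {self.bfi}")
        if not 0.0 <= self.anisotropy < 1.0:
            raise ValidationError(f"anisotropy must be in [0, 1), got {self.anisotropy}")
        if self.refractive_index <= 0:
            raise ValidationError("refractive_index must be positive")


@dataclass(frozen=True)
class HeadModel:
    """Ordered stack of tissue layers, surface first.

    The terminal layer is semi-infinite (``thickness == inf``).  The standard
    configuration is three layers: scalp, skull (zero flow), brain.
    ``wavelength_nm`` sets the in-medium wavenumber k0_i = 2 pi n_i / lambda.
    """

    layers: tuple[TissueLayer, ...]
    wavelength_nm: float = 785.0

    def __post_init__(self) -> None:
        if len(self.layers) < 1:
            raise ValidationError("HeadModel needs at least one layer")
        for lay in self.layers[:-1]:
            if not math.isfinite(lay.thickness):
                raise ValidationError("only the terminal layer may be semi-infinite")
        if not math.isfinite(self.layers[-1].thickness):
            pass
        else:
            raise ValidationError("terminal layer must have thickness == inf")
        if not self.wavelength_nm > 0:
            raise ValidationError("wavelength_nm must be positive")

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    @property
    def k0(self) -> np.ndarray:
        """Per-layer wavenumber in the medium, cm^-1 (2 pi n / lambda)."""
        lam_cm = self.wavelength_nm * 1e-7
        return np.array([2.0 * math.pi * lay.refractive_index / lam_cm
                         for lay in self.layers])

    def with_flows(self, bfi: Sequence[float]) -> "HeadModel":
        """Return a copy with per-layer blood flow indices replaced."""
        if len(bfi) != self.n_layers:
            raise ValidationError("bfi length must match layer count")
        new = tuple(replace(lay, bfi=float(b)) for lay, b in zip(self.layers, bfi))
        return replace(self, layers=new)

    @classmethod
    def three_layer(cls, mua, musp, thickness, bfi,
                    refractive_index: float = 1.4, anisotropy: float = 0.89,
                    wavelength_nm: float = 785.0) -> "HeadModel":
        """Build a scalp/skull/brain model from per-layer sequences.

        ``thickness`` gives (scalp, skull); the brain is semi-infinite.
        """
        th = (float(thickness[0]), float(thickness[1]), math.inf)
        layers = tuple(
            TissueLayer(mua=float(mua[i]), musp=float(musp[i]), thickness=th[i],
                        bfi=float(bfi[i]), refractive_index=refractive_index,
                        anisotropy=anisotropy)
            for i in range(3)
        )
        return cls(layers=layers, wavelength_nm=wavelength_nm)

    # -- structured-text serialization (round-trips bit-exact via repr) ----

    def to_text(self) -> str:
        lines = [f"wavelength_nm = {self.wavelength_nm!r}"]
        for i, lay in enumerate(self.layers, start=1):
            lines.append(f"[layer{i}]")
            lines.append(f"mua = {lay.mua!r}")
            lines.append(f"musp = {lay.musp!r}")
            lines.append(f"thickness = {lay.thickness!r}")
            lines.append(f"bfi = {lay.bfi!r}")
            lines.append(f"refractive_index = {lay.refractive_index!r}")
            lines.append(f"anisotropy = {lay.anisotropy!r}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "HeadModel":
        wavelength = 785.0
        sections: list[dict] = []
        current: dict | None = None
        for raw in text.splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("[") and line.endswith("]"):
                current = {}
                sections.append(current)
                continue
            key, _, val = line.partition("=")
            key = key.strip()
            val = float(val.strip())
            if current is None:
                if key == "wavelength_nm":
                    wavelength = val
            else:
                current[key] = val
        layers = tuple(TissueLayer(**sec) for sec in sections)
        return cls(layers=layers, wavelength_nm=wavelength)


@dataclass
class CorrelationCurve:
    """An autocorrelation curve at one source-detector separation.

    ``kind`` is ``"field"`` for g1 and ``"intensity"`` for g2.  ``sigma``
    optionally carries the per-bin noise standard deviation and
    ``intensity`` the detected photon rate in photons/s.
    """

    sds: float
    tau: np.ndarray
    values: np.ndarray
    kind: str
    sigma: np.ndarray | None = None
    intensity: float | None = None

    def __post_init__(self) -> None:
        self.tau = np.asarray(self.tau, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in ("field", "intensity"):
            raise ValidationError(f"kind must be 'field' or 'intensity', got {self.kind!r}")
        if self.tau.ndim != 1 or self.tau.shape != self.values.shape:
            raise ValidationError("tau and values must be matching 1-d arrays")
        if self.tau.size and (np.any(self.tau <= 0) or np.any(np.diff(self.tau) <= 0)):
            raise ValidationError("tau must be strictly increasing and positive")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.tau.shape:
                raise ValidationError("sigma must match tau shape")


# --------------------------------------------------------------------------
# Boundary condition
# --------------------------------------------------------------------------

def _fresnel_unpolarized(cos_i: float, n_rel: float) -> float:
    """Unpolarized Fresnel reflectance from inside (n_rel = n_in/n_out > 1)."""
    sin_i = math.sqrt(max(0.0, 1.0 - cos_i * cos_i))
    sin_t = n_rel * sin_i
    if sin_t >= 1.0:
        return 1.0
    cos_t = math.sqrt(1.0 - sin_t * sin_t)
    # from inside: n1 = n_in, n2 = n_out; n_rel = n1/n2
    rs = (n_rel * cos_i - cos_t) / (n_rel * cos_i + cos_t)
    rp = (cos_t * n_rel - cos_i) / (cos_t * n_rel + cos_i)
    # rp above uses n1 cos_t vs n2 cos_i form divided through by n2
    return 0.5 * (rs * rs + rp * rp)


@lru_cache(maxsize=32)
def effective_reflection_coefficient(n_in: float, n_out: float = 1.0) -> float:
    """Fresnel-averaged effective internal reflectance R_eff.

    Moments of the unpolarized Fresnel reflectance over the internal
    hemisphere (fluence and flux weighted), combined as
    R_eff = (R_phi + R_j) / (2 - R_phi + R_j).  For n_in = 1.4 against air
    this evaluates to approximately 0.493.
    """
    n_rel = n_in / n_out
    if n_rel <= 1.0:
        return 0.0

    def integrand_phi(theta):
        return 2.0 * math.sin(theta) * math.cos(theta) * _fresnel_unpolarized(math.cos(theta), n_rel)

    def integrand_j(theta):
        c = math.cos(theta)
        return 3.0 * math.sin(theta) * c * c * _fresnel_unpolarized(math.cos(theta), n_rel)

    r_phi, _ = quad(integrand_phi, 0.0, math.pi / 2.0, limit=200)
    r_j, _ = quad(integrand_j, 0.0, math.pi / 2.0, limit=200)
    return (r_phi + r_j) / (2.0 - r_phi + r_j)


# --------------------------------------------------------------------------
# Hankel-space surface fluence
# --------------------------------------------------------------------------

def _layer_arrays(head: HeadModel):
    """Pack layer properties into arrays used by the Hankel-space kernel."""
    musp = np.array([lay.musp for lay in head.layers])
    mua = np.array([lay.mua for lay in head.layers])
    bfi = np.array([lay.bfi for lay in head.layers])
    thick = np.array([lay.thickness for lay in head.layers])
    k0 = head.k0
    dp = 1.0 / (3.0 * musp)
    # mua_eff_i(tau) = mua_i + slope_i * tau
    slope = 2.0 * musp * k0 ** 2 * bfi
    return musp, mua, slope, dp, thick


def _phi_surface(s: np.ndarray, tau: np.ndarray, musp, mua, slope, dp, thick,
                 z0: float, zb: float) -> np.ndarray:
    """Hankel-space surface fluence Phi(s, z=0; tau), shape (n_s, n_tau).

    Closed-form solution of the layered depth problem; all exponentials are
    of negative argument, so the expression is stable for arbitrarily large
    spatial frequency.
    """
    n = len(musp)
    s2 = (s * s)[:, None]
    tau_row = tau[None, :]

    def alpha(i):
        # layers with zero flow are delay-independent: keep them (n_s, 1)
        # so the hyperbolic recursion for those layers is computed once
        if slope[i] == 0.0:
            return np.sqrt(3.0 * musp[i] * mua[i] + s2)
        return np.sqrt(3.0 * musp[i] * (mua[i] + slope[i] * tau_row) + s2)

    a1 = alpha(0)
    if n == 1:
        gamma = 1.0
        e_c = 0.0
    else:
        # admittance recursion from the semi-infinite substrate upward
        a = alpha(n - 1)
        g = dp[n - 1] * a
        for i in range(n - 2, 0, -1):
            a = alpha(i)
            b = dp[i] * a
            t = np.tanh(a * thick[i])
            g = b * (b * t + g) / (b + g * t)
        gamma = g / (dp[0] * a1)
        e_c = np.exp(-2.0 * a1 * (thick[0] - z0))
    e_b = np.exp(-2.0 * a1 * zb)
    p = np.exp(-a1 * z0)
    # exp(-2 a1 (zb + l1)) = e_b * e_c * p^2  since 2(zb+l1) = 2zb + 2(l1-z0) + 2z0
    e_d = e_b * e_c * p * p
    num = (1.0 - e_b) * ((1.0 + e_c) + gamma * (1.0 - e_c)) * p
    den = 2.0 * dp[0] * a1 * ((1.0 + e_d) + gamma * (1.0 - e_d))
    out = num / den
    if out.shape[1] != tau.size:
        out = np.broadcast_to(out, (s.size, tau.size)).copy()
    return out


def _source_depth(head: HeadModel) -> float:
    lay = head.layers[0]
    z0 = 1.0 / (lay.musp + lay.mua)
    if math.isfinite(head.layers[0].thickness) and z0 >= head.layers[0].thickness:
        raise ValidationError(
            "effective source depth 1/(musp+mua) exceeds the top layer thickness; "
            "the layered solution requires the source inside the first layer")
    return z0


def _extrapolation_length(head: HeadModel) -> float:
    lay = head.layers[0]
    reff = effective_reflection_coefficient(lay.refractive_index)
    dp1 = 1.0 / (3.0 * lay.musp)
    return 2.0 * dp1 * (1.0 + reff) / (1.0 - reff)


# --------------------------------------------------------------------------
# Inverse Hankel quadrature
# --------------------------------------------------------------------------

_ENVELOPE_CUTOFF = 1e-12   # truncate panels once envelope < cutoff * peak
_REFINE_RTOL = 1e-8        # doubling refinement target on the tau=0 integral
_MAX_PANELS = 4000
_GRID_CACHE: dict = {}
_GRID_CACHE_MAX = 256


def _optics_key(head: HeadModel) -> tuple:
    return tuple(
        (lay.mua, lay.musp, lay.thickness, lay.refractive_index)
        for lay in head.layers
    ) + (head.wavelength_nm,)


def hankel_grid(head: HeadModel, sds: float) -> tuple[np.ndarray, np.ndarray]:
    """Quadrature nodes and combined weights for the inverse Hankel transform.

    Returns ``(s_nodes, w)`` such that ``G1(sds, tau) = w @ Phi(s_nodes, tau)``
    where the weights fold in the Gauss-Legendre panel weights, the Bessel
    kernel J0(s*sds), the measure s ds, and the 1/(2 pi) prefactor.  The grid
    depends only on the static optics (not on the flow indices, which only
    narrow the integrand), so it is cached and reused across candidate flows
    during fitting.
    """
    key = (_optics_key(head), round(float(sds), 12))
    hit = _GRID_CACHE.get(key)
    if hit is not None:
        return hit

    musp, mua, slope, dp, thick = _layer_arrays(head)
    z0 = _source_depth(head)
    zb = _extrapolation_length(head)
    tau0 = np.array([0.0])

    def envelope(s_arr):
        phi = _phi_surface(s_arr, tau0, musp, mua, slope, dp, thick, z0, zb)[:, 0]
        return phi * s_arr

    # panel width: resolve both the J0 oscillation (period 2 pi / sds) and the
    # smooth envelope scale (~ the source depth / extrapolation length)
    width = min(math.pi / max(float(sds), 0.3), 2.0)

    # find the truncation point from the tau=0 envelope; once the envelope
    # has dropped below 1e-8 of its peak the J0 oscillation no longer needs
    # fine resolution (that tail contributes < 1e-8 of the integral), so
    # panels widen 4x there to keep the 1e-12 truncation affordable
    peak = 0.0
    edges = [0.0]
    coarse = False
    while len(edges) <= _MAX_PANELS:
        w_here = 4.0 * width if coarse else width
        mid = edges[-1] + 0.5 * w_here
        val = float(envelope(np.array([mid]))[0])
        peak = max(peak, val)
        edges.append(edges[-1] + w_here)
        if len(edges) >= 5 and val < _ENVELOPE_CUTOFF * peak:
            break
        if not coarse and len(edges) >= 5 and val < 1e-8 * peak:
            coarse = True
    else:
        raise QuadratureError(
            f"inverse Hankel transform did not truncate within {_MAX_PANELS} "
            f"panels at sds={sds} cm (worst tau = 0)")

    edges = np.asarray(edges)
    halves = 0.5 * np.diff(edges)
    centers = 0.5 * (edges[:-1] + edges[1:])

    def build(nodes_per_panel):
        x, w = leggauss(nodes_per_panel)
        s_nodes = (centers[:, None] + halves[:, None] * x[None, :]).ravel()
        w_nodes = (halves[:, None] * w[None, :]).ravel()
        wj = w_nodes * s_nodes * j0(s_nodes * sds) / (2.0 * math.pi)
        return s_nodes, wj

    def integral(grid):
        s_nodes, wj = grid
        phi0 = _phi_surface(s_nodes, tau0, musp, mua, slope, dp, thick, z0, zb)[:, 0]
        return float(wj @ phi0)

    # doubling refinement: keep the coarsest node count whose estimate agrees
    # with the next refinement to the relative tolerance
    grid = build(8)
    val = integral(grid)
    nodes = 8
    while nodes <= 64:
        finer = build(nodes * 2)
        val_f = integral(finer)
        if abs(val_f - val) <= _REFINE_RTOL * abs(val_f):
            break
        grid, val = finer, val_f
        nodes *= 2
    else:
        raise QuadratureError(
            f"inverse Hankel transform failed to converge to rtol={_REFINE_RTOL} "
            f"at sds={sds} cm (worst tau = 0)")
    s_nodes, wj = grid

    if len(_GRID_CACHE) >= _GRID_CACHE_MAX:
        _GRID_CACHE.clear()
    _GRID_CACHE[key] = (s_nodes, wj)
    return s_nodes, wj


# --------------------------------------------------------------------------
# Public operations
# --------------------------------------------------------------------------

def g1_layered(head: HeadModel, sds: float, tau: np.ndarray) -> CorrelationCurve:
    """Normalized field autocorrelation g1(r, tau) for a layered head.

    ``g1 = G1(r, tau) / G1(r, 0)``; deterministic, monotonically
    non-increasing in tau when all flow indices are non-negative.
    """
    tau = np.asarray(tau, dtype=float)
    if tau.ndim != 1 or tau.size == 0:
        raise ValidationError("tau must be a non-empty 1-d array")
    if np.any(tau <= 0) or np.any(np.diff(tau) <= 0):
        raise ValidationError("tau must be strictly increasing and positive")
    s_nodes, wj = hankel_grid(head, sds)
    musp, mua, slope, dp, thick = _layer_arrays(head)
    z0 = _source_depth(head)
    zb = _extrapolation_length(head)
    phi = _phi_surface(s_nodes, np.concatenate(([0.0], tau)),
                       musp, mua, slope, dp, thick, z0, zb)
    g1_all = wj @ phi
    values = g1_all[1:] / g1_all[0]
    return CorrelationCurve(sds=float(sds), tau=tau, values=values, kind="field")


def cw_reflectance(head: HeadModel, sds: float) -> float:
    """Unnormalized G1 at tau = 0 (proportional to detected CW intensity)."""
    s_nodes, wj = hankel_grid(head, sds)
    musp, mua, slope, dp, thick = _layer_arrays(head)
    z0 = _source_depth(head)
    zb = _extrapolation_length(head)
    phi = _phi_surface(s_nodes, np.array([0.0]), musp, mua, slope, dp, thick, z0, zb)
    val = float(wj @ phi[:, 0])
    if val <= 0:
        raise QuadratureError(f"non-positive CW reflectance at sds={sds} cm")
    return val


def siegert_g2(g1curve: CorrelationCurve, beta: float) -> CorrelationCurve:
    """Intensity autocorrelation via the Siegert relation g2 = 1 + beta*g1^2."""
    if g1curve.kind != "field":
        raise ValidationError("siegert_g2 expects a field (g1) curve")
    if not 0.0 <= beta <= 1.0:
        raise ValidationError(f"beta must be in [0, 1], got {beta}")
    return CorrelationCurve(
        sds=g1curve.sds, tau=g1curve.tau,
        values=1.0 + beta * g1curve.values ** 2,
        kind="intensity", sigma=None, intensity=g1curve.intensity)


def g2_layered(head: HeadModel, sds: float, tau: np.ndarray,
               beta: float = 0.5) -> CorrelationCurve:
    """Convenience: clean analytical g2(r, tau) = 1 + beta * g1^2."""
    return siegert_g2(g1_layered(head, sds, tau), beta)
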