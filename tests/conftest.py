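"""Shared fixtures and independent closed-form oracles."""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy.integrate import quad

from layerdcs import (HeadModel, ParameterGrid, SlabGeometry, build_scheme,
                      nonuniqueness_sample, mc_comparison_sample, transport_photons)


@pytest.fixture(scope="session")
def scheme():
    return build_scheme()


@pytest.fixture(scope="session")
def grid():
    return ParameterGrid()


@pytest.fixture(scope="session")
def degen_sample():
    return nonuniqueness_sample()


@pytest.fixture(scope="session")
def mc_sample():
    return mc_comparison_sample()


@pytest.fixture(scope="session")
def median_head(grid):
    return grid.median_head(sbfi=1.7e-8, cbfi=5.2e-8)


@pytest.fixture(scope="session")
def small_mc_run(mc_sample):
    """Reduced-size transport run shared across Monte Carlo unit tests."""
    return transport_photons(SlabGeometry(), mc_sample.head, 150_000, seed=42)


@pytest.fixture(scope="session")
def mc_run_homog():
    """Transport run with identical (scalp) optics in every layer."""
    head = homogeneous_head(mua=0.1, musp=10.0, bfi=1e-8, thickness=(0.3, 0.7))
    return transport_photons(SlabGeometry(), head, 200_000, seed=9)


# --------------------------------------------------------------------------
# Independent closed-form oracle: homogeneous semi-infinite medium
# --------------------------------------------------------------------------

def _fresnel_reff(n_rel: float) -> float:
    """Effective internal reflectance from hemispheric Fresnel moments."""

    def fresnel(cos_i):
        sin_i = math.sqrt(max(0.0, 1.0 - cos_i * cos_i))
        sin_t = n_rel * sin_i
        if sin_t >= 1.0:
            return 1.0
        cos_t = math.sqrt(1.0 - sin_t * sin_t)
        rs = (n_rel * cos_i - cos_t) / (n_rel * cos_i + cos_t)
        rp = (cos_i - n_rel * cos_t) / (cos_i + n_rel * cos_t)
        return 0.5 * (rs * rs + rp * rp)

    r_phi = quad(lambda t: 2 * math.sin(t) * math.cos(t) * fresnel(math.cos(t)),
                 0, math.pi / 2, limit=200)[0]
    r_j = quad(lambda t: 3 * math.sin(t) * math.cos(t) ** 2 * fresnel(math.cos(t)),
               0, math.pi / 2, limit=200)[0]
    return (r_phi + r_j) / (2 - r_phi + r_j)


def homogeneous_g1_oracle(mua, musp, bfi, n, wavelength_nm, sds, tau):
    """Image-source semi-infinite solution of the correlation diffusion
    equation with an extrapolated-zero boundary:

        g1 = (exp(-K r1)/r1 - exp(-K rb)/rb) / (same at tau=0),
        K(tau)^2 = 3 mua musp + 6 musp^2 k0^2 bfi tau.
    """
    k0 = 2 * math.pi * n / (wavelength_nm * 1e-7)
    z0 = 1.0 / (musp + mua)
    zb = 2.0 / (3.0 * musp) * (1 + _fresnel_reff(n)) / (1 - _fresnel_reff(n))
    r1 = math.hypot(sds, z0)
    rb = math.hypot(sds, z0 + 2 * zb)
    tau = np.asarray(tau, dtype=float)
    K = np.sqrt(3 * mua * musp + 6 * musp ** 2 * k0 ** 2 * bfi * tau)
    K0 = math.sqrt(3 * mua * musp)
    num = np.exp(-K * r1) / r1 - np.exp(-K * rb) / rb
    den = math.exp(-K0 * r1) / r1 - math.exp(-K0 * rb) / rb
    return num / den


def homogeneous_cw_oracle(mua, musp, n, sds):
    """Unnormalized image-source CW fluence at the surface (for ratios)."""
    z0 = 1.0 / (musp + mua)
    zb = 2.0 / (3.0 * musp) * (1 + _fresnel_reff(n)) / (1 - _fresnel_reff(n))
    r1 = math.hypot(sds, z0)
    rb = math.hypot(sds, z0 + 2 * zb)
    K0 = math.sqrt(3 * mua * musp)
    return math.exp(-K0 * r1) / r1 - math.exp(-K0 * rb) / rb


def homogeneous_head(mua=0.1, musp=10.0, bfi=1e-8, thickness=(0.4, 0.6)):
    """Three identical layers: the layered solver's homogeneous limit."""
    return HeadModel.three_layer(mua=(mua,) * 3, musp=(musp,) * 3,
                                 thickness=thickness, bfi=(bfi,) * 3)
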