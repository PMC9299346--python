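"""Layered forward model: oracles, limits, and invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from layerdcs import (CorrelationCurve, HeadModel, TissueLayer,
                      ValidationError, cw_reflectance, g1_layered, g2_layered,
                      siegert_g2)

from conftest import (homogeneous_cw_oracle, homogeneous_g1_oracle,
                      homogeneous_head)

TAU = np.logspace(-7, -3, 40)


class TestG1Layered:
    def test_normalization_at_small_tau(self, degen_sample, median_head):
        """g1 -> 1 as tau -> 0 for any head and separation."""
        for head in (degen_sample.head, median_head):
            for sds in (0.5, 2.5):
                g1 = g1_layered(head, sds, np.array([1e-12, 1e-11]))
                assert g1.values[0] == pytest.approx(1.0, abs=1e-6)

    def test_monotone_nonincreasing_in_tau(self, degen_sample):
        g1 = g1_layered(degen_sample.head, 2.0, TAU)
        assert np.all(np.diff(g1.values) <= 0)
        assert np.all(g1.values <= 1.0 + 1e-12)

    def test_homogeneous_limit_matches_image_source_solution(self):
        """Three identical layers reduce to the semi-infinite closed form."""
        head = homogeneous_head(mua=0.12, musp=9.0, bfi=3e-8)
        for sds in (1.0, 2.0):
            got = g1_layered(head, sds, TAU).values
            want = homogeneous_g1_oracle(0.12, 9.0, 3e-8, 1.4, 785.0, sds, TAU)
            mask = want > 1e-6
            assert np.max(np.abs(got[mask] - want[mask]) / want[mask]) < 1e-4

    def test_thick_top_layer_limit(self):
        """A 10 cm scalp makes the stack behave as homogeneous scalp."""
        head = HeadModel.three_layer(mua=(0.1, 0.2, 0.05), musp=(10, 8, 4),
                                     thickness=(10.0, 0.7),
                                     bfi=(1e-8, 0, 6e-8))
        got = g1_layered(head, 1.5, TAU).values
        want = homogeneous_g1_oracle(0.1, 10.0, 1e-8, 1.4, 785.0, 1.5, TAU)
        mask = want > 1e-6
        assert np.max(np.abs(got[mask] - want[mask]) / want[mask]) < 1e-3

    def test_brain_flow_monotonicity(self, grid):
        """Faster cerebral flow strictly lowers g1 at every delay, r >= 1.5."""
        tau = np.logspace(-6.5, -4, 12)
        for sds in (1.5, 2.5):
            prev = None
            for cbfi in (2e-8, 5e-8, 9e-8):
                head = grid.median_head(sbfi=1.7e-8, cbfi=cbfi)
                vals = g1_layered(head, sds, tau).values
                if prev is not None:
                    assert np.all(vals < prev)
                prev = vals

    def test_invalid_tau_rejected(self, degen_sample):
        with pytest.raises(ValidationError):
            g1_layered(degen_sample.head, 1.0, np.array([1e-6, 1e-7]))
        with pytest.raises(ValidationError):
            g1_layered(degen_sample.head, 1.0, np.array([0.0, 1e-6]))


class TestSiegert:
    def test_identity_to_rounding_of_unity(self, degen_sample):
        """g2 - 1 equals beta*g1^2 to the rounding floor of 1.0 (one ulp):
        forming 1 + x truncates bits of x below ~2e-16, so exact bitwise
        equality is only defined above that floor."""
        g1 = g1_layered(degen_sample.head, 1.5, TAU)
        g2 = siegert_g2(g1, 0.5)
        want = 0.5 * g1.values ** 2
        diff = np.abs((g2.values - 1.0) - want)
        assert np.max(diff) <= 2 ** -52

    @pytest.mark.parametrize("g1_val,beta,want", [
        (1.0, 0.5, 1.5), (0.0, 0.5, 1.0), (0.7, 0.0, 1.0)])
    def test_endpoint_values(self, g1_val, beta, want):
        curve = CorrelationCurve(sds=1.0, tau=np.array([1e-6]),
                                 values=np.array([g1_val]), kind="field")
        assert siegert_g2(curve, beta).values[0] == pytest.approx(want)

    def test_kind_mismatch_rejected(self, degen_sample):
        g2 = g2_layered(degen_sample.head, 1.5, TAU)
        with pytest.raises(ValidationError):
            siegert_g2(g2, 0.5)


class TestCwReflectance:
    def test_strictly_decreasing_in_separation(self, degen_sample):
        vals = [cw_reflectance(degen_sample.head, r) for r in (0.5, 1.0, 2.0, 3.0)]
        assert all(a > b > 0 for a, b in zip(vals, vals[1:]))

    def test_homogeneous_ratio_matches_closed_form(self):
        head = homogeneous_head(mua=0.08, musp=11.0, bfi=1e-8)
        got = cw_reflectance(head, 1.0) / cw_reflectance(head, 2.5)
        want = (homogeneous_cw_oracle(0.08, 11.0, 1.4, 1.0)
                / homogeneous_cw_oracle(0.08, 11.0, 1.4, 2.5))
        assert got == pytest.approx(want, rel=1e-3)


class TestDomainTypes:
    @pytest.mark.parametrize("kwargs", [
        {"mua": -0.1, "musp": 10.0},
        {"mua": 0.1, "musp": 0.0},
        {"mua": 0.1, "musp": 10.0, "bfi": -1e-9},
        {"mua": 0.1, "musp": 10.0, "anisotropy": 1.0},
    ])
    def test_layer_invariants(self, kwargs):
        with pytest.raises(ValidationError):
            TissueLayer(**kwargs)

    def test_terminal_layer_must_be_semi_infinite(self):
        with pytest.raises(ValidationError):
            HeadModel(layers=(TissueLayer(mua=0.1, musp=10, thickness=1.0),))

    def test_only_terminal_layer_semi_infinite(self):
        with pytest.raises(ValidationError):
            HeadModel(layers=(TissueLayer(mua=0.1, musp=10),
                              TissueLayer(mua=0.1, musp=10)))

    def test_k0_from_wavelength(self):
        head = homogeneous_head()
        want = 2 * math.pi * 1.4 / 785e-7
        assert head.k0 == pytest.approx([want] * 3)

    def test_serialization_roundtrip_bit_exact(self, degen_sample):
        text = degen_sample.head.to_text()
        back = HeadModel.from_text(text)
        assert back == degen_sample.head

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(mua=st.floats(0.01, 0.5), musp=st.floats(2.0, 15.0),
           l1=st.floats(0.1, 1.0), bfi=st.floats(0, 1e-7))
    def test_roundtrip_property(self, mua, musp, l1, bfi):
        head = HeadModel.three_layer(mua=(mua,) * 3, musp=(musp,) * 3,
                                     thickness=(l1, 0.7), bfi=(bfi, 0, bfi))
        assert HeadModel.from_text(head.to_text()) == head
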