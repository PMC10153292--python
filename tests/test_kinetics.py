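"""Rate-law catalog: guarded exponentiation, Hill responses, composite laws."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from segpol.kinetics import (DEFAULT_EPSILON, GuardConfig, HillParams,
                             TxnRateParams, bind_ptc_hh, decay_rate,
                             guarded_pow, hill_activation, hill_repression,
                             txn_composite_wg, txn_inducer_repressor)

GUARD = GuardConfig()
NO_GUARD = GuardConfig(enabled=False)


class TestGuardedPow:
    def test_positive_base_is_plain_power(self):
        assert guarded_pow(4.0, 0.5) == 2.0

    def test_negative_base_clamps_to_epsilon(self):
        # max(eps, -1e-12) = 1e-80, squared
        assert guarded_pow(-1e-12, 2.0) == pytest.approx(1e-160, rel=1e-12)

    def test_zero_base_fractional_exponent(self):
        # eps ** 1.7 = 10 ** -136, computed independently
        assert guarded_pow(0.0, 1.7) == pytest.approx(10.0 ** -136, rel=1e-10)

    def test_rejects_nonpositive_epsilon(self):
        with pytest.raises(ValueError):
            guarded_pow(1.0, 1.0, eps=0.0)

    @settings(max_examples=200, deadline=None)
    @given(base=st.floats(-1e6, 1e6, allow_nan=False),
           expo=st.floats(0.1, 12.0))
    def test_always_finite_never_nan(self, base, expo):
        # a clamped eps base can underflow to exactly 0.0 at large
        # exponents; what the guard forbids is a NaN or infinity
        v = guarded_pow(base, expo)
        assert math.isfinite(v) and v >= 0


class TestHill:
    @pytest.mark.parametrize("nu", [1.0, 2.0, 5.7, 10.0])
    def test_half_saturation_identity(self, nu):
        p = HillParams(kappa=0.3, nu=nu)
        assert hill_activation(0.3, p) == pytest.approx(0.5)
        assert hill_repression(0.3, p) == pytest.approx(0.5)

    def test_zero_input(self):
        p = HillParams(0.2, 2.0)
        assert hill_activation(0.0, p) == 0.0
        assert hill_repression(0.0, p) == 1.0

    def test_hand_computed_value(self):
        # 0.4^2 / (0.2^2 + 0.4^2) = 0.16 / 0.20 = 0.8
        assert hill_activation(0.4, HillParams(0.2, 2.0)) == pytest.approx(0.8)

    @settings(max_examples=100, deadline=None)
    @given(x=st.floats(0, 10), kappa=st.floats(1e-3, 1), nu=st.floats(1, 10))
    def test_complement_and_monotonicity(self, x, kappa, nu):
        p = HillParams(kappa, nu)
        a = hill_activation(x, p)
        assert 0.0 <= a <= 1.0
        assert a + hill_repression(x, p) == pytest.approx(1.0)
        assert hill_activation(x * 1.1 + 1e-9, p) >= a - 1e-15

    def test_invalid_kappa_rejected(self):
        with pytest.raises(ValueError):
            HillParams(0.0, 2.0)
        with pytest.raises(ValueError):
            HillParams(-1.0, 2.0)


class TestTxnInducerRepressor:
    P = TxnRateParams(V=2.0, inducer=HillParams(0.5, 2.0),
                      repressor=HillParams(0.1, 3.0))

    def test_half_saturation_without_repressor(self):
        # R = 0 makes psi = 1; I = k1 gives V/2
        assert txn_inducer_repressor(0.5, 0.0, self.P, NO_GUARD) == pytest.approx(1.0)

    def test_no_inducer_guarded_is_effectively_zero(self):
        v = txn_inducer_repressor(0.0, 0.7, self.P, GUARD)
        assert 0.0 <= v < 1e-100

    @settings(max_examples=100, deadline=None)
    @given(I=st.floats(1e-6, 5), R=st.floats(1e-6, 5))
    def test_guarded_matches_unguarded_on_safe_domain(self, I, R):
        g = txn_inducer_repressor(I, R, self.P, GUARD)
        u = txn_inducer_repressor(I, R, self.P, NO_GUARD)
        # psi can round to exactly zero for strong repression; the guard
        # clamps it to eps, both paths then agree to machine precision
        assert g == pytest.approx(u, rel=1e-12, abs=1e-60)

    def test_unguarded_negative_base_propagates_nan(self):
        p = TxnRateParams(V=1.0, inducer=HillParams(0.5, 2.5),
                          repressor=HillParams(0.1, 3.0))
        assert math.isnan(txn_inducer_repressor(-1e-12, 0.0, p, NO_GUARD))

    def test_bounded_by_v(self, rng):
        for _ in range(200):
            I, R = rng.uniform(0, 10, 2)
            v = txn_inducer_repressor(I, R, self.P, GUARD)
            assert 0.0 <= v <= self.P.V


class TestCompositeWg:
    KW = dict(alpha_CIwg=2.0, alpha_WGwg=1.5,
              hill_CIwg=HillParams(0.3, 2.0), hill_WGwg=HillParams(0.2, 3.0),
              hill_CNwg=HillParams(0.1, 2.0), V=1.0)

    def test_reduces_without_autoactivation(self):
        v = txn_composite_wg(0.3, 0.0, 0.0, **{**self.KW, "alpha_WGwg": 0.0})
        # phi(CI)=0.5, S = 2*0.5 = 1, psi = 1 -> V * 1/2
        assert v == pytest.approx(0.5)

    def test_all_inputs_zero(self):
        assert txn_composite_wg(0.0, 0.0, 0.0, **self.KW) == 0.0

    def test_bounded_by_v_over_random_inputs(self, rng):
        for CI, CN, WG in rng.uniform(0, 10, (1000, 3)):
            assert 0.0 <= txn_composite_wg(CI, CN, WG, **self.KW, guard=GUARD) <= self.KW["V"]

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            txn_composite_wg(1, 1, 1, **{**self.KW, "alpha_CIwg": -1.0})


class TestDecayAndBinding:
    def test_decay_unit_case(self):
        assert decay_rate(1.0, math.log(2.0)) == pytest.approx(1.0)
        assert decay_rate(0.0, 10.0) == 0.0

    def test_decay_rejects_nonpositive_halflife(self):
        with pytest.raises(ValueError):
            decay_rate(1.0, 0.0)

    def test_pure_decay_halves_at_halflife(self):
        # dx/dt = -(ln2/H) x integrated to t = H gives x0 / 2
        from scipy.integrate import odeint
        H = 7.3
        sol = odeint(lambda x, t: -decay_rate(x[0], H), [1.0], [0.0, H],
                     rtol=1e-10, atol=1e-12)
        assert sol[-1, 0] == pytest.approx(0.5, rel=1e-6)

    def test_binding_zero_reactant_gives_zero_flux(self):
        assert bind_ptc_hh(0.0, 0.5, 1.0, 10.0, 20.0) == (0.0, 0.0)
        assert bind_ptc_hh(0.5, 0.0, 1.0, 10.0, 20.0) == (0.0, 0.0)

    def test_binding_is_bilinear(self):
        f1 = bind_ptc_hh(0.25, 0.5, 0.7, 3.0, 5.0)
        f2 = bind_ptc_hh(0.5, 0.5, 0.7, 3.0, 5.0)
        assert f2[0] == pytest.approx(2 * f1[0])
        assert f2[1] == pytest.approx(2 * f1[1])

    def test_binding_unit_example(self):
        fp, fh = bind_ptc_hh(0.5, 0.5, 1.0, 1.0, 1.0)
        assert fp == pytest.approx(0.25)
        assert fh == pytest.approx(0.25)

    def test_binding_rejects_bad_scales(self):
        with pytest.raises(ValueError):
            bind_ptc_hh(0.5, 0.5, 1.0, 0.0, 1.0)
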