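"""Interaction constants, spectral densities and closed-form rates."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spinrelax import (FieldContext, SpinSystem, csa_constant,
                       dipolar_constant, eta_xy, j_axial, j_extended,
                       j_modelfree, kappa, rates_from_j,
                       reduced_spectral_density_map)
from spinrelax.spinphys import (GAMMA_H1, GAMMA_MAG, H_PLANCK,
                                MagicAngleError, MU0, p2)

from conftest import flat_high_freq_j


class TestInteractionConstants:
    def test_dipolar_constant_field_independent(self, spin_n15):
        d1 = dipolar_constant(spin_n15, FieldContext(500.0))
        d2 = dipolar_constant(spin_n15, FieldContext(900.0))
        assert d1 == d2

    def test_dipolar_constant_r_cubed(self, spin_n15, field_750):
        d1 = dipolar_constant(spin_n15, field_750)
        d2 = dipolar_constant(SpinSystem(r_xh=2.04), field_750)
        assert d2 == pytest.approx(d1 / 8.0, rel=1e-12)

    def test_dipolar_constant_value(self, spin_n15, field_750):
        # independent high-precision constant arithmetic
        r = 1.02e-10
        expected = MU0 * H_PLANCK * GAMMA_H1 * GAMMA_MAG["N15"] \
            / (8.0 * math.pi**2 * r**3)
        assert dipolar_constant(spin_n15, field_750) == pytest.approx(
            expected, rel=1e-14)
        # magnitude of the familiar amide dipolar coupling scale
        assert 7.0e4 < expected < 7.5e4

    def test_csa_constant_zero_anisotropy(self, field_750):
        assert csa_constant(SpinSystem(delta_sigma=0.0), field_750) == 0.0

    def test_csa_constant_field_scaling(self, spin_n15):
        c750 = csa_constant(spin_n15, FieldContext(750.0))
        c900 = csa_constant(spin_n15, FieldContext(900.0))
        assert c900 == pytest.approx(c750 * 900.0 / 750.0, rel=1e-12)

    def test_csa_constant_value_and_sign(self, spin_n15, field_750):
        wn = 2.0 * math.pi * 750e6 * GAMMA_MAG["N15"] / GAMMA_H1
        expected = wn * (-164e-6) / math.sqrt(3.0)
        c = csa_constant(spin_n15, field_750)
        assert c == pytest.approx(expected, rel=1e-14)
        assert c < 0

    def test_invalid_bond_length(self):
        with pytest.raises(ValueError):
            SpinSystem(r_xh=-1.0)


class TestKappa:
    def test_printed_value_750(self, spin_n15, field_750):
        assert kappa(spin_n15, field_750) == pytest.approx(1.2283, abs=1e-4)

    def test_monotone_in_field(self, spin_n15):
        vals = [kappa(spin_n15, FieldContext(f))
                for f in (500.0, 600.0, 700.0, 750.0, 900.0)]
        diffs = np.diff(vals)
        assert np.all(diffs > 0) or np.all(diffs < 0)

    def test_beta_dependence_through_p2_only(self, field_750):
        k18 = kappa(SpinSystem(beta=18.0), field_750)
        k0 = kappa(SpinSystem(beta=0.0), field_750)
        assert k0 == pytest.approx(k18 * p2(math.cos(math.radians(18.0))),
                                   rel=1e-12)

    def test_independent_symbolic_evaluation_500(self, spin_n15):
        # evaluate the defining expression from scratch at 500 MHz
        f = FieldContext(500.0)
        d = MU0 * H_PLANCK * GAMMA_H1 * GAMMA_MAG["N15"] / (
            8.0 * math.pi**2 * (1.02e-10) ** 3)
        c = 2.0 * math.pi * 500e6 * GAMMA_MAG["N15"] / GAMMA_H1 \
            * (-164e-6) / math.sqrt(3.0)
        p2b = 0.5 * (3.0 * math.cos(math.radians(18.0)) ** 2 - 1.0)
        expected = -6.0 * (d * d / 8.0 + c * c / 6.0) / (
            math.sqrt(3.0) * c * d * p2b)
        assert kappa(spin_n15, f) == pytest.approx(expected, rel=1e-12)

    def test_magic_angle_singular(self, field_750):
        with pytest.raises(MagicAngleError):
            kappa(SpinSystem(beta=math.degrees(math.acos(1 / math.sqrt(3)))),
                  field_750)


class TestSpectralDensities:
    def test_rigid_j0(self):
        tau_c = 6.5e-9
        assert j_modelfree(0.0, 1.0, tau_c, 0.0) == pytest.approx(
            0.4 * tau_c, rel=1e-14)

    def test_zero_internal_time_drops_second_term(self):
        w = 2 * math.pi * 60.8e6
        assert j_modelfree(w, 0.7, 8e-9, 0.0) == pytest.approx(
            0.4 * 0.7 * 8e-9 / (1 + (w * 8e-9) ** 2), rel=1e-14)

    def test_modelfree_value_vs_arithmetic(self):
        w = 2 * math.pi * 76.01e6
        s2, tc, ti = 0.85, 6.5e-9, 50e-12
        tau = tc * ti / (tc + ti)
        expected = 0.4 * (s2 * tc / (1 + (w * tc) ** 2)
                          + (1 - s2) * tau / (1 + (w * tau) ** 2))
        assert j_modelfree(w, s2, tc, ti) == pytest.approx(expected, rel=1e-14)

    @pytest.mark.parametrize("w", [0.0, 1e8, 5e9])
    def test_extended_reduces_to_modelfree_at_sf2_one(self, w):
        assert j_extended(w, 1.0, 0.55, 6.5e-9, 1.2e-9) == pytest.approx(
            float(j_modelfree(w, 0.55, 6.5e-9, 1.2e-9)), rel=1e-14)

    def test_extended_single_lorentzian_at_ss2_one(self):
        w, sf2, tc = 3e8, 0.8, 6.5e-9
        assert j_extended(w, sf2, 1.0, tc, 1e-9) == pytest.approx(
            0.4 * sf2 * tc / (1 + (w * tc) ** 2), rel=1e-14)

    def test_axial_isotropic_limit(self):
        for ang in (0.0, 30.0, 90.0):
            got = j_axial(2e8, 0.85, 30e-12, 6.5e-9, 1.0, ang)
            want = j_modelfree(2e8, 0.85, 6.5e-9, 30e-12)
            assert float(got) == pytest.approx(float(want), rel=1e-12)

    def test_axial_weights_sum_to_one(self):
        from spinrelax.spinphys import axial_weights
        for ang in np.linspace(0, 90, 13):
            assert sum(axial_weights(ang)) == pytest.approx(1.0, abs=1e-12)

    def test_axial_value_vs_numerical_composition(self):
        # independently re-compose the three-Lorentzian sum
        from spinrelax.spinphys import axial_taus, axial_weights
        w, s2, ti, tc, ratio, ang = 2.9e8, 0.9, 25e-12, 11.8e-9, 1.26, 30.0
        acc = 0.0
        for a, t in zip(axial_weights(ang), axial_taus(tc, ratio)):
            tp = t * ti / (t + ti)
            acc += a * (s2 * t / (1 + (w * t) ** 2)
                        + (1 - s2) * tp / (1 + (w * tp) ** 2))
        assert float(j_axial(w, s2, ti, tc, ratio, ang)) == pytest.approx(
            0.4 * acc, rel=1e-12)


class TestRatesFromJ:
    def test_rex_adds_to_r2_only(self, spin_n15, field_700):
        j = lambda w: j_modelfree(w, 0.9, 6.5e-9, 30e-12)
        r1a, r2a, noea = rates_from_j(spin_n15, field_700, j, rex=0.0)
        r1b, r2b, noeb = rates_from_j(spin_n15, field_700, j, rex=5.0)
        assert r2b == pytest.approx(r2a + 5.0, abs=1e-12)
        assert r1b == r1a and noeb == noea

    def test_zero_j_gives_zero_rates(self, spin_n15, field_700):
        with pytest.raises(ZeroDivisionError):
            rates_from_j(spin_n15, field_700, lambda w: np.zeros_like(
                np.atleast_1d(w)))

    def test_rigid_r2_over_r1_vs_independent_evaluation(self, spin_n15):
        # closed-form ratio recomputed from scratch with its own J values
        f = FieldContext(700.0)
        tc = 6.5e-9
        d = dipolar_constant(spin_n15, f)
        c = csa_constant(spin_n15, f)
        wh, wx = f.omega_h, f.omega_x("N15")
        jj = lambda w: 0.4 * tc / (1 + (w * tc) ** 2)
        r1 = d**2 / 4 * (jj(wh - wx) + 3 * jj(wx) + 6 * jj(wh + wx)) \
            + c**2 * jj(wx)
        r2 = d**2 / 8 * (4 * jj(0) + jj(wh - wx) + 3 * jj(wx) + 6 * jj(wh)
                         + 6 * jj(wh + wx)) + c**2 / 6 * (4 * jj(0)
                                                          + 3 * jj(wx))
        got = rates_from_j(spin_n15, f, lambda w: j_modelfree(w, 1.0, tc, 0.0))
        assert got[1] / got[0] == pytest.approx(r2 / r1, rel=1e-12)

    def test_noe_below_one_for_slow_tumbling_15n(self, spin_n15, field_700):
        # signed gamma ratio makes the 15N NOE < 1 (and possibly < 0)
        _, _, noe = rates_from_j(
            spin_n15, field_700, lambda w: j_modelfree(w, 0.9, 6.5e-9, 0.0))
        assert noe < 1.0

    @given(s2=st.floats(0.2, 1.0), tc=st.floats(2e-9, 20e-9),
           f=st.floats(400.0, 1000.0))
    @settings(max_examples=60, deadline=None)
    def test_rates_nonnegative_and_r2_dominates(self, s2, tc, f):
        field = FieldContext(f)
        r1, r2, _ = rates_from_j(
            SpinSystem(), field, lambda w: j_modelfree(w, s2, tc, 20e-12))
        assert r1 >= 0 and r2 >= 0
        assert r2 >= r1 / 2


class TestEtaXy:
    @given(j0=st.floats(0, 5e-9), jwx=st.floats(0, 5e-9),
           f=st.floats(400.0, 1000.0))
    @settings(max_examples=200, deadline=None)
    def test_kappa_eta_identity(self, j0, jwx, f):
        spin, field = SpinSystem(), FieldContext(f)
        d = dipolar_constant(spin, field)
        c = csa_constant(spin, field)
        lhs = kappa(spin, field) * eta_xy(spin, field, j0, jwx)
        rhs = (d * d / 8.0 + c * c / 6.0) * (4.0 * j0 + 3.0 * jwx)
        assert lhs == pytest.approx(rhs, rel=1e-12, abs=1e-30)

    def test_zero_j_gives_zero(self, spin_n15, field_750):
        assert eta_xy(spin_n15, field_750, 0.0, 0.0) == 0.0

    def test_positive_for_15n_defaults(self, spin_n15, field_750):
        # derived value via the kappa identity, computed independently
        j = lambda w: j_modelfree(w, 0.9, 6.5e-9, 0.0)
        j0, jx = float(j(0.0)), float(j(field_750.omega_x("N15")))
        eta = eta_xy(spin_n15, field_750, j0, jx)
        assert eta > 0
        d = dipolar_constant(spin_n15, field_750)
        c = csa_constant(spin_n15, field_750)
        expected = (d * d / 8 + c * c / 6) * (4 * j0 + 3 * jx) / kappa(
            spin_n15, field_750)
        assert eta == pytest.approx(expected, rel=1e-12)


class TestReducedSpectralDensityMapping:
    def test_exact_roundtrip_flat_high_freq(self, spin_n15, field_700):
        j0, jwx, jh = 2.5e-9, 1.0e-9, 3.0e-11
        j = flat_high_freq_j(j0, jwx, jh, field_700.omega_x("N15"))
        r1, r2, noe = rates_from_j(spin_n15, field_700, j)
        t = reduced_spectral_density_map(r1, r2, noe, spin_n15, field_700)
        assert t.j0 == pytest.approx(j0, rel=1e-12)
        assert t.jwx == pytest.approx(jwx, rel=1e-12)
        assert t.jwh_eff == pytest.approx(jh, rel=1e-12)
        assert not t.negative_j0

    def test_noe_of_one_gives_zero_high_freq_j(self, spin_n15, field_700):
        t = reduced_spectral_density_map(2.0, 8.0, 1.0, spin_n15, field_700)
        assert t.jwh_eff == 0.0

    def test_lorentzian_j0_within_5_percent(self, spin_n15, field_700):
        j = lambda w: j_modelfree(w, 0.9, 6.5e-9, 0.0)
        r1, r2, noe = rates_from_j(spin_n15, field_700, j)
        t = reduced_spectral_density_map(r1, r2, noe, spin_n15, field_700)
        assert t.j0 == pytest.approx(float(j(0.0)), rel=0.05)

    def test_exchange_flags_negative_j0(self, spin_n15, field_700):
        # inconsistent (very large R1) input drives J(0) negative
        t = reduced_spectral_density_map(50.0, 1.0, 0.7, spin_n15, field_700)
        assert t.negative_j0
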