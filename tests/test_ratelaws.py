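"""Rate-law library: closed-form identities, limits and monotonicity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import snrk1kin as sk
from snrk1kin.params import SnRK1Params
from snrk1kin.ratelaws import InhibitorVector

conc = st.floats(0.0, 10.0, allow_nan=False)


class TestMichaelisMenten:
    @pytest.mark.parametrize(
        "vmax,km,s,expected",
        [
            (1.0, 0.5, 0.0, 0.0),           # zero substrate
            (2.0, 0.5, 0.5, 1.0),           # half saturation
            (3.0, 1e-3, 1e3, 3.0 * 1e3 / (1e-3 + 1e3)),  # saturation
        ],
    )
    def test_identities(self, vmax, km, s, expected):
        assert sk.rate_mm_irrev(vmax, km, s) == pytest.approx(expected, rel=1e-12)

    def test_saturation_limit(self):
        assert sk.rate_mm_irrev(1.0, 0.5, 1e6 * 0.5) >= 0.999

    @pytest.mark.parametrize("vmax,km", [(0.0, 1.0), (-1.0, 1.0), (1.0, 0.0)])
    def test_rejects_nonpositive_constants(self, vmax, km):
        with pytest.raises(ValueError):
            sk.rate_mm_irrev(vmax, km, 1.0)


class TestMassAction:
    def test_proportionality(self):
        assert sk.rate_mass_action(2.0, 3.0) == 6.0
        assert sk.rate_mass_action(2.0, 0.0) == 0.0

    @given(k=st.floats(1e-3, 1e3), s=conc)
    @settings(deadline=None, max_examples=50)
    def test_linearity(self, k, s):
        assert sk.rate_mass_action(k, 2 * s) == pytest.approx(
            2 * sk.rate_mass_action(k, s), rel=1e-12
        )

    def test_rejects_negative_substrate(self):
        with pytest.raises(ValueError):
            sk.rate_mass_action(1.0, -0.1)


class TestSPS:
    def test_vmax_from_peptide(self):
        """k_SPS·E_total at saturating substrates reproduces the measured
        maximal SPS activity of ~25.3 μmol gFW⁻¹ h⁻¹."""
        v = sk.rate_sps(8.5e-6, 1e6, 1e6, 2.98e6, 0.5, 1.0)
        assert v == pytest.approx(25.32, rel=5e-3)

    def test_no_active_enzyme_no_flux(self):
        assert sk.rate_sps(0.0, 1.0, 1.0, 2.98e6, 0.5, 1.0) == 0.0

    def test_double_half_saturation(self):
        v = sk.rate_sps(1.0, 0.5, 1.0, 10.0, 0.5, 1.0)
        assert v == pytest.approx(10.0 / 4.0, rel=1e-12)

    @given(
        e=st.floats(0, 1e-5), f=conc, u=conc,
        df=st.floats(0, 1.0), du=st.floats(0, 1.0),
    )
    @settings(deadline=None, max_examples=50)
    def test_monotone_in_every_argument(self, e, f, u, df, du):
        lo = sk.rate_sps(e, f, u, 2.98e6, 0.5, 1.0)
        hi = sk.rate_sps(e * 1.5 + 1e-9, f + df, u + du, 2.98e6, 0.5, 1.0)
        assert hi >= lo - 1e-15


class TestInvertaseMixed:
    KM = 2.0

    def test_reduces_to_mm_without_products(self):
        v = sk.rate_inv_mixed(1.0, self.KM, self.KM, 0.0, 0.0, 10.0, 10.0)
        assert v == pytest.approx(0.5, rel=1e-12)

    def test_noncompetitive_halving_at_saturation(self):
        v = sk.rate_inv_mixed(1.0, self.KM, 1e7 * self.KM, 10.0, 0.0, 10.0, 10.0)
        assert v == pytest.approx(0.5, rel=1e-5)

    def test_competitive_doubles_apparent_km(self):
        # Fru = Ki doubles the apparent KM: half-max now at Suc = 2·KM
        v = sk.rate_inv_mixed(1.0, self.KM, 2 * self.KM, 0.0, 10.0, 10.0, 10.0)
        assert v == pytest.approx(0.5, rel=1e-12)


class TestHexokinase:
    def test_plain_mm_without_inhibitor(self):
        assert sk.rate_hxk_noncomp(1.0, 0.15, 0.15, 0.0, 0.5) == pytest.approx(0.5)

    def test_halving_at_ki(self):
        v = sk.rate_hxk_noncomp(1.0, 0.15, 1e6, 0.5, 0.5)
        assert v == pytest.approx(0.5, rel=1e-5)

    def test_zero_substrate(self):
        assert sk.rate_hxk_noncomp(1.0, 0.15, 0.0, 0.3, 0.5) == 0.0


class TestSnRK1:
    """The partial non-competitive mixed-type inhibition law."""

    def test_uninhibited_saturating_substrate(self, snrk1):
        v = sk.rate_snrk1(1.7e-6, InhibitorVector(), snrk1)
        assert v == pytest.approx(snrk1.vmax, rel=1e-1)
        # fully saturating: relative deviation < 1e-3
        v_sat = sk.rate_snrk1(1e-3, InhibitorVector(), snrk1)
        assert abs(v_sat - snrk1.vmax) / snrk1.vmax < 1e-3

    def test_t6p_residual_activity(self, snrk1):
        """1 mM T6P alone leaves (1+0.29·200)/(1+200) ≈ 29.35% of vmax."""
        v = sk.rate_snrk1(1.0, InhibitorVector(T6P=1.0), snrk1)
        expected = (1 + 0.29 * 200) / (1 + 200)
        assert v / snrk1.vmax == pytest.approx(expected, rel=1e-3)
        assert v / snrk1.vmax == pytest.approx(0.2935, abs=5e-4)

    def test_g1p_residual_activity(self, snrk1):
        """1 mM G1P alone: 1/(1 + 1/0.48) ≈ 0.324 of vmax."""
        v = sk.rate_snrk1(1.0, InhibitorVector(G1P=1.0), snrk1)
        assert v / snrk1.vmax == pytest.approx(1 / (1 + 1 / 0.48), rel=1e-3)

    def test_no_substrate_no_rate(self, snrk1):
        assert sk.rate_snrk1(0.0, InhibitorVector(T6P=0.5), snrk1) == 0.0

    def test_t6p_saturation_approaches_k_partial(self, snrk1):
        t6p = 1e4 * snrk1.ki_t6p
        v = sk.rate_snrk1(1.0, InhibitorVector(T6P=t6p), snrk1)
        assert abs(v / snrk1.vmax - snrk1.k_partial) / snrk1.k_partial < 1e-3

    @given(
        t=st.floats(0, 1.0), g1=st.floats(0, 1.0), g6=st.floats(0, 1.0),
        dt=st.floats(0, 1.0),
        which=st.sampled_from(["T6P", "G1P", "G6P"]),
    )
    @settings(deadline=None, max_examples=100)
    def test_monotone_nonincreasing_in_each_inhibitor(self, snrk1, t, g1, g6, dt, which):
        base = {"T6P": t, "G1P": g1, "G6P": g6}
        more = dict(base)
        more[which] += dt
        v0 = sk.rate_snrk1(1.0, InhibitorVector(**base), snrk1)
        v1 = sk.rate_snrk1(1.0, InhibitorVector(**more), snrk1)
        assert v1 <= v0 + 1e-12

    def test_combination_ordering_at_1mM(self, snrk1):
        """Triple < T6P+G1P < T6P+G6P < T6P alone; G1P+G6P < G1P alone."""
        def v(**inh):
            return sk.rate_snrk1(1.0, InhibitorVector(**inh), snrk1)

        v_t = v(T6P=1)
        v_tg1 = v(T6P=1, G1P=1)
        v_tg6 = v(T6P=1, G6P=1)
        v_g1 = v(G1P=1)
        v_g1g6 = v(G1P=1, G6P=1)
        v_all = v(T6P=1, G1P=1, G6P=1)
        assert v_all < v_tg1 < v_tg6 < v_t
        assert v_g1g6 < v_g1

    def test_rejects_negative_inhibitor(self):
        with pytest.raises(ValueError):
            InhibitorVector(T6P=-0.1)


class TestSnRK1ParamsValidation:
    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            SnRK1Params(vmax=1.0, km_e=0.0, ki_t6p=0.005, ki_g1p=0.48,
                        ki_g6p=1.5, k_partial=0.29)

    def test_rejects_k_partial_above_one(self):
        with pytest.raises(ValueError):
            SnRK1Params(vmax=1.0, km_e=1e-7, ki_t6p=0.005, ki_g1p=0.48,
                        ki_g6p=1.5, k_partial=1.2)
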