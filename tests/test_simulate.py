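"""Feeding-protocol integration: conservation, dynamics, restartability."""

import numpy as np
import pytest

import snrk1kin as sk
from conftest import linear_r2


class TestIntegrate:
    def test_phospho_cycle_conserved_along_trajectory(self, feeding_8h, params):
        total = feeding_8h.e_sps_total
        drift = np.max(np.abs(total - params.e_sps_total)) / params.e_sps_total
        assert drift < 1e-9

    def test_zero_inputs_zero_sugars_stay_zero(self, params):
        p = params.update(validate=False, suc_external=0.0, v_cfbpase=0.0)
        init = sk.ModelState(
            **{n: 0.0 for n in sk.STATE_NAMES[:9]},
            E_SPS_act=1.7e-6, E_SPS_inact=6.8e-6,
        )
        res = sk.integrate(p, init, sk.Protocol(t_end=1.0, suc_external=0.0))
        mets = res.states[list(sk.STATE_NAMES[:9])].to_numpy()
        assert np.max(np.abs(mets)) < 1e-10

    def test_states_nonnegative_within_tolerance(self, feeding_8h):
        assert feeding_8h.states.to_numpy().min() > -1e-9

    def test_fluxes_recomputed_from_states(self, feeding_3h, params):
        from snrk1kin.odes import reaction_rates

        i = 500
        y = feeding_3h.states.iloc[i].to_numpy()
        r = reaction_rates(y, params, suc_external=15.0)
        assert np.allclose(feeding_3h.fluxes.iloc[i].to_numpy(), r, rtol=1e-12)

    def test_tolerance_halving_changes_endpoint_little(self, params):
        a = sk.integrate(params, protocol=sk.Protocol(t_end=3.0, n_points=10))
        b = sk.integrate(
            params, protocol=sk.Protocol(t_end=3.0, n_points=10),
            rtol=5e-9, atol=5e-13,
        )
        rel = np.abs(a.states.iloc[-1] - b.states.iloc[-1]) / np.maximum(
            np.abs(b.states.iloc[-1]), 1e-12
        )
        assert rel.max() < 1e-4

    def test_restartability(self, params):
        """3 h run continued 5 h matches a single 8 h run."""
        first = sk.integrate(params, protocol=sk.Protocol(t_end=3.0))
        mid = first.final_state()
        cont = sk.integrate(
            params, mid, sk.Protocol(3.0, 8.0, 15.0, onset=0.0, n_points=200)
        )
        full = sk.integrate(params, protocol=sk.Protocol(0.0, 8.0, 15.0, n_points=200))
        end_a = cont.states.iloc[-1].to_numpy()
        end_b = full.states.iloc[-1].to_numpy()
        rel = np.abs(end_a - end_b) / np.maximum(np.abs(end_b), 1e-15)
        assert rel.max() < 1e-6

    def test_solver_failure_reports_last_time(self, params, monkeypatch):
        import snrk1kin.simulate as sim

        class FailedSol:
            success = False
            t = np.array([0.0, 0.125])
            message = "step size became too small"

        monkeypatch.setattr(sim, "solve_ivp", lambda *a, **k: FailedSol())
        with pytest.raises(RuntimeError, match="failed at t = 0.125"):
            sk.integrate(params, protocol=sk.Protocol(t_end=3.0))


class TestFeedingDynamics:
    """Qualitative behaviour of the shipped default parameterization."""

    def test_fast_sps_activation_crossing(self, feeding_8h):
        """E_act overtakes E_inact within 0.01 h of feeding onset."""
        res = sk.integrate(
            feeding_8h.params,
            protocol=sk.Protocol(t_end=0.02, n_points=2000),
        )
        t_cross = sk.activation_crossing_time(res)
        assert 0.0 < t_cross < 0.01

    def test_hexoses_linear_sugars_saturating(self, feeding_8h):
        t = feeding_8h.time
        for hexose in ("Glc", "Fru"):
            r2 = linear_r2(t, feeding_8h.states[hexose], 1.0, 8.0)
            assert r2 > 0.99, hexose
        for saturating in ("Suc", "T6P"):
            y = feeding_8h.states[saturating].to_numpy()[t >= 1.0]
            assert np.all(np.diff(y, 2) < 0), saturating

    def test_metabolites_bounded_except_hexoses(self, feeding_8h):
        bounded = ["F6P", "G6P", "G1P", "UDPG", "T6P", "Tre", "Suc"]
        assert feeding_8h.states[bounded].to_numpy().max() < 20.0


class TestCrossingTime:
    def test_already_crossed_returns_zero(self, params, feeding_3h):
        res = sk.integrate(
            params,
            sk.default_initial_state(active_fraction=0.5),
            sk.Protocol(t_end=0.01, n_points=50),
        )
        assert sk.activation_crossing_time(res) == 0.0
        res2 = sk.integrate(
            params,
            sk.default_initial_state(active_fraction=0.7),
            sk.Protocol(t_end=0.01, n_points=50),
        )
        assert sk.activation_crossing_time(res2) == 0.0

    def test_no_crossing_raises(self, params):
        p = params.update(validate=False, vmax_pp=0.2)
        res = sk.integrate(p, protocol=sk.Protocol(t_end=0.001, n_points=20))
        with pytest.raises(ValueError, match="never"):
            sk.activation_crossing_time(res)


class TestPhasePlane:
    def test_t6p_vs_suc_monotone_curve(self, feeding_3h):
        curve = sk.t6p_vs_suc(feeding_3h)
        assert list(curve.columns) == ["Suc", "T6P"]
        assert np.all(np.diff(curve.Suc) > 0)
        assert np.all(np.diff(curve.T6P) > 0)

    def test_t6p_curvature_decreases_at_high_suc(self, feeding_8h):
        """Convex-then-linear: T6P rises steeply with Suc first, then the
        slope settles (second differences fall towards zero)."""
        curve = sk.t6p_vs_suc(feeding_8h)
        suc = curve.Suc.to_numpy()
        t6p = np.interp(
            np.linspace(suc[0], suc[-1], 200), suc, curve.T6P.to_numpy()
        )
        d2 = np.diff(t6p, 2)
        early = np.abs(d2[:50]).mean()
        late = np.abs(d2[-50:]).mean()
        assert late < early


class TestProtocolValidation:
    def test_bad_span_rejected(self):
        with pytest.raises(ValueError):
            sk.Protocol(t_start=1.0, t_end=0.5)

    def test_negative_supply_rejected(self):
        with pytest.raises(ValueError):
            sk.Protocol(suc_external=-1.0)
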