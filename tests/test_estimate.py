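"""Synthetic-data generation and simplex parameter recovery."""

import numpy as np
import pytest

import snrk1kin as sk
from snrk1kin.estimate import (
    PENALTY,
    read_timecourse_csv,
    write_timecourse_csv,
)

FREE = ("vmax_inv", "vmax_glck", "v_cfbpase")


@pytest.fixture(scope="module")
def clean_data(params):
    return sk.generate_synthetic_timecourse(params, noise_cv=0.0)


class TestGenerator:
    def test_noiseless_matches_simulation(self, params, clean_data):
        res = sk.integrate(params, protocol=sk.Protocol(t_end=3.0))
        suc = np.interp(clean_data.times, res.time, res.states["Suc"].to_numpy())
        j = clean_data.species.index("Suc")
        assert np.allclose(clean_data.values[:, j], suc, rtol=1e-9)

    def test_same_seed_reproducible(self, params):
        a = sk.generate_synthetic_timecourse(params, noise_cv=0.1, seed=7)
        b = sk.generate_synthetic_timecourse(params, noise_cv=0.1, seed=7)
        assert np.array_equal(a.values, b.values)
        c = sk.generate_synthetic_timecourse(params, noise_cv=0.1, seed=8)
        assert not np.array_equal(a.values, c.values)

    def test_noise_model_is_mean_one(self, params, clean_data):
        """Mean of replicates at cv = 0.1 stays within 2% of the
        noiseless value per point (lognormal noise has unit mean)."""
        reps = [
            sk.generate_synthetic_timecourse(params, noise_cv=0.1, seed=s).values
            for s in range(500)
        ]
        mean = np.mean(reps, axis=0)
        ref = clean_data.values
        mask = ref > 1e-9
        assert np.max(np.abs(mean[mask] - ref[mask]) / ref[mask]) < 0.02

    def test_negative_cv_rejected(self, params):
        with pytest.raises(ValueError):
            sk.generate_synthetic_timecourse(params, noise_cv=-0.1)

    def test_csv_round_trip(self, tmp_path, clean_data):
        path = tmp_path / "tc.csv"
        write_timecourse_csv(clean_data, str(path))
        back = read_timecourse_csv(str(path))
        assert back.species == clean_data.species
        assert np.allclose(back.values, clean_data.values)
        assert np.allclose(back.times, clean_data.times)


class TestObjective:
    def test_zero_at_generating_parameters(self, params, clean_data):
        assert sk.objective(params, clean_data, FREE) < 1e-8

    def test_nonnegative(self, params, clean_data):
        p2 = params.update(vmax_inv=params.vmax_inv * 1.5)
        assert sk.objective(p2, clean_data, FREE) > 0

    @pytest.mark.parametrize("name", FREE)
    def test_local_identifiability(self, params, clean_data, name):
        """Perturbing any free parameter away from the generating value
        strictly increases the objective on noiseless data."""
        for factor in (0.7, 1.4):
            p2 = params.update(validate=False, **{name: params[name] * factor})
            assert sk.objective(p2, clean_data, FREE) > 1e-6

    def test_bound_violation_maps_to_penalty(self, params, clean_data):
        lo, hi = params.bounds("vmax_inv")
        p2 = params.update(validate=False, vmax_inv=hi * 10)
        assert sk.objective(p2, clean_data, FREE) >= PENALTY


class TestFitSimplex:
    def test_init_at_truth_converges_immediately(self, params, clean_data):
        res = sk.fit_simplex(clean_data, params, FREE, max_iterations=200)
        assert res.objective_value < 1e-6

    def test_degenerate_bounds_pin_parameter(self, params, clean_data):
        import snrk1kin.params as P

        target = params["vmax_inv"] * 1.1
        bounds = {n: params.bounds(n) for n in params.names()}
        bounds["vmax_inv"] = (target, target)
        values = dict(params.as_dict(), vmax_inv=target)
        pinned = P.ParameterSet(values, bounds, validate=False)
        res = sk.fit_simplex(clean_data, pinned, ("vmax_inv",))
        assert res.params["vmax_inv"] == target

    def test_recovery_from_perturbed_start_noiseless(self, params, clean_data):
        """3 free parameters displaced 2x from truth are recovered within
        10% relative on noiseless synthetic data."""
        start = params.update(
            vmax_inv=params.vmax_inv * 2.0,
            vmax_glck=params.vmax_glck * 0.5,
            v_cfbpase=params.v_cfbpase * 2.0,
        )
        res = sk.fit_simplex(clean_data, start, FREE, max_iterations=200)
        for name in FREE:
            rel = abs(res.params[name] - params[name]) / params[name]
            assert rel < 0.10, (name, rel, res.params[name])

    def test_column_order_invariance(self, params, clean_data):
        shuffled = sk.TimeCourseData(
            times=clean_data.times,
            species=tuple(reversed(clean_data.species)),
            values=clean_data.values[:, ::-1].copy(),
        )
        start = params.update(vmax_inv=params.vmax_inv * 1.6)
        a = sk.fit_simplex(clean_data, start, ("vmax_inv",), max_iterations=150)
        b = sk.fit_simplex(shuffled, start, ("vmax_inv",), max_iterations=150)
        assert a.params["vmax_inv"] == pytest.approx(b.params["vmax_inv"], rel=1e-6)

    def test_empty_free_names_rejected(self, params, clean_data):
        with pytest.raises(ValueError, match="nonempty"):
            sk.fit_simplex(clean_data, params, ())
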