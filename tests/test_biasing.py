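import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cectrack as ct
from cectrack.biasing import (
    KB_KCAL_PER_MOL_K,
    BiasState,
    DoubleWell,
    FlatPotential,
    deposit_hill,
    evaluate_bias,
    metad_double_well_demo,
    run_toy_metad,
    softmin,
    xi_atom_gradient,
    xi_cv,
)
from cectrack.calibration import _glu_pair_frame
from cectrack.errors import GeometryError

finite_dist = st.floats(min_value=0.0, max_value=1e6, allow_nan=False)


class TestSoftmin:
    def test_equal_arguments_closed_form(self):
        for d in (0.5, 2.0, 7.3):
            assert softmin(d, d, 40.0) == pytest.approx(d - np.log(2) / 40.0, abs=1e-14)

    def test_distant_branch_negligible(self):
        # d1 = 2, d2 = 5: correction is ln(1 + e^-120)/40 ~ 1e-54
        assert softmin(2.0, 5.0, 40.0) == pytest.approx(2.0, abs=1e-12)

    def test_huge_arguments_do_not_overflow(self):
        assert np.isfinite(softmin(1e300, 1e300, 40.0))
        assert softmin(1e6, 0.5, 40.0) == pytest.approx(0.5, abs=1e-12)

    @given(d1=finite_dist, d2=finite_dist)
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_bounds(self, d1, d2):
        sm = softmin(d1, d2, 40.0)
        m = min(d1, d2)
        assert m - np.log(2) / 40.0 - 1e-12 <= sm <= m + 1e-12

    @given(d1=st.floats(0.1, 10.0), d2=st.floats(0.1, 10.0), shift=st.floats(0.01, 1.0))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_monotone_in_both_arguments(self, d1, d2, shift):
        assert softmin(d1 + shift, d2, 40.0) >= softmin(d1, d2, 40.0) - 1e-12
        assert softmin(d1, d2 + shift, 40.0) >= softmin(d1, d2, 40.0) - 1e-12


class TestXiCv:
    def test_equidistant_symmetric(self):
        cec = np.array([0.0, 1.0, 0.0])
        o1 = np.array([-1.0, 0.0, 0.0])
        o2 = np.array([1.0, 0.0, 0.0])
        d = np.sqrt(2.0)
        val, g = xi_cv(cec, o1, o2, 40.0)
        assert val == pytest.approx(d - np.log(2) / 40.0, abs=1e-12)
        # mirror symmetry through the yz-plane: equal weights on both oxygens
        assert g["o1"][0] == pytest.approx(-g["o2"][0], abs=1e-12)
        assert g["o1"][1] == pytest.approx(g["o2"][1], abs=1e-12)
        assert g["cec"][0] == pytest.approx(0.0, abs=1e-12)

    def test_near_branch_dominates(self):
        val, g = xi_cv([0, 0, 0], [1.0, 0, 0], [6.0, 0, 0], 40.0)
        assert val == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(g["cec"], [-1.0, 0, 0], atol=1e-12)

    def test_gradients_sum_to_zero(self, rng):
        for _ in range(10):
            cec, o1, o2 = rng.normal(size=(3, 3)) * 3
            _, g = xi_cv(cec, o1, o2, 40.0)
            assert np.allclose(g["cec"] + g["o1"] + g["o2"], 0.0, atol=1e-12)

    def test_finite_difference(self, rng):
        cec = np.array([0.3, 0.1, -0.2])
        o1 = np.array([1.2, 0.0, 0.4])
        o2 = np.array([1.5, 0.3, -0.2])
        val, g = xi_cv(cec, o1, o2, 40.0)
        eps = 1e-6
        for key, point in (("cec", cec), ("o1", o1), ("o2", o2)):
            for b in range(3):
                num = 0.0
                for sgn in (+1, -1):
                    p = {"cec": cec.copy(), "o1": o1.copy(), "o2": o2.copy()}
                    p[key][b] += sgn * eps
                    v, _ = xi_cv(p["cec"], p["o1"], p["o2"], 40.0)
                    num += sgn * v / (2 * eps)
                assert abs(num - g[key][b]) < 1e-6 * max(abs(num), 1.0)

    def test_coincident_points_error(self):
        with pytest.raises(GeometryError):
            xi_cv([1.0, 0, 0], [1.0, 0, 0], [3.0, 0, 0])

    def test_atom_gradient_matches_finite_differences(self, params, charges):
        acid = ct.AcidSpec(oxygens=(1, 2), carbon=0, label="glu")
        fr = _glu_pair_frame(2.5, 1.0)
        topo = ct.assign_topology(fr, acid=acid)
        ss = ct.enumerate_states(fr, topo, acid=acid)
        from cectrack.cec_core import compute_cec, state_weights

        val, grads = xi_atom_gradient(fr, ss, params, charges, 1, 2)
        eps = 1e-6
        for atom in grads:
            for b in range(3):
                num = 0.0
                for sgn in (+1, -1):
                    f2 = ct.Frame(list(fr.elements), fr.positions.copy())
                    f2.positions[atom, b] += sgn * eps
                    t2 = ct.assign_topology(f2, acid=acid)
                    s2 = ct.enumerate_states(f2, t2, acid=acid)
                    w2 = state_weights(s2, f2, params)
                    r2 = compute_cec(f2, s2, w2, charges)
                    v2, _ = xi_cv(r2.cec, f2.positions[1], f2.positions[2])
                    num += sgn * v2 / (2 * eps)
                assert abs(num - grads[atom][b]) < 1e-6


class TestWellTemperedHills:
    def test_first_hill_has_initial_height(self):
        bias = BiasState()
        deposit_hill(bias, 0.7)
        assert bias.heights == [pytest.approx(0.2)]

    def test_second_hill_damped_by_well_tempered_rule(self):
        bias = BiasState()
        deposit_hill(bias, 0.0)
        deposit_hill(bias, 0.0)
        expected = 0.2 * np.exp(-0.2 / (KB_KCAL_PER_MOL_K * 11 * 300.0))
        assert bias.heights[1] == pytest.approx(expected, rel=1e-12)

    def test_heights_strictly_decreasing_at_fixed_point(self):
        bias = BiasState()
        for _ in range(50):
            deposit_hill(bias, -1.0)
        assert all(a > b for a, b in zip(bias.heights, bias.heights[1:]))

    def test_fixed_point_bias_follows_logarithmic_law(self):
        """Repeated deposits at one point: V_n ~ c ln(1 + n h0 / c)."""
        bias = BiasState()
        c = KB_KCAL_PER_MOL_K * bias.delta_temperature
        n = 2000
        V = 0.0
        for _ in range(n):
            V += bias.height0 * np.exp(-V / c)
        assert V == pytest.approx(c * np.log(1 + n * bias.height0 / c), rel=0.01)
        # deposits through the public API agree with the scalar recursion
        for _ in range(200):
            deposit_hill(bias, 0.0)
        v_api, _ = evaluate_bias(bias, 0.0)
        V200 = 0.0
        for _ in range(200):
            V200 += bias.height0 * np.exp(-V200 / c)
        assert v_api == pytest.approx(V200, rel=1e-9)


class TestEvaluateBias:
    def test_no_hills(self):
        assert evaluate_bias(BiasState(), 1.23) == (0.0, 0.0)

    def test_at_hill_center(self):
        bias = BiasState()
        deposit_hill(bias, 0.5)
        e, de = evaluate_bias(bias, 0.5)
        assert e == pytest.approx(0.2) and de == pytest.approx(0.0, abs=1e-15)

    def test_one_sigma_away_gaussian_calculus(self):
        bias = BiasState(width=0.1)
        deposit_hill(bias, 0.0)
        e, de = evaluate_bias(bias, 0.1)
        assert e == pytest.approx(0.2 * np.exp(-0.5), rel=1e-12)
        assert de == pytest.approx(-0.2 * np.exp(-0.5) / 0.1, rel=1e-12)


class TestToyMetadynamics:
    def test_flat_potential_einstein_relation(self):
        D = 1e-3
        res = run_toy_metad(
            FlatPotential(), BiasState(), n_steps=100_000, dt_fs=1.0, seed=3,
            x0=0.0, diffusion=D, domain=(-50, 50), biased=False,
        )
        x = res.trajectory
        for lag in (500, 1000, 2000):
            msd = np.mean((x[lag:] - x[:-lag]) ** 2)
            assert msd == pytest.approx(2 * D * lag, rel=0.2)

    def test_deterministic_given_seed(self):
        kw = dict(n_steps=5000, dt_fs=1.0, seed=9, diffusion=5e-5)
        a = run_toy_metad(DoubleWell(), BiasState(), **kw)
        b = run_toy_metad(DoubleWell(), BiasState(), **kw)
        assert np.array_equal(a.trajectory, b.trajectory)
        assert a.bias.heights == b.bias.heights

    def test_divergence_reports_step(self):
        steep = DoubleWell(barrier=-5.0)  # inverted potential expels the walker
        with pytest.raises(RuntimeError, match="step"):
            run_toy_metad(steep, BiasState(), n_steps=200_000, seed=0, diffusion=1e-3,
                          domain=(-2.0, 2.0), biased=False)

    def test_biased_run_escapes_well_unbiased_stays(self):
        demo = metad_double_well_demo(
            seed=5, n_steps_biased=150_000, n_steps_unbiased=30_000
        )
        assert demo["range_unbiased"] < 1.6  # trapped around s = -1
        assert demo["range_biased"] > 3.0  # crossed to the other well
        assert demo["range_ratio"] > 3.0
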