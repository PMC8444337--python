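import numpy as np
import pytest

import cectrack as ct
from cectrack.cec_core import (
    CTParams,
    cec_for_frame,
    cec_gradient,
    center_of_charge,
    charge_transfer_factor,
    compute_cec,
    hop_delta,
    state_weights,
)
from cectrack.errors import ConfigurationError
from cectrack.fixtures import _proton_pair_frame
from cectrack.topology_states import Hop, assign_topology, enumerate_states
from conftest import jitter_frame

H3O = CTParams("h3o-water", k=4.234, delta0=0.0)
GLU = CTParams("glu-water", k=2.946, delta0=0.5361)


def pair_frame_with_delta(delta, r_oo=2.6):
    """Collinear hydronium-water pair whose single hop has the given delta."""
    return _proton_pair_frame(r_oo, (r_oo + delta) / 2.0)


class TestHopDelta:
    def test_value_and_sign_convention(self):
        fr = pair_frame_with_delta(-0.5, r_oo=2.5)  # r(H,donor)=1.0, r(H,acceptor)=1.5
        hop = Hop(donor_o=0, shared_h=1, acceptor_o=4, pair_kind="h3o-water")
        assert hop_delta(fr, hop) == pytest.approx(-0.5, abs=1e-12)

    def test_midpoint_is_zero(self):
        fr = pair_frame_with_delta(0.0)
        hop = Hop(donor_o=0, shared_h=1, acceptor_o=4, pair_kind="h3o-water")
        assert hop_delta(fr, hop) == pytest.approx(0.0, abs=1e-12)

    def test_antisymmetric_under_label_swap(self):
        fr = pair_frame_with_delta(-0.3)
        fwd = Hop(donor_o=0, shared_h=1, acceptor_o=4, pair_kind="h3o-water")
        rev = Hop(donor_o=4, shared_h=1, acceptor_o=0, pair_kind="h3o-water")
        assert hop_delta(fr, fwd) == pytest.approx(-hop_delta(fr, rev), abs=1e-12)


class TestChargeTransferFactor:
    @pytest.mark.parametrize("params", [H3O, GLU, CTParams("h3o-water", 4.898, 0.0)])
    def test_unity_at_delta0(self, params):
        assert charge_transfer_factor(params.delta0, params) == pytest.approx(1.0, abs=1e-15)

    def test_closed_form(self):
        # exp(4.234 * (-0.3)) = exp(-1.2702)
        assert charge_transfer_factor(-0.3, H3O) == pytest.approx(np.exp(-1.2702), rel=1e-12)

    def test_monotone_and_clipped(self):
        ds = np.linspace(-30, 30, 101)
        fs = [charge_transfer_factor(d, H3O) for d in ds]
        assert all(b >= a for a, b in zip(fs, fs[1:]))
        assert np.isfinite(fs[-1]) and fs[-1] <= np.exp(50.0)


class TestStateWeights:
    def params(self):
        return {"h3o-water": H3O}

    def test_equal_sharing_splits_half_half(self):
        fr = pair_frame_with_delta(0.0)
        topo = assign_topology(fr)
        ss = enumerate_states(fr, topo)
        w = state_weights(ss, fr, self.params())
        assert np.allclose(w, [0.5, 0.5], atol=1e-12)

    def test_factor_one_quarter_gives_four_to_one(self):
        delta = np.log(0.25) / H3O.k  # f_CT = 0.25 exactly
        fr = pair_frame_with_delta(delta)
        topo = assign_topology(fr)
        ss = enumerate_states(fr, topo)
        w = state_weights(ss, fr, self.params())
        assert np.allclose(w, [0.8, 0.2], atol=1e-12)

    def test_linear_chain_with_unit_factors_shares_equally(self):
        # three-molecule wire, both shared protons exactly at their midpoints
        r = 2.6
        elements = ["O", "H", "H", "H", "O", "H", "H", "O", "H", "H"]
        pos = np.array(
            [
                [0, 0, 0], [-0.97, 0, 0], [0, 0.97, 0], [r / 2, 0, 0],
                [r, 0, 0], [r, -0.97, 0], [1.5 * r, 0, 0],
                [2 * r, 0, 0], [2 * r, 0.97, 0], [2 * r + 0.6, 0.75, 0],
            ]
        )
        fr = ct.Frame(elements, pos)
        topo = assign_topology(fr)
        assert topo.root_species.label == "hydronium"
        ss = enumerate_states(fr, topo)
        w = state_weights(ss, fr, self.params())
        assert len(ss) == 3
        assert np.allclose(w, [1 / 3] * 3, atol=1e-12)

    def test_missing_pair_kind_is_config_error(self):
        fr = pair_frame_with_delta(0.0)
        topo = assign_topology(fr)
        ss = enumerate_states(fr, topo)
        with pytest.raises(ConfigurationError, match="h3o-water"):
            state_weights(ss, fr, {})

    def test_brute_force_path_product_oracle(self, network_frame, params):
        """Weights match an independent recursive path-product enumeration."""
        topo = assign_topology(network_frame)
        ss = enumerate_states(network_frame, topo, max_shell=2)
        w = state_weights(ss, network_frame, params)

        # independent oracle: recursive search over H...O contacts
        fr = network_frame
        k = params["h3o-water"].k
        o_idx = [i for i, e in enumerate(fr.elements) if e == "O"]
        h_of = {o: [] for o in o_idx}
        h_idx = [i for i, e in enumerate(fr.elements) if e == "H"]
        for h in h_idx:
            o = min(o_idx, key=lambda o: np.linalg.norm(fr.positions[h] - fr.positions[o]))
            h_of[o].append(h)
        root = next(o for o in o_idx if len(h_of[o]) == 3)

        products = []

        def recurse(o_cur, hs, product, depth, visited, banned):
            products.append(product)
            if depth == 2:
                return
            for h in hs:
                for o_new in o_idx:
                    if o_new in visited or (h, o_new) == banned:
                        continue
                    d_acc = np.linalg.norm(fr.positions[h] - fr.positions[o_new])
                    if d_acc <= 2.5:
                        d_don = np.linalg.norm(fr.positions[h] - fr.positions[o_cur])
                        f = np.exp(k * (d_don - d_acc))
                        recurse(
                            o_new,
                            h_of[o_new] + [h],
                            product * f,
                            depth + 1,
                            visited | {o_new},
                            (h, o_cur),
                        )

        recurse(root, h_of[root], 1.0, 0, {root}, None)
        oracle = np.array(sorted(products)) / np.sum(products)
        assert len(oracle) == len(w)
        assert np.allclose(np.sort(w), oracle, atol=1e-12)


class TestCenterOfCharge:
    def test_charge_on_hydrogens_gives_their_centroid(self):
        fr = _proton_pair_frame(2.8, 0.97)
        topo = assign_topology(fr)
        ss = enumerate_states(fr, topo, max_shell=0)
        table = {"hydronium": {"O": 0.0, "H": 1.0 / 3.0}}
        coc = center_of_charge(fr, ss.root, table)
        hs = list(topo.root_species.h_atoms)
        assert np.allclose(coc, fr.positions[hs].mean(axis=0), atol=1e-12)

    def test_all_charge_on_one_atom(self):
        fr = _proton_pair_frame(2.8, 0.97)
        ss = enumerate_states(fr, assign_topology(fr), max_shell=0)
        table = {"hydronium": {"O": 1.0, "H": 0.0}}
        coc = center_of_charge(fr, ss.root, table)
        assert np.allclose(coc, fr.positions[0], atol=1e-12)

    def test_symmetric_hydronium_coc_on_axis(self):
        # planar C3 hydronium: equal H charges put the COC on the O position
        pos = [[0, 0, 0]]
        for p in (0, 2 * np.pi / 3, 4 * np.pi / 3):
            pos.append([0.97 * np.cos(p), 0.97 * np.sin(p), 0.0])
        fr = ct.Frame(["O", "H", "H", "H"], np.array(pos))
        ss = enumerate_states(fr, assign_topology(fr), max_shell=0)
        table = {"hydronium": {"O": 0.25, "H": 0.25}}
        coc = center_of_charge(fr, ss.root, table)
        assert np.allclose(coc, [0, 0, 0], atol=1e-12)


class TestComputeCec:
    def test_single_state_equals_coc(self, params, charges):
        fr = _proton_pair_frame(5.0, 0.97)
        ss = enumerate_states(fr, assign_topology(fr))
        assert len(ss) == 1
        res = compute_cec(fr, ss, np.array([1.0]), charges)
        assert np.allclose(res.cec, center_of_charge(fr, ss.root, charges), atol=1e-12)

    def test_symmetric_zundel_on_bisecting_plane(self, params, charges):
        fr = pair_frame_with_delta(0.0, r_oo=2.6)
        res, _ = cec_for_frame(fr, params, charges)
        assert res.cec[0] == pytest.approx(1.3, abs=1e-9)

    def test_two_state_weighted_average(self, charges):
        delta = np.log(0.25) / H3O.k
        fr = pair_frame_with_delta(delta)
        ss = enumerate_states(fr, assign_topology(fr))
        w = np.array([0.8, 0.2])
        res = compute_cec(fr, ss, w, charges)
        cocs = [center_of_charge(fr, s, charges) for s in ss]
        assert np.allclose(res.cec, 0.8 * cocs[0] + 0.2 * cocs[1], atol=1e-12)

    def test_normalization_and_conservation_on_random_frames(self, shuttle_series, params, charges, rng):
        base = [shuttle_series[i] for i in rng.integers(0, len(shuttle_series), 25)]
        for frame in base:
            f = jitter_frame(frame, rng, scale=0.02)
            res, _ = cec_for_frame(f, params, charges)
            assert abs(res.weights.sum() - 1.0) < 1e-12
            assert abs(sum(res.per_atom_excess.values()) - 1.0) < 1e-9

    def test_dipole_equals_cec_times_unit_charge(self, shuttle_series, params, charges, rng):
        for i in (0, 10, 25, 40):
            f = jitter_frame(shuttle_series[i], rng, scale=0.01)
            res, _ = cec_for_frame(f, params, charges)
            assert np.abs(res.dipole - res.cec).max() < 1e-9

    def test_locality_far_atom_changes_nothing(self, params, charges):
        net = ct.make_ideal_network()
        water = np.array([[20.0, 0, 0], [20.97, 0, 0], [19.7, 0.92, 0]])
        fr = ct.Frame(net.elements + ["O", "H", "H"], np.vstack([net.positions, water]))
        res1, _ = cec_for_frame(fr, params, charges)
        moved = fr.positions.copy()
        moved[-3:] += np.array([5.0, 3.0, -2.0])
        res2, _ = cec_for_frame(ct.Frame(list(fr.elements), moved), params, charges)
        assert np.array_equal(res1.cec, res2.cec)

    def test_continuity_along_shuttle(self, shuttle_series, params, charges):
        prev_cec, prev_pos = None, None
        for f in shuttle_series:
            res, _ = cec_for_frame(f, params, charges)
            if prev_cec is not None:
                cec_step = np.linalg.norm(res.cec - prev_cec)
                atom_step = np.abs(f.positions - prev_pos).max()
                assert cec_step <= 10.0 * atom_step + 1e-12
            prev_cec, prev_pos = res.cec, f.positions


class TestGradient:
    def finite_difference(self, frame, atoms, params, charges, eps=1e-5):
        num = {}
        for a in atoms:
            J = np.zeros((3, 3))
            for b in range(3):
                for sgn in (+1, -1):
                    f2 = ct.Frame(list(frame.elements), frame.positions.copy())
                    f2.positions[a, b] += sgn * eps
                    r2, _ = cec_for_frame(f2, params, charges)
                    J[:, b] += sgn * r2.cec / (2 * eps)
            num[a] = J
        return num

    def test_single_state_jacobian_is_charge_fraction(self, params, charges):
        fr = _proton_pair_frame(5.0, 0.97)
        ss = enumerate_states(fr, assign_topology(fr))
        grads = cec_gradient(fr, ss, params, charges)
        q = charges["hydronium"]
        for a, role in zip(ss.root.species.atoms, ss.root.species.roles):
            assert np.allclose(grads[a], q[role] * np.eye(3), atol=1e-12)

    @pytest.mark.parametrize("delta", [-0.4, -0.05, 0.0, 0.05])
    def test_matches_finite_differences_incl_near_crossing(self, delta, params, charges):
        fr = pair_frame_with_delta(delta)
        ss = enumerate_states(fr, assign_topology(fr))
        grads = cec_gradient(fr, ss, params, charges)
        num = self.finite_difference(fr, list(grads), params, charges)
        for a in grads:
            scale = max(np.abs(num[a]).max(), 1.0)
            assert np.abs(grads[a] - num[a]).max() / scale < 1e-6

    def test_matches_finite_differences_on_network(self, network_frame, params, charges):
        topo = assign_topology(network_frame)
        ss = enumerate_states(network_frame, topo)
        grads = cec_gradient(network_frame, ss, params, charges)
        probe = list(grads)[:6]
        num = self.finite_difference(network_frame, probe, params, charges)
        for a in probe:
            scale = max(np.abs(num[a]).max(), 1.0)
            assert np.abs(grads[a] - num[a]).max() / scale < 1e-6

    def test_blocks_sum_to_identity(self, network_frame, params, charges):
        ss = enumerate_states(network_frame, assign_topology(network_frame))
        grads = cec_gradient(network_frame, ss, params, charges)
        assert np.allclose(sum(grads.values()), np.eye(3), atol=1e-9)
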