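"""Mass-spring-damper relaxation and its least-squares oracles."""

import numpy as np
import pytest

from msemstitch.model import OverlapPair
from msemstitch.registration import (
    MsdParams,
    default_anchor,
    integrate_msd,
    msd_derivative,
    registration_report,
    residuals,
    solve_least_squares,
    spring_stiffness,
)

PARAMS = MsdParams()


def mk_pair(i, j, p, R=1.0):
    return OverlapPair(i, j, p=np.asarray(p, float), R=R)


def grid_instance(seed, n_side, jitter=10.0, p_noise=3.0, r_range=(0.3, 1.0)):
    """Random connected grid-graph instance with noisy pairwise offsets."""
    rng = np.random.default_rng(seed)
    ids = [f"t{i:03d}" for i in range(n_side * n_side)]
    truth = {
        ids[i * n_side + j]: np.array([j * 100.0, i * 100.0])
        for i in range(n_side)
        for j in range(n_side)
    }
    pos = {k: v + rng.normal(size=2) * jitter for k, v in truth.items()}
    pairs = []
    for i in range(n_side):
        for j in range(n_side):
            a = ids[i * n_side + j]
            for b in ([ids[i * n_side + j + 1]] if j + 1 < n_side else []) + (
                [ids[(i + 1) * n_side + j]] if i + 1 < n_side else []
            ):
                pairs.append(
                    mk_pair(a, b, truth[a] - truth[b] + rng.normal(size=2) * p_noise,
                            R=rng.uniform(*r_range))
                )
    return pos, pairs


class TestSpringStiffness:
    @pytest.mark.parametrize("R, expected", [(1.0, 1.0), (0.5, 0.03125), (0.0, 0.0)])
    def test_power_law(self, R, expected):
        assert spring_stiffness(R, PARAMS) == pytest.approx(expected)

    @pytest.mark.parametrize("R", [-0.1, 1.1])
    def test_out_of_range_rejected(self, R):
        with pytest.raises(ValueError):
            spring_stiffness(R, PARAMS)


class TestResiduals:
    def test_perfect_alignment(self):
        pos = {"a": np.array([0.0, 0.0]), "b": np.array([-10.0, 0.0])}
        r, rms = residuals(pos, [mk_pair("a", "b", (10.0, 0.0))])
        assert np.array_equal(r, [[0.0, 0.0]])
        assert rms == 0.0

    def test_single_pair_direct(self):
        pos = {"a": np.array([10.0, 0.0]), "b": np.array([0.0, 0.0])}
        r, rms = residuals(pos, [mk_pair("a", "b", (7.0, 0.0))])
        assert np.array_equal(r, [[3.0, 0.0]])
        assert rms == pytest.approx(3.0)

    def test_matches_naive_loop_oracle(self):
        rng = np.random.default_rng(8)
        pos, pairs = grid_instance(8, 4)
        r, rms = residuals(pos, pairs)
        acc = [pos[pr.tile_i] - pos[pr.tile_j] - pr.p for pr in pairs]
        assert np.allclose(r, acc)
        assert rms == pytest.approx(np.sqrt(np.mean([v @ v for v in acc])))

    def test_unknown_tile_rejected(self):
        with pytest.raises(KeyError):
            residuals({"a": np.zeros(2)}, [mk_pair("a", "zz", (0.0, 0.0))])


class TestMsdDerivative:
    def test_single_spring_to_anchor(self):
        pos = {"a": np.array([0.0, 0.0]), "b": np.array([3.0, 4.0])}
        vel = {k: np.zeros(2) for k in pos}
        _, acc = msd_derivative(pos, vel, [mk_pair("a", "b", (0.0, 0.0))], PARAMS, "a")
        assert np.allclose(acc["b"], [-3.0, -4.0])
        assert np.array_equal(acc["a"], [0.0, 0.0])

    def test_zero_stiffness_is_pure_damping(self):
        pos = {"a": np.zeros(2), "b": np.array([50.0, 0.0])}
        vel = {"a": np.zeros(2), "b": np.array([2.0, -4.0])}
        _, acc = msd_derivative(pos, vel, [mk_pair("a", "b", (0.0, 0.0), R=0.0)], PARAMS, "a")
        assert np.allclose(acc["b"], -PARAMS.c / PARAMS.m * vel["b"])

    def test_newtons_third_law(self):
        # anchor "d" carries no spring, so action-reaction sums to zero
        # over the three spring-bearing tiles
        pos = {
            "a": np.array([1.0, 2.0]),
            "b": np.array([40.0, -3.0]),
            "c": np.array([10.0, 50.0]),
            "d": np.array([500.0, 500.0]),
        }
        vel = {k: np.zeros(2) for k in pos}
        pairs = [mk_pair("a", "b", (-30.0, 0.0), 0.8), mk_pair("b", "c", (25.0, -55.0), 0.6)]
        _, acc = msd_derivative(pos, vel, pairs, PARAMS, anchor_tile="d")
        assert np.allclose(acc["a"] + acc["b"] + acc["c"], [0.0, 0.0], atol=1e-12)


class TestIntegrateMsd:
    def test_single_spring_reaches_rest_length(self):
        pos = {"a": np.zeros(2), "b": np.zeros(2)}
        state = integrate_msd(pos, [mk_pair("a", "b", (10.0, 0.0))], anchor_tile="a")
        assert state.converged
        offset = state.positions["a"] - state.positions["b"]
        assert np.allclose(offset, [10.0, 0.0], atol=1e-3)
        assert state.rms_trace[-1][1] < 1e-3

    def test_inconsistent_triangle_matches_normal_equations(self):
        pos = {"a": np.zeros(2), "b": np.array([10.0, 0.0]), "c": np.array([10.0, 10.0])}
        pairs = [
            mk_pair("a", "b", (-10.0, 0.0), 0.9),
            mk_pair("b", "c", (0.0, -10.0), 0.7),
            mk_pair("a", "c", (-13.0, -12.0), 0.5),
        ]
        state = integrate_msd(pos, pairs, anchor_tile="a")
        # closed-form weighted normal equations, b and c free (dense oracle)
        w = [spring_stiffness(pr.R, PARAMS) for pr in pairs]
        A = np.array([[w[0] + w[1], -w[1]], [-w[1], w[1] + w[2]]])
        rhs_x = np.array(
            [w[0] * (pos["a"][0] - pairs[0].p[0]) + w[1] * pairs[1].p[0],
             w[2] * (pos["a"][0] - pairs[2].p[0]) - w[1] * pairs[1].p[0]]
        )
        rhs_y = np.array(
            [w[0] * (pos["a"][1] - pairs[0].p[1]) + w[1] * pairs[1].p[1],
             w[2] * (pos["a"][1] - pairs[2].p[1]) - w[1] * pairs[1].p[1]]
        )
        bx, cx = np.linalg.solve(A, rhs_x)
        by, cy = np.linalg.solve(A, rhs_y)
        assert np.allclose(state.positions["b"], [bx, by], atol=1e-3)
        assert np.allclose(state.positions["c"], [cx, cy], atol=1e-3)

    def test_consistent_graph_recovers_exactly(self):
        truth = {"a": np.zeros(2), "b": np.array([100.0, 0.0]), "c": np.array([50.0, 90.0])}
        rng = np.random.default_rng(3)
        start = {k: v + rng.normal(size=2) * 8 for k, v in truth.items()}
        start["a"] = truth["a"]
        pairs = [
            mk_pair("a", "b", truth["a"] - truth["b"]),
            mk_pair("b", "c", truth["b"] - truth["c"]),
            mk_pair("a", "c", truth["a"] - truth["c"]),
        ]
        state = integrate_msd(start, pairs, anchor_tile="a")
        for k in truth:
            assert np.allclose(state.positions[k], truth[k], atol=1e-3)

    def test_zero_stiffness_limit_keeps_positions(self):
        pos = {"a": np.zeros(2), "b": np.array([37.0, -4.0])}
        pairs = [mk_pair("a", "b", (10.0, 0.0), R=0.0)]
        state = integrate_msd(pos, pairs, anchor_tile="a")
        assert np.array_equal(state.positions["b"], pos["b"])

    def test_gauge_shift_equivariance(self):
        pos, pairs = grid_instance(5, 3)
        base = integrate_msd(pos, pairs)
        shift = np.array([1234.0, -777.0])
        moved = integrate_msd({k: v + shift for k, v in pos.items()}, pairs)
        for k in pos:
            assert np.allclose(moved.positions[k], base.positions[k] + shift, atol=1e-6)

    def test_energy_dissipation_and_rms_improvement(self):
        pos, pairs = grid_instance(6, 4)
        state = integrate_msd(pos, pairs)
        energy = [e for _, e in state.energy_trace]
        tol = 1e-6 * max(energy)
        assert all(b <= a + tol for a, b in zip(energy, energy[1:]))
        assert state.rms_trace[-1][1] <= state.rms_trace[0][1]

    def test_anchor_never_moves(self):
        pos, pairs = grid_instance(7, 3)
        anchor = sorted(pos)[0]
        state = integrate_msd(pos, pairs, anchor_tile=anchor)
        assert np.array_equal(state.positions[anchor], pos[anchor])
        assert np.array_equal(state.velocities[anchor], [0.0, 0.0])


class TestSolveLeastSquares:
    def test_consistent_chain_exact(self):
        pos = {"a": np.zeros(2), "b": np.array([93.0, 1.0]), "c": np.array([188.0, 5.0])}
        pairs = [mk_pair("a", "b", (-94.0, 0.0)), mk_pair("b", "c", (-94.0, 0.0))]
        out = solve_least_squares(pos, pairs, weighted=False, anchor_tile="a")
        assert np.allclose(out["b"], [94.0, 0.0])
        assert np.allclose(out["c"], [188.0, 0.0])
        _, rms = residuals(out, pairs)
        assert rms == pytest.approx(0.0, abs=1e-9)

    def test_uniform_weights_match_unweighted(self):
        pos, pairs = grid_instance(9, 4, r_range=(0.77, 0.77))
        w = solve_least_squares(pos, pairs, weighted=True)
        u = solve_least_squares(pos, pairs, weighted=False)
        for k in pos:
            assert np.allclose(w[k], u[k], atol=1e-8)

    def test_two_tile_single_equation(self):
        pos = {"a": np.array([5.0, 6.0]), "b": np.array([0.0, 0.0])}
        out = solve_least_squares(pos, [mk_pair("a", "b", (-70.0, 3.0))], anchor_tile="a")
        assert np.allclose(out["b"], pos["a"] - np.array([-70.0, 3.0]))

    def test_disconnected_component_is_hard_error(self):
        pos = {"a": np.zeros(2), "b": np.array([10.0, 0.0]), "z": np.array([900.0, 0.0])}
        with pytest.raises(ValueError, match="disconnected"):
            solve_least_squares(pos, [mk_pair("a", "b", (-10.0, 0.0))], anchor_tile="a")

    def test_msd_matches_weighted_ls(self):
        pos, pairs = grid_instance(10, 5)
        state = integrate_msd(pos, pairs)
        ls = solve_least_squares(pos, pairs, weighted=True)
        for k in pos:
            assert np.allclose(state.positions[k], ls[k], atol=0.5)


class TestRegistrationReport:
    def test_identity_zero_reduction(self):
        pos, pairs = grid_instance(11, 3)
        rep = registration_report(pos, pos, pairs)
        assert rep["reduction_pct"] == pytest.approx(0.0)

    def test_perfect_registration_full_reduction(self):
        truth = {"a": np.zeros(2), "b": np.array([80.0, 0.0])}
        start = {"a": np.zeros(2), "b": np.array([70.0, 4.0])}
        pairs = [mk_pair("a", "b", truth["a"] - truth["b"])]
        rep = registration_report(start, truth, pairs)
        assert rep["reduction_pct"] == pytest.approx(100.0)

    def test_reduction_matches_recomputation(self):
        pos, pairs = grid_instance(12, 4)
        after = solve_least_squares(pos, pairs, weighted=True)
        rep = registration_report(pos, after, pairs)
        _, rms_b = residuals(pos, pairs)
        _, rms_a = residuals(after, pairs)
        assert rep["rms_before"] == pytest.approx(rms_b)
        assert rep["rms_after"] == pytest.approx(rms_a)
        assert rep["reduction_pct"] == pytest.approx(100 * (1 - rms_a / rms_b))
        assert len(rep["pair_table"]) == len(pairs)


def test_default_anchor_is_center_of_first_mfov(mfov61):
    anchor = default_anchor(mfov61.tiles)
    members = [t for t in mfov61.tiles if t.mfov_id == 0]
    centroid = np.mean([t.stage_position for t in members], axis=0)
    dist = {
        t.tile_id: np.linalg.norm(t.stage_position - centroid) for t in members
    }
    assert dist[anchor] == min(dist.values())
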