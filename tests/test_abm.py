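"""Lattice agent-based model: seeding, migration bias, step dynamics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from gliomalatt import abm
from gliomalatt.abm import (
    LatticeState,
    SimulationParams,
    direction_field,
    direction_to_axis_weights,
    initialize_tumor,
    mixed_migration_distribution,
    run_simulation,
    step,
    structure_attraction,
    unit_direction,
)


class TestInitializeTumor:
    @pytest.mark.parametrize(
        "radius, n_voxels",
        [(0, 1), (1, 7), (8, 2109)],
        ids=["point", "radius1", "radius8"],
    )
    def test_sphere_voxel_and_cell_counts(self, radius, n_voxels):
        from gliomalatt.anatomy import generate_synthetic_atlas

        atlas = generate_synthetic_atlas((21, 21, 21), brain="full")
        state = initialize_tumor(atlas, (10, 10, 10), radius, 3, K=3)
        assert (state.counts > 0).sum() == n_voxels
        assert state.n_cells == 3 * n_voxels

    def test_injection_sphere_totals_6327_cells(self, open_atlas):
        state = initialize_tumor(open_atlas, (20, 20, 20), 8, 3, K=3)
        assert state.n_cells == 6327

    def test_no_newborn_flags(self, open_atlas):
        state = initialize_tumor(open_atlas, (20, 20, 20), 2, 3, K=3)
        assert not state.newborn_counts.any()

    def test_out_of_bounds_sphere_rejected(self, open_atlas):
        with pytest.raises(ValueError, match="bounds"):
            initialize_tumor(open_atlas, (2, 20, 20), 8, 3, K=3)

    def test_overfull_seeding_rejected(self, open_atlas):
        with pytest.raises(ValueError, match="capacity"):
            initialize_tumor(open_atlas, (20, 20, 20), 2, 5, K=3)


class TestDirections:
    def test_axis_aligned_unit_direction(self):
        np.testing.assert_allclose(unit_direction((3, 4, 5), (4, 4, 5)), [1, 0, 0])

    def test_diagonal_unit_direction(self):
        np.testing.assert_allclose(
            unit_direction((0, 0, 0), (1, 1, 0)), [1 / np.sqrt(2), 1 / np.sqrt(2), 0]
        )

    def test_coincident_voxels_rejected(self):
        with pytest.raises(ValueError):
            unit_direction((1, 2, 3), (1, 2, 3))

    @pytest.mark.parametrize(
        "v, expected",
        [
            ((1, 0, 0), (1, 0, 0, 0, 0, 0)),
            ((-1, 0, 0), (0, 1, 0, 0, 0, 0)),
            (
                (1 / np.sqrt(2), 1 / np.sqrt(2), 0),
                (1 / np.sqrt(2), 0, 1 / np.sqrt(2), 0, 0, 0),
            ),
        ],
    )
    def test_axis_weight_folding(self, v, expected):
        np.testing.assert_allclose(direction_to_axis_weights(v), expected)

    @settings(derandomize=True, max_examples=50)
    @given(st.tuples(*[st.floats(-1, 1) for _ in range(3)]).filter(
        lambda v: np.linalg.norm(v) > 1e-3))
    def test_axis_weight_slots_never_oppose(self, v):
        u = direction_to_axis_weights(np.asarray(v) / np.linalg.norm(v))
        assert (u >= 0).all()
        assert np.count_nonzero(u) <= 3
        for axis in range(3):
            assert u[2 * axis] == 0 or u[2 * axis + 1] == 0


class TestStructureAttraction:
    def test_no_structure_in_range_falls_back_to_uniform(self):
        mask = np.zeros((11, 11, 11), dtype=bool)
        np.testing.assert_allclose(structure_attraction((5, 5, 5), mask, 3), np.full(6, 1 / 6))

    def test_single_voxel_pulls_along_its_axis(self):
        mask = np.zeros((11, 11, 11), dtype=bool)
        mask[7, 5, 5] = True
        np.testing.assert_allclose(
            structure_attraction((5, 5, 5), mask, 5), [1, 0, 0, 0, 0, 0]
        )

    def test_symmetric_structures_balance(self):
        mask = np.zeros((11, 11, 11), dtype=bool)
        mask[7, 5, 5] = mask[3, 5, 5] = True
        np.testing.assert_allclose(
            structure_attraction((5, 5, 5), mask, 5), [0.5, 0.5, 0, 0, 0, 0]
        )

    def test_own_voxel_and_beyond_radius_excluded(self):
        mask = np.zeros((11, 11, 11), dtype=bool)
        mask[5, 5, 5] = True  # the cell's own voxel
        mask[5, 5, 9] = True  # distance 4 > d = 3
        np.testing.assert_allclose(structure_attraction((5, 5, 5), mask, 3), np.full(6, 1 / 6))

    def test_field_matches_direct_computation(self, rng):
        mask = rng.random((14, 14, 14)) > 0.9
        field = direction_field(mask, 4)
        for pos in [(0, 0, 0), (7, 7, 7), (13, 2, 9), (4, 11, 6)]:
            np.testing.assert_allclose(
                field[pos], structure_attraction(pos, mask, 4), atol=2e-5
            )


class TestMixedDistribution:
    def test_zero_weights_give_uniform(self):
        out = mixed_migration_distribution(np.full(6, 1 / 6), np.full(6, 1 / 6), 0, 0)
        np.testing.assert_allclose(out, np.full(6, 1 / 6))

    def test_full_white_matter_weight_returns_P_wm(self):
        P = np.array([0.5, 0.1, 0.1, 0.1, 0.1, 0.1])
        np.testing.assert_allclose(
            mixed_migration_distribution(P, np.full(6, 1 / 6), 1.0, 0.0), P
        )

    def test_mixture_arithmetic(self):
        P_wm = np.array([1.0, 0, 0, 0, 0, 0])
        P_bv = np.array([0, 1.0, 0, 0, 0, 0])
        out = mixed_migration_distribution(P_wm, P_bv, 0.45, 0.45)
        expected = [0.45 + 1 / 60, 0.45 + 1 / 60, 1 / 60, 1 / 60, 1 / 60, 1 / 60]
        np.testing.assert_allclose(out, expected)

    def test_weight_constraint_enforced(self):
        with pytest.raises(ValueError):
            mixed_migration_distribution(np.full(6, 1 / 6), np.full(6, 1 / 6), 0.6, 0.6)


def _one_cell_state(shape, pos):
    counts = np.zeros(shape, dtype=np.int32)
    counts[pos] = 1
    return LatticeState(counts=counts)


class TestStepDynamics:
    def test_inert_parameters_leave_state_unchanged(self, small_atlas, rng):
        state = initialize_tumor(small_atlas, (12, 12, 12), 2, 3, K=3)
        params = SimulationParams(p_m=0.0, p_p=0.0, seed=5)
        after = step(state, params, small_atlas, rng)
        np.testing.assert_array_equal(after.counts, state.counts)

    def test_deterministic_growth_to_capacity(self, open_atlas):
        # one cell, certain proliferation, no migration: newborns wait one
        # step, so counts go 1 -> 2 -> 3 and then saturate at K = 3
        state = _one_cell_state(open_atlas.shape, (20, 20, 20))
        params = SimulationParams(p_m=0.0, p_p=1.0, K=3, T=3, seed=0)
        res = run_simulation(params, open_atlas, state)
        np.testing.assert_array_equal(res.n_trajectory, [1, 2, 3, 3])

    def test_full_voxel_blocks_birth(self, open_atlas):
        counts = np.zeros(open_atlas.shape, dtype=np.int32)
        counts[20, 20, 20] = 3
        params = SimulationParams(p_m=0.0, p_p=1.0, K=3, T=2, seed=0)
        res = run_simulation(params, open_atlas, LatticeState(counts=counts))
        assert res.state.n_cells == 3

    def test_zero_steps_returns_initial_state(self, small_atlas):
        state = initialize_tumor(small_atlas, (12, 12, 12), 2, 3, K=3)
        params = SimulationParams(p_m=0.5, p_p=0.5, T=0, seed=1)
        res = run_simulation(params, small_atlas, state)
        np.testing.assert_array_equal(res.state.counts, state.counts)

    def test_same_seed_reproduces_final_lattice(self, bench_atlas):
        params = SimulationParams(p_m=0.7, p_p=0.01, w_wm=0.4, w_bv=0.3, T=50, seed=42)
        a = run_simulation(params, bench_atlas, {"radius": 2})
        b = run_simulation(params, bench_atlas, {"radius": 2})
        np.testing.assert_array_equal(a.state.counts, b.state.counts)
        c = run_simulation(
            SimulationParams(p_m=0.7, p_p=0.01, w_wm=0.4, w_bv=0.3, T=50, seed=43),
            bench_atlas, {"radius": 2})
        assert not np.array_equal(a.state.counts, c.state.counts)

    def test_growth_matches_branching_process_oracle(self, open_atlas):
        # with a huge capacity and an open grid each cell births
        # independently with probability p_p, so E[N_T] = N_0 (1 + p_p)^T
        p_p, T, n_seeds = 0.05, 20, 20
        finals = []
        for seed in range(n_seeds):
            state = _one_cell_state(open_atlas.shape, (20, 20, 20))
            counts = state.counts.copy()
            counts[20, 20, 20] = 20
            params = SimulationParams(p_m=0.2, p_p=p_p, K=10**6, T=T, seed=seed)
            res = run_simulation(params, open_atlas, LatticeState(counts=counts))
            finals.append(res.state.n_cells)
        finals = np.asarray(finals, dtype=float)
        expected = 20 * (1 + p_p) ** T
        se = finals.std(ddof=1) / np.sqrt(n_seeds)
        assert abs(finals.mean() - expected) < 3 * se + 1e-9

    def test_unbiased_migration_is_a_symmetric_random_walk(self, open_atlas):
        # 10^4 independent single-step displacements, huge capacity: the six
        # von Neumann directions should be equally likely (chi-square)
        counts = np.zeros(open_atlas.shape, dtype=np.int32)
        counts[20, 20, 20] = 10_000
        params = SimulationParams(p_m=1.0, p_p=0.0, K=10**6, T=1, seed=11)
        res = run_simulation(params, open_atlas, LatticeState(counts=counts))
        moved = res.state.counts.copy()
        moved[20, 20, 20] = 0
        observed = [
            moved[21, 20, 20], moved[19, 20, 20],
            moved[20, 21, 20], moved[20, 19, 20],
            moved[20, 20, 21], moved[20, 20, 19],
        ]
        assert sum(observed) == 10_000
        assert sps.chisquare(observed).pvalue > 1e-3

    def test_full_attraction_pulls_toward_structure(self, rng):
        from gliomalatt.anatomy import generate_synthetic_atlas

        atlas = generate_synthetic_atlas(
            (21, 21, 21),
            tract_specs=[{"kind": "slab", "axis": 0, "start": 13, "thickness": 2}],
            brain="full",
        )
        counts = np.zeros(atlas.shape, dtype=np.int32)
        counts[10, 10, 10] = 5000  # slab lies at +x within sensing range
        params = SimulationParams(p_m=1.0, p_p=0.0, w_wm=1.0, K=10**6, T=1, seed=3)
        res = run_simulation(params, atlas, LatticeState(counts=counts))
        x = np.arange(21)[:, None, None]
        mean_dx = ((res.state.counts * x).sum() / 5000.0) - 10.0
        n_plus = res.state.counts[11:].sum()
        n_minus = res.state.counts[:10].sum()
        assert mean_dx > 0
        # sign test: overwhelmingly more movers toward the slab
        assert sps.binomtest(int(n_plus), int(n_plus + n_minus), 0.5,
                             alternative="greater").pvalue < 1e-6

    def test_white_matter_only_variant_ignores_vessels(self, small_atlas):
        params = SimulationParams(p_m=0.8, p_p=0.0, w_wm=0.3, w_bv=0.5,
                                  T=30, seed=9, variant="white-matter-only")
        assert params.w_bv == 0.0
        res_a = run_simulation(params, small_atlas, {"radius": 2, "center": (12, 12, 12)})
        plain = SimulationParams(p_m=0.8, p_p=0.0, w_wm=0.3, w_bv=0.0, T=30, seed=9)
        res_b = run_simulation(plain, small_atlas, {"radius": 2, "center": (12, 12, 12)})
        np.testing.assert_array_equal(res_a.state.counts, res_b.state.counts)

    def test_snapshot_recording(self, small_atlas):
        params = SimulationParams(p_m=0.5, p_p=0.05, T=10, seed=2)
        res = run_simulation(params, small_atlas, {"radius": 1, "center": (12, 12, 12)},
                             record_steps=range(11))
        assert res.snapshots.shape[0] == 11
        np.testing.assert_array_equal(res.snapshots[-1], res.state.counts)
        np.testing.assert_array_equal(
            res.snapshots.sum(axis=(1, 2, 3)), res.n_trajectory)
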