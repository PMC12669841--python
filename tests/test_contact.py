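"""Translational contact optimization and lattice ROM sweeps."""

import numpy as np
import pytest

from romkit.contact import (ContactConfig, JointModel, optimize_translation,
                            proximity_stats, simulate_rom)
from romkit.errors import InvalidInputError
from romkit.fixtures import make_ball_and_socket
from romkit.posespace import generate_pose_grid

SMALL_GRID = {"fe": (-60.0, 60.0), "abad": (-60.0, 60.0),
              "lar": (-60.0, 60.0)}


class TestProximityStats:
    def test_concentric_spheres_uniform_distance(self, bas_joint):
        d, mean, var, mn = proximity_stats(bas_joint, np.eye(4))
        assert mean == pytest.approx(0.5, abs=1e-3)
        assert var < 1e-4
        assert mn == pytest.approx(0.5, abs=1e-3)

    def test_penetration_gives_negative_minimum(self, bas_joint):
        T = np.eye(4)
        T[:3, 3] = [0.7, 0, 0]  # push the ball into the socket wall
        _, _, _, mn = proximity_stats(bas_joint, T)
        assert mn < 0

    def test_single_vertex_has_zero_variance(self, bas_joint):
        solo = JointModel(
            proximal_mesh=bas_joint.proximal_mesh,
            proximal_sdf=bas_joint.proximal_sdf,
            distal_mesh=bas_joint.distal_mesh,
            articular_vertices=[0], d_t=bas_joint.d_t)
        d, mean, var, _ = proximity_stats(solo, np.eye(4))
        assert len(d) == 1
        assert var == 0.0

    def test_empty_articular_set_rejected(self, bas_joint):
        with pytest.raises(InvalidInputError):
            JointModel(proximal_mesh=bas_joint.proximal_mesh,
                       proximal_sdf=bas_joint.proximal_sdf,
                       distal_mesh=bas_joint.distal_mesh,
                       articular_vertices=[])


class TestOptimizeTranslation:
    def test_concentric_optimum_recovered(self, bas_joint):
        sol = optimize_translation(bas_joint, (0, 0, 0))
        assert sol.converged
        assert np.linalg.norm(sol.pose.translation) < 1e-3
        assert sol.proximity_variance < 1e-6

    def test_offset_start_reaches_same_basin(self, bas_joint):
        sol = optimize_translation(bas_joint, (0, 0, 0), init=(0.3, 0, 0))
        assert sol.converged
        assert np.linalg.norm(sol.pose.translation) < 1e-3

    def test_rotations_remain_concentric_by_symmetry(self, bas_joint):
        sol = optimize_translation(bas_joint, (45, 30, -60))
        assert sol.converged
        assert np.linalg.norm(sol.pose.translation) < 1e-3

    def test_infeasible_joint_reports_nonconvergence(self):
        # ball larger than the socket: every placement penetrates
        joint, _ = make_ball_and_socket(r_ball=5.0, clearance=0.5)
        big, _ = make_ball_and_socket(r_ball=6.0, clearance=0.5,
                                      sdf_resolution=21)
        infeasible = JointModel(
            proximal_mesh=joint.proximal_mesh,
            proximal_sdf=joint.proximal_sdf,  # socket radius 5.5
            distal_mesh=big.distal_mesh,      # ball radius 6.0
            articular_vertices=np.arange(len(big.distal_mesh.vertices)),
            d_t=0.5)
        sol = optimize_translation(infeasible, (0, 0, 0),
                                   config=ContactConfig(
                                       translation_bound=1.0, n_retries=1))
        assert not sol.converged

    def test_local_optimality_of_converged_solution(self, saddle_joint):
        sol = optimize_translation(saddle_joint, (0, 0, 0))
        assert sol.converged
        base = sol.objective
        for ax in range(3):
            for sign in (-1, 1):
                t = sol.pose.translation.copy()
                t[ax] += sign * 0.05
                _, mean, var, mn = proximity_stats(
                    saddle_joint, _transform(saddle_joint, t))
                if mn < 0:
                    continue  # infeasible perturbation cannot undercut
                perturbed = (mean - saddle_joint.d_t) ** 2 + var
                assert perturbed >= base - 1e-6

    def test_feasibility_of_converged_solutions(self, saddle_joint, rng):
        for _ in range(10):
            ang = rng.uniform((-60, -30, -60), (60, 30, 60))
            sol = optimize_translation(saddle_joint, ang,
                                       config=ContactConfig(max_iter=60))
            if sol.converged:
                assert sol.min_proximity >= -1e-3


def _transform(joint, t):
    T = np.eye(4)
    T[:3, 3] = t
    return T


class TestSimulateRom:
    def test_one_solution_per_lattice_pose(self, bas_joint,
                                           lean_contact_config):
        grid = generate_pose_grid(SMALL_GRID, 60.0)
        res = simulate_rom(bas_joint, grid, lean_contact_config)
        assert len(res.translations) == len(grid)
        assert res.viable_mask.shape == (len(grid),)

    def test_full_coverage_ball_and_socket_fully_viable(
            self, bas_joint, lean_contact_config):
        grid = generate_pose_grid(step=45.0)
        res = simulate_rom(bas_joint, grid, lean_contact_config)
        assert res.viable_mask.all()

    def test_warm_start_order_does_not_change_solutions(
            self, bas_joint, lean_contact_config):
        grid = generate_pose_grid(SMALL_GRID, 30.0)
        warm = simulate_rom(bas_joint, grid, lean_contact_config)
        cold_cfg = ContactConfig(max_iter=60, n_retries=1, warm_start=False)
        cold = simulate_rom(bas_joint, grid, cold_cfg)
        assert np.array_equal(warm.viable_mask, cold.viable_mask)
        both = warm.viable_mask & cold.viable_mask
        dt = np.linalg.norm(warm.translations[both]
                            - cold.translations[both], axis=1)
        assert dt.max() < 1e-3

    def test_six_dof_viability_contains_fixed_centre_viability(
            self, bas_joint):
        grid = generate_pose_grid(SMALL_GRID, 60.0)
        free = simulate_rom(bas_joint, grid,
                            ContactConfig(max_iter=60, n_retries=1))
        fixed = simulate_rom(bas_joint, grid,
                             ContactConfig(max_iter=60, n_retries=1,
                                           translation_bound=0.0))
        assert np.all(free.viable_mask >= fixed.viable_mask)

    def test_dataframe_schema(self, bas_joint, lean_contact_config):
        grid = generate_pose_grid(SMALL_GRID, 120.0)
        df = simulate_rom(bas_joint, grid, lean_contact_config).to_dataframe()
        for col in ("fe", "abad", "lar", "tx", "ty", "tz", "mean_prox",
                    "var_prox", "min_prox", "converged", "viable"):
            assert col in df.columns
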