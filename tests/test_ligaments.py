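"""Ligament frames, shortest-path solves, strains and interpolation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from romkit.errors import DegenerateFrameError, InvalidInputError
from romkit.fixtures import make_ball_and_socket
from romkit.ligaments import (Ligament, Obstacle, compute_strain,
                              evaluate_ligaments, interpolate_failed_lengths,
                              ligament_frame, path_length_for_pose,
                              solve_ligament_path)
from romkit.posespace import Pose, sine_correct


def cylinder_geodesic_length(d: float, r: float) -> float:
    """Closed-form taut string around a circle: two tangents plus an arc.

    Endpoints diametrically opposite at distance ``d`` from the axis.
    """
    alpha = np.arccos(r / d)
    return 2 * np.sqrt(d * d - r * r) + r * (np.pi - 2 * alpha)


class TestLigamentFrame:
    def test_orthonormal_triad(self):
        f = ligament_frame([0, 0, 0], [1, 0, 0], [0.5, 1, 0])
        assert np.allclose(f.axes[0], [1, 0, 0])
        assert np.allclose(f.axes @ f.axes.T, np.eye(3), atol=1e-12)

    def test_collinear_joint_centre_rejected(self):
        with pytest.raises(DegenerateFrameError):
            ligament_frame([0, 0, 0], [1, 0, 0], [0.5, 0, 0])

    def test_right_handedness_random_inputs(self, rng):
        for _ in range(100):
            p0, pn, pj = rng.normal(size=(3, 3))
            if np.linalg.norm(np.cross(pn - p0, pj - p0)) < 1e-3:
                continue
            f = ligament_frame(p0, pn, pj)
            assert np.linalg.det(f.axes) == pytest.approx(1.0, abs=1e-9)


class TestSolvePath:
    def test_no_obstacles_straight_line(self):
        f = ligament_frame([-2, 0, 0], [2, 0, 0], [0, 5, 0])
        path = solve_ligament_path(f, [], n_segments=20)
        assert path.converged
        assert path.length == pytest.approx(4.0, abs=1e-6)
        assert np.abs(path.local[:, 1:]).max() < 1e-12

    def test_cylinder_wrap_matches_taut_string(self, cylinder):
        grid, _, _ = cylinder
        f = ligament_frame([-2, 0, 0], [2, 0, 0], [0, 5, 0])
        exact = cylinder_geodesic_length(2.0, 0.5)
        path = solve_ligament_path(f, [Obstacle(grid)], n_segments=20)
        assert path.converged
        assert abs(path.length - exact) / exact < 0.01

    def test_error_decreases_with_segments(self, cylinder):
        grid, _, _ = cylinder
        f = ligament_frame([-2, 0, 0], [2, 0, 0], [0, 5, 0])
        exact = cylinder_geodesic_length(2.0, 0.5)
        errs = [abs(solve_ligament_path(f, [Obstacle(grid)], n).length
                    - exact) for n in (10, 20, 40)]
        assert errs[0] >= errs[1] >= errs[2]

    def test_length_never_below_chord(self, cylinder, rng):
        grid, _, _ = cylinder
        for _ in range(5):
            p0 = np.array([-2.0, rng.uniform(-1, 1), rng.uniform(-1, 1)])
            pn = np.array([2.0, rng.uniform(-1, 1), rng.uniform(-1, 1)])
            f = ligament_frame(p0, pn, [0, 5, 0])
            path = solve_ligament_path(f, [Obstacle(grid)], 20)
            assert path.length >= np.linalg.norm(pn - p0) - 1e-9

    def test_obstacle_growth_never_shortens_path(self):
        from romkit.fixtures import make_cylinder_obstacle

        f = ligament_frame([-2, 0, 0], [2, 0, 0], [0, 5, 0])
        prev = 0.0
        for r in (0.1, 0.3, 0.5, 0.7, 0.9):
            grid, _, _ = make_cylinder_obstacle(radius=r, half_extent=3.0,
                                                resolution=41)
            path = solve_ligament_path(f, [Obstacle(grid)], 20)
            assert path.converged
            assert path.length >= prev - 1e-9
            prev = path.length

    def test_constraints_hold_on_converged_solves(self, cylinder):
        grid, _, analytic = cylinder
        f = ligament_frame([-2, 0.3, -0.2], [2, -0.4, 0.1], [0, 5, 0])
        path = solve_ligament_path(f, [Obstacle(grid)], 20)
        assert path.converged
        # distance constraint at the interior points
        assert analytic(path.world[1:-1]).min() >= -1e-3
        # 60-degree angular constraint per segment
        step = np.diff(path.local, axis=0)
        angles = np.degrees(np.arctan2(
            np.hypot(step[:, 1], step[:, 2]), step[:, 0]))
        assert angles.max() <= 60.0 + 1e-6

    def test_fixed_x_stations(self, cylinder):
        grid, _, _ = cylinder
        f = ligament_frame([-2, 0, 0], [2, 0, 0], [0, 5, 0])
        path = solve_ligament_path(f, [Obstacle(grid)], 20)
        assert np.allclose(path.local[:, 0], np.linspace(0, 4, 21),
                           atol=1e-12)


class TestStrain:
    @pytest.mark.parametrize("ratio,expected", [
        (1.395, 39.5),   # stretched beyond rest length
        (0.054, -94.6),  # collapsed origin-insertion distance
        (1.0, 0.0),
    ])
    def test_engineering_strain_worked_examples(self, ratio, expected):
        for rest in (1.0, 10.0, 37.2):
            assert compute_strain(ratio * rest, rest) == \
                pytest.approx(expected, abs=1e-9)

    def test_nonpositive_rest_length_rejected(self):
        with pytest.raises(InvalidInputError):
            compute_strain(1.0, 0.0)

    @given(rest=st.floats(1e-3, 1e3), factor=st.floats(0.0, 10.0))
    def test_strain_depends_only_on_length_ratio(self, rest, factor):
        # engineering strain is scale invariant: 100 * (factor - 1)
        assert compute_strain(factor * rest, rest) == \
            pytest.approx(100.0 * (factor - 1.0), rel=1e-9, abs=1e-6)


class TestMotionIndependence:
    def test_batch_lengths_invariant_under_permutation(self, bas_joint, rng):
        lig = Ligament(name="LAcH", origin=[0, 5.3, 0.8],
                       insertion=[0, 4.9, 0.5], rest_length=1.5,
                       n_segments=10)
        poses = np.stack([rng.uniform(-90, 90, 30),
                          rng.uniform(-45, 45, 30),
                          rng.uniform(-90, 90, 30)], axis=-1)
        table = evaluate_ligaments(bas_joint, [lig], poses)
        perm = rng.permutation(30)
        shuffled = evaluate_ligaments(bas_joint, [lig], poses[perm])
        assert np.array_equal(shuffled["len_LAcH"].to_numpy(),
                              table["len_LAcH"].to_numpy()[perm])

    def test_single_pose_isolated_vs_in_sequence(self, bas_joint):
        lig = Ligament(name="L", origin=[0, 5.3, 0.8],
                       insertion=[0, 4.9, 0.5], rest_length=1.5,
                       n_segments=10)
        pose = Pose(25, -10, 40)
        alone = path_length_for_pose(bas_joint, lig, pose)
        for prior in (Pose(0, 0, 0), Pose(-80, 40, 10)):
            path_length_for_pose(bas_joint, lig, prior)
            again = path_length_for_pose(bas_joint, lig, pose)
            assert again == alone

    def test_straight_length_option(self, bas_joint):
        lig = Ligament(name="L", origin=[0, 7.0, 0], insertion=[0, 5.0, 0.0],
                       rest_length=2.0)
        length, conv = path_length_for_pose(bas_joint, lig, Pose(0, 0, 0),
                                            straight=True)
        assert conv
        assert length == pytest.approx(2.0, abs=1e-12)


class TestInterpolateFailed:
    @staticmethod
    def _smooth_table(rng, n=600, fail_frac=0.0):
        angles = np.stack([rng.uniform(-60, 60, n),
                           rng.uniform(-45, 45, n),
                           rng.uniform(-60, 60, n)], axis=-1)
        sc = sine_correct(angles)
        lengths = (10.0 + 0.02 * sc[:, 0] + 0.03 * sc[:, 1]
                   - 0.01 * sc[:, 2] + 1e-4 * sc[:, 0] * sc[:, 1])
        conv = np.ones(n, dtype=bool)
        if fail_frac:
            conv[rng.random(n) < fail_frac] = False
        table = pd.DataFrame({
            "fe": angles[:, 0], "abad": angles[:, 1], "lar": angles[:, 2],
            "len_L": np.where(conv, lengths, 1e6), "conv_L": conv})
        return table, lengths

    def test_no_failures_returns_unchanged(self, rng):
        table, _ = self._smooth_table(rng)
        out = interpolate_failed_lengths(table)
        assert np.array_equal(out["len_L"].to_numpy(),
                              table["len_L"].to_numpy())

    def test_recovers_masked_smooth_field(self, rng):
        table, truth = self._smooth_table(rng, fail_frac=0.05)
        out = interpolate_failed_lengths(table)
        bad = ~table["conv_L"].to_numpy()
        rms = np.sqrt(np.mean(
            ((out["len_L"].to_numpy()[bad] - truth[bad]) / truth[bad]) ** 2))
        assert rms < 0.02

    def test_flags_robust_outliers_among_converged(self, rng):
        table, truth = self._smooth_table(rng)
        vals = table["len_L"].to_numpy().copy()
        vals[17] = 50.0  # wildly off but flagged converged
        table["len_L"] = vals
        out = interpolate_failed_lengths(table)
        assert abs(out["len_L"].iloc[17] - truth[17]) < 1.0

    def test_all_failed_rejected(self, rng):
        table, _ = self._smooth_table(rng)
        table["conv_L"] = False
        with pytest.raises(InvalidInputError):
            interpolate_failed_lengths(table)
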