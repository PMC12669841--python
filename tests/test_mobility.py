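"""Strain thresholds, envelope filtering and alpha-shape volumetry."""

import numpy as np
import pandas as pd
import pytest

from romkit.errors import InvalidInputError
from romkit.ligaments import Ligament
from romkit.mobility import (alpha_sensitivity, alpha_volume,
                             apply_strain_filter, derive_thresholds,
                             missed_volume, smallest_connecting_alpha)


def cube_lattice(n=11, spacing=1.0):
    ax = spacing * np.arange(n, dtype=float)
    return np.stack(np.meshgrid(ax, ax, ax, indexing="ij"),
                    axis=-1).reshape(-1, 3)


def synthetic_length_table(rng, n=200):
    angles = rng.uniform(-60, 60, size=(n, 3))
    return pd.DataFrame({
        "fe": angles[:, 0], "abad": angles[:, 1], "lar": angles[:, 2],
        "len_A": 10 + 0.05 * np.abs(angles[:, 0]),
        "len_B": 8 + 0.04 * np.abs(angles[:, 1]),
    })


class TestThresholds:
    def test_trajectory_max(self):
        trj = pd.DataFrame({"len_LAcH": [9.8, 10.0, 10.4]})
        thr = derive_thresholds("trajectory_max", trajectory=trj)
        assert thr.max_length["LAcH"] == pytest.approx(10.4)

    def test_scaled_rest_plus_strain_factor(self):
        lig = Ligament(name="LAcH", origin=[0, 0, 0], insertion=[1, 0, 0],
                       rest_length=10.0)
        thr = derive_thresholds("scaled_rest_plus_strain", ligaments=[lig],
                                scale=1.0, strain_factor=0.26)
        assert thr.max_length["LAcH"] == pytest.approx(12.6)

    def test_rom_interpolated_consistent_with_trajectory_max(self, rng):
        # when the ROM table covers the trajectory poses with identical
        # translations, interpolated maxima reduce to the trajectory maxima
        rom = synthetic_length_table(rng, n=500)
        idx = rng.choice(len(rom), 60, replace=False)
        trj = rom.iloc[idx].reset_index(drop=True)
        thr_i = derive_thresholds("rom_interpolated", trajectory=trj,
                                  rom_table=rom)
        thr_t = derive_thresholds("trajectory_max", trajectory=trj)
        for k in thr_t.max_length:
            assert thr_i.max_length[k] == pytest.approx(
                thr_t.max_length[k], rel=0.02)

    def test_empty_trajectory_rejected(self):
        with pytest.raises(InvalidInputError):
            derive_thresholds("trajectory_max", trajectory=pd.DataFrame())

    def test_unknown_mode_rejected(self):
        with pytest.raises(InvalidInputError):
            derive_thresholds("nonsense")


class TestStrainFilter:
    def test_infinite_thresholds_keep_viable_set(self, rng):
        table = synthetic_length_table(rng)
        viable = rng.random(len(table)) < 0.7
        from romkit.mobility import StrainThresholds

        thr = StrainThresholds({"A": np.inf, "B": np.inf})
        out = apply_strain_filter(viable, table, thr)
        assert np.array_equal(out, viable)

    def test_single_exceedance_removes_pose(self, rng):
        from romkit.mobility import StrainThresholds

        table = synthetic_length_table(rng)
        viable = np.ones(len(table), dtype=bool)
        limit = float(table["len_A"].iloc[5]) - 1e-9
        thr = StrainThresholds({"A": limit, "B": np.inf})
        out = apply_strain_filter(viable, table, thr)
        assert not out[5]

    def test_monotone_in_thresholds(self, rng):
        from romkit.mobility import StrainThresholds

        # exhaustive check over a 15-deg rotational lattice
        from romkit.posespace import generate_pose_grid

        grid = generate_pose_grid({"fe": (-60, 60), "abad": (-45, 45),
                                   "lar": (-60, 60)}, 15.0)
        a = grid.angles
        table = pd.DataFrame({
            "fe": a[:, 0], "abad": a[:, 1], "lar": a[:, 2],
            "len_A": 10 + 0.05 * np.abs(a[:, 0]) + 0.01 * np.abs(a[:, 2]),
            "len_B": 8 + 0.04 * np.abs(a[:, 1])})
        viable = np.ones(len(table), dtype=bool)
        tight = StrainThresholds({"A": 11.0, "B": 9.0})
        loose = StrainThresholds({"A": 12.5, "B": 10.0})
        s_tight = apply_strain_filter(viable, table, tight)
        s_loose = apply_strain_filter(viable, table, loose)
        assert np.all(s_loose >= s_tight)  # tight set is a subset

    def test_filtering_never_adds_poses(self, rng):
        from romkit.mobility import StrainThresholds

        table = synthetic_length_table(rng)
        viable = rng.random(len(table)) < 0.5
        thr = StrainThresholds({"A": 11.0, "B": 9.0})
        out = apply_strain_filter(viable, table, thr)
        assert np.all(out <= viable)

    def test_missing_column_rejected(self, rng):
        from romkit.mobility import StrainThresholds

        table = synthetic_length_table(rng)
        thr = StrainThresholds({"C": 1.0})
        with pytest.raises(InvalidInputError):
            apply_strain_filter(np.ones(len(table), bool), table, thr)


class TestAlphaVolume:
    def test_unit_cube_lattice_volume(self):
        mv = alpha_volume(cube_lattice(), alpha=3.0)
        assert mv.volume == pytest.approx(1000.0, rel=0.05)

    def test_three_points_zero_volume(self):
        mv = alpha_volume(np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0.0]]), 3.0)
        assert mv.volume == 0.0

    def test_nested_in_alpha_and_bounded_by_hull(self, rng):
        from scipy.spatial import ConvexHull

        pts = rng.uniform(0, 10, size=(300, 3))
        v2 = alpha_volume(pts, 2.0).volume
        v4 = alpha_volume(pts, 4.0).volume
        hull = ConvexHull(pts).volume
        assert 0.0 <= v2 <= v4 <= hull + 1e-9

    def test_sensitivity_curve_plateaus_at_box_volume(self):
        pts = cube_lattice()
        curve = alpha_sensitivity(pts, [0.5, 1.0, 2.0, 4.0, 8.0])
        assert np.all(np.diff(curve.volume) >= -1e-9)
        assert curve.volume.iloc[-1] == pytest.approx(1000.0, rel=0.05)
        assert smallest_connecting_alpha(pts, [0.5, 1.0, 2.0]) == 1.0

    def test_single_point_all_volumes_zero(self):
        curve = alpha_sensitivity(np.zeros((1, 3)), [1.0, 2.0])
        assert (curve.volume == 0).all()


class TestMissedVolume:
    def test_self_coverage_is_zero(self):
        pts = cube_lattice()
        deg3, pct, _ = missed_volume(pts, pts, alpha=3.0, n_samples=20000)
        assert deg3 == 0.0
        assert pct == 0.0

    def test_reference_inside_candidate_is_zero(self, rng):
        ref = cube_lattice(6)  # 5x5x5 cube
        cand = cube_lattice(11) * 1.0 - 2.5  # larger box around it
        _, pct, _ = missed_volume(ref, cand, alpha=3.0, n_samples=20000)
        assert pct == 0.0

    def test_disjoint_clouds_fully_missed(self):
        ref = cube_lattice()
        _, pct, _ = missed_volume(ref, ref + 100.0, alpha=3.0,
                                  n_samples=20000)
        assert pct == pytest.approx(100.0, abs=1.0)

    def test_percentages_bounded(self, rng):
        ref = cube_lattice()
        cand = ref[rng.random(len(ref)) < 0.4]
        _, pct, _ = missed_volume(ref, cand, alpha=3.0, n_samples=20000)
        assert 0.0 <= pct <= 100.0

    def test_empty_reference_rejected(self):
        with pytest.raises(InvalidInputError):
            missed_volume(np.empty((0, 3)), cube_lattice(), 3.0)

    def test_degenerate_reference_rejected(self):
        flat = cube_lattice()[:, :2]
        flat = np.column_stack([flat[:20], np.zeros(20)])
        with pytest.raises(InvalidInputError):
            missed_volume(flat, cube_lattice(), 3.0)
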