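import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from tiltscf.distributions import sample_side_like, sample_uniform
from tiltscf.geometry import OrientationSet, rotation_about_axis, eulers_from_rotations
from tiltscf.sampling import (
    ShellGrid,
    ShellSamplingMap,
    accumulate_sampling,
    build_shell_grid,
    compute_scf,
    scf_of_orientations,
)


def equal_area_map(counts):
    """Synthetic sampling map on a fake grid of identical-solid-angle bins."""
    counts = np.asarray(counts, dtype=float)
    m = len(counts)
    grid = ShellGrid(
        resolution=10.0,
        centers=np.tile([0.0, 0.0, 1.0], (m, 1)),
        solid_angles=np.full(m, 4 * np.pi / m),
        ring_start=np.array([0]),
        n_phi=np.array([m]),
    )
    return ShellSamplingMap(grid=grid, counts=counts, n_projections=1)


class TestBuildShellGrid:
    @pytest.mark.parametrize("res", [0.5, 1.5, 3.0, 10.0])
    def test_solid_angles_sum_to_sphere(self, res):
        g = build_shell_grid(res)
        assert abs(g.solid_angles.sum() - 4 * np.pi) < 4 * np.pi * 1e-3

    def test_bin_count_scaling(self):
        n_fine = build_shell_grid(1.5).n_bins
        n_coarse = build_shell_grid(10.0).n_bins
        expected_ratio = (10.0 / 1.5) ** 2
        assert abs(n_fine / n_coarse - expected_ratio) / expected_ratio < 0.2

    def test_centers_unit_norm(self, coarse_grid):
        assert np.allclose(np.linalg.norm(coarse_grid.centers, axis=1), 1.0)

    def test_bin_index_recovers_centers(self, coarse_grid):
        idx = coarse_grid.bin_index(coarse_grid.centers)
        assert np.array_equal(idx, np.arange(coarse_grid.n_bins))

    def test_rejects_out_of_range_resolution(self):
        for bad in (0.4, 10.5):
            with pytest.raises(ValueError):
                build_shell_grid(bad)


class TestAccumulateSampling:
    def test_single_projection_great_circle(self, coarse_grid):
        s = OrientationSet(np.array([[30.0, 60.0, 10.0]]))
        smap = accumulate_sampling(s, coarse_grid, circle_samples=2000)
        assert smap.counts.sum() == 2000
        n = s.directions()[0]
        hot = coarse_grid.centers[smap.counts > 0]
        # every sampled bin center lies near the central plane of n
        assert np.abs(hot @ n).max() < np.sin(np.deg2rad(2 * coarse_grid.resolution))

    def test_mass_conservation_with_weights(self, coarse_grid):
        w = np.array([1.0, 2.5, 0.0])
        s = OrientationSet(sample_uniform(3, seed=1).angles, weights=w)
        smap = accumulate_sampling(s, coarse_grid, circle_samples=100)
        assert np.isclose(smap.counts.sum(), w.sum() * 100)

    def test_uniform_counts_uniform(self, default_grid):
        s = sample_uniform(10_000, seed=5)
        smap = accumulate_sampling(s, default_grid, circle_samples=1000)
        density = smap.counts / default_grid.solid_angles
        cv = density.std() / density.mean()
        assert cv < 0.1

    def test_side_like_inverse_sine_density(self, default_grid):
        # great circles through the poles: density ~ 1/sin(theta)
        s = sample_side_like(10_000, deterministic=True)
        smap = accumulate_sampling(s, default_grid, circle_samples=1000)
        theta = np.arccos(np.clip(default_grid.centers[:, 2], -1, 1))
        away_from_poles = (theta > np.deg2rad(20)) & (theta < np.deg2rad(160))
        density = smap.counts[away_from_poles] / default_grid.solid_angles[away_from_poles]
        predicted = 1.0 / np.sin(theta[away_from_poles])
        ratio = density / predicted
        assert ratio.std() / ratio.mean() < 0.05

    def test_engines_agree(self, coarse_grid):
        pytest.importorskip("numba")
        s = sample_uniform(200, seed=9)
        a = accumulate_sampling(s, coarse_grid, circle_samples=500, engine="numba")
        b = accumulate_sampling(s, coarse_grid, circle_samples=500, engine="numpy")
        assert np.array_equal(a.counts, b.counts)

    def test_brute_force_plane_membership_oracle(self, rng):
        # coarse grid, few projections: sampled bins = bins whose center lies
        # within the bin width of some projection's central plane
        grid = build_shell_grid(10.0)
        s = sample_uniform(15, seed=3)
        smap = accumulate_sampling(s, grid, circle_samples=4000)
        dots = np.abs(grid.centers @ s.directions().T)  # (M, P)
        res_rad = np.deg2rad(grid.resolution)
        near_plane = (dots < np.sin(0.5 * res_rad)).any(axis=1)
        far_from_plane = (dots > np.sin(1.5 * res_rad)).all(axis=1)
        sampled = smap.counts > 0
        assert np.all(sampled[near_plane])
        assert not np.any(sampled[far_from_plane])

    def test_rejects_empty_set(self, coarse_grid):
        with pytest.raises(ValueError):
            accumulate_sampling(
                OrientationSet(np.empty((0, 3))), coarse_grid)


class TestComputeScf:
    def test_constant_sampling_gives_one(self):
        res = compute_scf(equal_area_map(np.full(100, 7.0)))
        assert np.isclose(res.scf, 1.0) and np.isclose(res.scf_star, 1.0)

    def test_hand_computed_example(self):
        # counts {1,1,1,4}: HM = 4/3.25 = 1.2308, AM = 1.75, SCF = 0.7033
        res = compute_scf(equal_area_map([1, 1, 1, 4]))
        omega = np.pi  # each bin is a quarter sphere
        assert np.isclose(res.harmonic_mean * omega, 1.230769, atol=1e-5)
        assert np.isclose(res.arithmetic_mean * omega, 1.75, atol=1e-9)
        assert np.isclose(res.scf, 0.703297, atol=1e-5)

    def test_zero_policies(self):
        res = compute_scf(equal_area_map([0, 2, 2, 2]))
        assert res.scf == 0.0
        assert 0 < res.scf_star < 1
        assert np.isclose(res.unsampled_fraction, 0.25)

    def test_rejects_all_zero(self):
        with pytest.raises(ValueError):
            compute_scf(equal_area_map([0, 0, 0]))

    def test_rejects_unknown_policy(self):
        with pytest.raises(ValueError):
            compute_scf(equal_area_map([1, 2]), zero_handling="zeropad")

    @given(hnp.arrays(np.float64, st.integers(4, 200),
                      elements=st.floats(0, 1e6)))
    @settings(max_examples=150, deadline=None)
    def test_am_hm_inequality_and_range(self, counts):
        if counts.sum() == 0:
            return
        res = compute_scf(equal_area_map(counts))
        assert res.harmonic_mean <= res.arithmetic_mean * (1 + 1e-12)
        assert 0.0 <= res.scf <= 1.0 + 1e-12
        assert 0.0 <= res.scf_star <= 1.0 + 1e-12


class TestScfOfOrientations:
    def test_side_like_matches_closed_form(self):
        res = scf_of_orientations(sample_side_like(10_000, deterministic=True))
        assert abs(res.scf - 8 / np.pi**2) < 0.01

    def test_rotation_invariance(self, default_grid):
        s = sample_side_like(5_000, seed=8)
        base = scf_of_orientations(s, grid=default_grid).scf
        Q = rotation_about_axis(np.array([1.0, 2.0, 0.5]), 53.0)
        rotated = OrientationSet(eulers_from_rotations(Q @ s.rotations()))
        rot = scf_of_orientations(rotated, grid=default_grid).scf
        assert abs(base - rot) < 0.01

    def test_antipodal_invariance(self, default_grid):
        # inverting every viewing direction leaves the sampling unchanged
        s = sample_uniform(2_000, seed=10)
        base = scf_of_orientations(s, grid=default_grid).scf
        flipped = OrientationSet(
            np.column_stack([s.angles[:, 0] + 180.0, 180.0 - s.angles[:, 1],
                             -s.angles[:, 2]]))
        flip = scf_of_orientations(flipped, grid=default_grid).scf
        assert abs(base - flip) < 0.01

    def test_resolution_stability(self):
        s = sample_side_like(10_000, deterministic=True)
        vals = [scf_of_orientations(s, resolution=r).scf for r in (1.0, 3.0)]
        assert abs(vals[0] - vals[1]) < 0.02

    def test_export_text(self, tmp_path, coarse_grid):
        s = sample_uniform(100, seed=1)
        smap = accumulate_sampling(s, coarse_grid, circle_samples=100)
        out = tmp_path / "map.txt"
        smap.export_text(out)
        data = np.loadtxt(out)
        assert data.shape == (coarse_grid.n_bins, 4)
        assert np.isclose(data[:, 3].sum(), smap.counts.sum(), rtol=1e-3)
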