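import math

import numpy as np
import pytest

import somafret as sf
from somafret.spatial import NeighborhoodSpec, permutation_null
from somafret.synth import CellTruth, read_scene, write_scene

from conftest import SMALL_FIELD, make_small_scene


class TestSampleCellCenters:
    def test_trivial_counts(self):
        assert sf.sample_cell_centers(0, (100, 100, 100), 10, seed=0) == []
        (p,) = sf.sample_cell_centers(1, (100, 100, 100), 10, seed=0)
        assert all(0 <= c <= 100 for c in p)

    def test_hardcore_and_deterministic(self):
        args = dict(n=200, field_dims_um=(100, 300, 300), min_separation_um=12.0, seed=1)
        pts = np.array(sf.sample_cell_centers(**args))
        assert pts.shape == (200, 3)
        # exhaustive all-pairs check
        d = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 12.0
        np.testing.assert_array_equal(pts, np.array(sf.sample_cell_centers(**args)))

    def test_impossible_packing_fails_clearly(self):
        with pytest.raises(RuntimeError, match="min separation"):
            sf.sample_cell_centers(50, (30, 30, 30), 25.0, seed=0)


class TestRatioField:
    def test_zero_variance_gives_mean(self):
        params = sf.RatioFieldParams(mean_ratio=2.5, sill=0.0, nugget=0.0)
        centers = [(0, 0, 0), (0, 0, 50.0), (0, 40.0, 0)]
        assert sf.sample_ratio_field(centers, params, seed=0) == [2.5, 2.5, 2.5]

    def test_two_cell_correlation_matches_closed_form(self):
        """Empirical correlation of a cell pair equals
        sill*exp(-d/range)/(sill+nugget) within Monte-Carlo error."""
        params = sf.RatioFieldParams(mean_ratio=2.5, sill=0.09, range_um=30.0, nugget=0.01)
        for dist in [10.0, 30.0, 60.0]:
            centers = [(0, 0, 0), (0, 0, dist)]
            draws = np.array(
                [sf.sample_ratio_field(centers, params, seed=s) for s in range(4000)]
            )
            emp = np.corrcoef(draws[:, 0], draws[:, 1])[0, 1]
            expected = params.sill * math.exp(-dist / params.range_um) / (params.sill + params.nugget)
            assert emp == pytest.approx(expected, abs=0.05)

    def test_nugget_only_uncorrelated(self):
        params = sf.RatioFieldParams(mean_ratio=2.5, sill=0.0, nugget=0.09)
        centers = [(0, 0, 0), (0, 0, 5.0)]
        draws = np.array([sf.sample_ratio_field(centers, params, seed=s) for s in range(3000)])
        assert abs(np.corrcoef(draws[:, 0], draws[:, 1])[0, 1]) < 0.06

    def test_duplicate_centers_without_nugget_fail(self):
        params = sf.RatioFieldParams(sill=0.09, nugget=0.0)
        with pytest.raises(ValueError, match="positive definite"):
            sf.sample_ratio_field([(0, 0, 0), (0, 0, 0)], params, seed=0)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            sf.RatioFieldParams(sill=-0.1)
        with pytest.raises(ValueError):
            sf.RatioFieldParams(mean_ratio=0.5, sill=0.09, nugget=0.09)


class TestDistractors:
    def test_zero_unchanged(self):
        sc = make_small_scene(0, n_cells=10)
        out = sf.add_distractors(sc, 0)
        assert out.distractors == [] and len(out.cells) == 10

    def test_ratios_below_threshold(self):
        sc = make_small_scene(0, n_cells=10)
        out = sf.add_distractors(sc, 30, ratio_low=0.6, ratio_high=1.2, seed=3)
        assert len(out.distractors) == 30
        assert all(0.6 <= d.true_ratio <= 1.2 for d in out.distractors)
        assert all(d.true_ratio < 1.5 for d in out.distractors)
        assert sc.distractors == []  # original untouched

    def test_invalid_band(self):
        sc = make_small_scene(0, n_cells=5)
        with pytest.raises(ValueError):
            sf.add_distractors(sc, 5, ratio_low=0.5, ratio_high=1.6)


class TestRender:
    def _one_cell_scene(self, ratio=2.0, amp=100.0):
        return sf.SyntheticScene(
            field_dims_um=(24.0, 24.0, 24.0),
            voxel_size_um=(2.0, 1.0, 1.0),
            cells=[CellTruth((12.0, 12.0, 12.0), 6.0, amp, ratio)],
            distractors=[],
            field_params=sf.RatioFieldParams(),
            rng_seed=0,
        )

    def test_noise_free_voxel_ratio_exact(self):
        scene = self._one_cell_scene(ratio=2.0)
        stack = sf.render_stack(scene, sf.OpticsParams.noise_free())
        interior = stack.donor > 1e-9
        assert interior.sum() > 50
        np.testing.assert_allclose(stack.acceptor[interior] / stack.donor[interior], 2.0, rtol=1e-12)

    def test_empty_scene_uniform_background(self):
        scene = sf.SyntheticScene(
            field_dims_um=(8.0, 10.0, 10.0),
            voxel_size_um=(2.0, 1.0, 1.0),
            cells=[],
            distractors=[],
            field_params=sf.RatioFieldParams(),
            rng_seed=0,
        )
        optics = sf.OpticsParams(
            psf_sigma_um=(0, 0, 0), background_offset=5.0,
            background_gradient_amplitude=0.0, read_noise_sd=0.0, shot_noise=False,
        )
        stack = sf.render_stack(scene, optics)
        np.testing.assert_allclose(stack.data, 5.0, atol=1e-12)

    def test_default_noise_interior_ratio_within_2pct(self):
        """Mean rendered acceptor/donor over interior voxels tracks the
        true ratio within 2% across seeds at default noise."""
        scene = self._one_cell_scene(ratio=2.5, amp=12000.0)
        clean = sf.render_stack(scene, sf.OpticsParams.noise_free())
        interior = clean.donor > 0.1 * clean.donor.max()
        errs = []
        for seed in range(10):
            noisy = sf.render_stack(scene, sf.OpticsParams(), seed=seed)
            # subtract the known background before forming voxel ratios
            d = noisy.donor[interior] - 20.0 - 10.0 * 0.5
            a = noisy.acceptor[interior] - 20.0 - 10.0 * 0.5
            errs.append(abs(a.mean() / d.mean() - 2.5) / 2.5)
        assert np.mean(errs) < 0.02

    def test_attenuation_dims_with_depth_equally_in_both_channels(self):
        scene = self._one_cell_scene()
        shallow = sf.render_stack(scene, sf.OpticsParams.noise_free())
        att = sf.OpticsParams.noise_free()
        att = sf.OpticsParams(
            psf_sigma_um=(0, 0, 0), background_offset=0.0,
            background_gradient_amplitude=0.0, attenuation_length_um=30.0,
            read_noise_sd=0.0, shot_noise=False,
        )
        dimmed = sf.render_stack(scene, att)
        nz = shallow.donor > 1e-9
        factor = dimmed.donor[nz] / shallow.donor[nz]
        assert factor.max() < 1.0
        np.testing.assert_allclose(
            dimmed.acceptor[nz] / dimmed.donor[nz],
            shallow.acceptor[nz] / shallow.donor[nz],
            rtol=1e-9,
        )

    def test_bad_grid_rejected(self):
        scene = self._one_cell_scene()
        scene.field_dims_um = (25.0, 24.0, 24.0)  # not a multiple of dz=2
        with pytest.raises(ValueError, match="integer multiple"):
            sf.render_stack(scene, sf.OpticsParams.noise_free())

    def test_render_deterministic(self):
        scene = make_small_scene(3, n_cells=5)
        a = sf.render_stack(scene, sf.OpticsParams(), seed=9)
        b = sf.render_stack(scene, sf.OpticsParams(), seed=9)
        np.testing.assert_array_equal(a.data, b.data)


class TestSceneTransforms:
    def test_scaling_exact_and_identity(self):
        sc = make_small_scene(1, n_cells=20)
        sc = sf.add_distractors(sc, 6, seed=1)
        same = sf.apply_global_ratio_scaling(sc, 1.0)
        assert [c.true_ratio for c in same.cells] == [c.true_ratio for c in sc.cells]
        scaled = sf.apply_global_ratio_scaling(sc, 0.779)
        np.testing.assert_allclose(
            [c.true_ratio for c in scaled.cells],
            [c.true_ratio * 0.779 for c in sc.cells],
            rtol=1e-15,
        )
        assert np.mean([c.true_ratio for c in scaled.cells]) == pytest.approx(
            0.779 * np.mean([c.true_ratio for c in sc.cells])
        )
        # distractor ratios untouched
        assert [d.true_ratio for d in scaled.distractors] == [d.true_ratio for d in sc.distractors]

    def test_shuffle_preserves_multiset(self):
        sc = make_small_scene(2, n_cells=30)
        sh = sf.shuffle_ratio_positions(sc, seed=4)
        assert sorted(c.true_ratio for c in sh.cells) == sorted(c.true_ratio for c in sc.cells)
        assert [c.center_um for c in sh.cells] == [c.center_um for c in sc.cells]
        assert np.mean([c.true_ratio for c in sh.cells]) == pytest.approx(
            np.mean([c.true_ratio for c in sc.cells])
        )

    def test_shuffle_destroys_spatial_structure(self):
        rs = []
        for seed in range(30):
            sc = make_small_scene(seed, n_cells=80)
            sh = sf.shuffle_ratio_positions(sc, seed=seed + 1000)
            rs.append(sf.oracle_neighbor_correlation(sh).r)
        assert abs(np.mean(rs)) < 0.05


class TestOracleCorrelation:
    def test_linear_ratio_gradient(self):
        cells = [CellTruth((10.0, 10.0, 10.0 + 10 * i), 5.0, 100.0, 1.5 + 0.1 * i) for i in range(15)]
        sc = sf.SyntheticScene(
            field_dims_um=(120.0, 186.0, 186.0), voxel_size_um=(2.0, 0.62, 0.62),
            cells=cells, distractors=[], field_params=sf.RatioFieldParams(), rng_seed=0,
        )
        res = sf.oracle_neighbor_correlation(sc, NeighborhoodSpec("knn", k=2))
        assert res.r > 0.97

    def test_needs_three_cells(self):
        sc = make_small_scene(0, n_cells=2)
        with pytest.raises(ValueError, match="at least 3"):
            sf.oracle_neighbor_correlation(sc)

    def test_type_i_control_on_nugget_only_scenes(self):
        """Without spatial structure the permutation test rejects at
        alpha=0.001 no more often than 1% of seeds.

        The permutation p is the calibrated inference for the neighbor-
        mean statistic; the parametric t-based p is anti-conservative
        here because overlapping neighborhoods violate the independence
        assumption (see the companion test below).
        """
        rejections = 0
        n_seeds = 200
        params = sf.RatioFieldParams(sill=0.0, nugget=0.1)
        for seed in range(n_seeds):
            sc = sf.make_scene(seed=seed, n_cells=250, field_params=params)
            p_emp, _, _ = permutation_null(
                list(range(len(sc.cells))), sc.cell_centers(), sc.cell_ratios(),
                NeighborhoodSpec("knn", k=5), n_perm=1999, seed=seed + 10_000,
            )
            rejections += p_emp < 0.001
        assert rejections / n_seeds <= 0.01

    def test_parametric_p_mildly_anticonservative_under_null(self):
        """The t-transform p inherits mild type-I inflation from the
        dependence between overlapping neighbor means: the empirical
        rejection rate at alpha=0.001 exceeds the nominal level but
        stays within a few-fold of it."""
        params = sf.RatioFieldParams(sill=0.0, nugget=0.1)
        ps = []
        for seed in range(200):
            sc = sf.make_scene(seed=seed, n_cells=250, field_params=params)
            ps.append(sf.oracle_neighbor_correlation(sc).p_value)
        rate = np.mean(np.asarray(ps) < 0.001)
        assert rate <= 0.04

    def test_power_on_structured_scenes(self):
        """Strong 30 um-range field, 250 cells: positive significant r in
        >=95% of seeds."""
        params = sf.RatioFieldParams(sill=0.1, range_um=30.0, nugget=0.0)
        hits = 0
        n_seeds = 50
        for seed in range(n_seeds):
            sc = sf.make_scene(seed=seed, n_cells=250, field_params=params)
            res = sf.oracle_neighbor_correlation(sc)
            hits += res.significant and res.r > 0
        assert hits / n_seeds >= 0.95


def test_scene_json_round_trip(tmp_path):
    sc = make_small_scene(7, n_cells=12)
    sc = sf.add_distractors(sc, 6, seed=2)
    path = write_scene(sc, tmp_path / "scene.json")
    back = read_scene(path)
    assert back.field_dims_um == sc.field_dims_um
    assert len(back.cells) == 12 and len(back.distractors) == 6
    assert back.cells[3].true_ratio == sc.cells[3].true_ratio
    assert back.distractors[1].shape == sc.distractors[1].shape
    assert back.distractors[1].waypoints_um == sc.distractors[1].waypoints_um


def test_make_scene_deterministic():
    a = make_small_scene(5, n_cells=15)
    b = make_small_scene(5, n_cells=15)
    assert [c.center_um for c in a.cells] == [c.center_um for c in b.cells]
    assert [c.true_ratio for c in a.cells] == [c.true_ratio for c in b.cells]
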