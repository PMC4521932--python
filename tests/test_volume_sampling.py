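import numpy as np
import pytest

from cbflat.correspondence import SurfacePair
from cbflat.io_formats import VertexMap, VolumeImage
from cbflat.mesh_core import TriangleMesh
from cbflat.volume_sampling import (SampledProfile, composite_map, integrate,
                                    one_sample_tmap, sample_profile,
                                    winner_take_all)


@pytest.fixture
def plane_pair(grid_mesh_factory):
    """Outer plane z=0, inner plane z=1, placed inside a 6^3 voxel grid."""
    base = grid_mesh_factory(4)
    outer_v = base.vertices.copy() + np.array([1.0, 1.0, 1.0])
    inner_v = outer_v.copy()
    inner_v[:, 2] = 2.0
    return SurfacePair(outer=TriangleMesh(outer_v, base.faces),
                       inner=TriangleMesh(inner_v, base.faces.copy()))


class TestSampleProfile:
    def test_constant_volume(self, plane_pair):
        vol = VolumeImage(np.full((6, 6, 6), 3.7), np.eye(4))
        prof = sample_profile(vol, plane_pair)
        np.testing.assert_allclose(prof.values, 3.7)

    def test_linear_field_reproduced_by_trilinear(self, plane_pair):
        # f(x, y, z) = z; sampling from z=1 to z=2 at five depths
        z = np.broadcast_to(np.arange(6.0), (6, 6, 6)).copy()
        vol = VolumeImage(z, np.eye(4))
        prof = sample_profile(vol, plane_pair,
                              depths=(0, 0.25, 0.5, 0.75, 1.0))
        expected = 1.0 + np.array([0, 0.25, 0.5, 0.75, 1.0])
        np.testing.assert_allclose(prof.values,
                                   np.tile(expected, (prof.n_vertices, 1)),
                                   atol=1e-12)

    def test_out_of_mask_midpoint_is_nan_only_there(self, plane_pair):
        vol = VolumeImage(np.ones((6, 6, 6)), np.eye(4))
        mask_data = np.ones((6, 6, 6), dtype=np.int32)
        # carve out the z=1.5 midplane region: nearest voxel plane k=1 or 2
        mask_data[:, :, 2] = 0
        mask = VolumeImage(mask_data, np.eye(4), kind="label")
        prof = sample_profile(vol, plane_pair, depths=(0.0, 0.5, 1.0),
                              mask=mask)
        # brute-force membership of each sample's nearest voxel
        depths = np.array([0.0, 0.5, 1.0])
        for vi in range(prof.n_vertices):
            s = plane_pair.outer.vertices[vi]
            e = plane_pair.inner.vertices[vi]
            for di, d in enumerate(depths):
                p = (1 - d) * s + d * e
                vox = np.round(p).astype(int)
                expect_nan = mask_data[tuple(vox)] == 0
                assert np.isnan(prof.values[vi, di]) == expect_nan

    def test_outside_volume_is_nan(self, plane_pair):
        vol = VolumeImage(np.ones((2, 2, 2)), np.eye(4))  # grid far too small
        prof = sample_profile(vol, plane_pair, depths=(1.0,))
        assert np.isnan(prof.values).all()

    def test_empty_depths_rejected(self, plane_pair):
        vol = VolumeImage(np.ones((6, 6, 6)), np.eye(4))
        with pytest.raises(ValueError, match="empty"):
            sample_profile(vol, plane_pair, depths=())

    def test_depths_must_increase(self):
        with pytest.raises(ValueError, match="increasing"):
            SampledProfile(np.zeros((2, 2)), np.array([0.5, 0.25]))


class TestIntegrate:
    def test_mean_of_linear_row(self):
        prof = SampledProfile(np.array([[0, 0.25, 0.5, 0.75, 1.0]]),
                              np.array([0, 0.25, 0.5, 0.75, 1.0]))
        assert integrate(prof, "mean").values[0] == pytest.approx(0.5)

    def test_mode_of_labels(self):
        prof = SampledProfile(np.array([[2, 2, 7, 7, 7]], dtype=float),
                              np.array([0, 0.25, 0.5, 0.75, 1.0]))
        out = integrate(prof, "mode")
        assert out.kind == "label" and out.values[0] == 7

    def test_mode_tie_prefers_smallest_label(self):
        prof = SampledProfile(np.array([[4, 4, 2, 2]], dtype=float),
                              np.array([0, 0.3, 0.6, 1.0]))
        assert integrate(prof, "mode").values[0] == 2

    def test_glass_brain_keeps_signed_extreme(self):
        prof = SampledProfile(np.array([[2.0, -5.0, 3.0]]),
                              np.array([0, 0.5, 1.0]))
        assert integrate(prof, "absmax").values[0] == -5.0

    def test_min_max(self):
        prof = SampledProfile(np.array([[2.0, -5.0, 3.0]]),
                              np.array([0, 0.5, 1.0]))
        assert integrate(prof, "min").values[0] == -5.0
        assert integrate(prof, "max").values[0] == 3.0

    def test_nan_ignored_and_all_nan_propagates(self):
        prof = SampledProfile(np.array([[1.0, np.nan], [np.nan, np.nan]]),
                              np.array([0, 1.0]))
        out = integrate(prof, "mean")
        assert out.values[0] == 1.0 and np.isnan(out.values[1])
        lab = integrate(SampledProfile(np.array([[np.nan, np.nan]]),
                                       np.array([0, 1.0])), "mode")
        assert lab.values[0] == 0  # unassigned, not an error

    def test_mode_rejects_non_integer(self):
        prof = SampledProfile(np.array([[1.5, 2.5]]), np.array([0, 1.0]))
        with pytest.raises(ValueError, match="integer"):
            integrate(prof, "mode")

    def test_absmax_dominates_mean(self):
        rng = np.random.default_rng(11)
        vals = rng.normal(size=(50, 5))
        prof = SampledProfile(vals, np.linspace(0, 1, 5))
        am = integrate(prof, "absmax").values
        mn = integrate(prof, "mean").values
        assert np.all(np.abs(am) >= np.abs(mn) - 1e-12)


class TestWinnerTakeAll:
    def _pair_and_probs(self, plane_pair, p1, p2):
        mk = lambda v: VolumeImage(np.full((6, 6, 6), v), np.eye(4),
                                   kind="probability")
        return [mk(p1), mk(p2)]

    def test_higher_average_wins(self, plane_pair):
        out = winner_take_all(self._pair_and_probs(plane_pair, 0.6, 0.3),
                              plane_pair)
        assert np.all(out.values == 1)
        out2 = winner_take_all(self._pair_and_probs(plane_pair, 0.3, 0.6),
                               plane_pair)
        assert np.all(out2.values == 2)

    def test_exact_tie_goes_to_lowest_index(self, plane_pair):
        out = winner_take_all(self._pair_and_probs(plane_pair, 0.4, 0.4),
                              plane_pair)
        assert np.all(out.values == 1)

    def test_all_zero_is_unassigned(self, plane_pair):
        out = winner_take_all(self._pair_and_probs(plane_pair, 0.0, 0.0),
                              plane_pair)
        assert np.all(out.values == 0)

    def test_invariant_under_common_scaling(self, plane_pair):
        rng = np.random.default_rng(5)
        vols = [VolumeImage(rng.uniform(0, 0.5, (6, 6, 6)), np.eye(4),
                            kind="probability") for _ in range(3)]
        base = winner_take_all(vols, plane_pair)
        scaled = [VolumeImage(v.data * 0.5, v.affine, kind="probability")
                  for v in vols]
        np.testing.assert_array_equal(
            winner_take_all(scaled, plane_pair).values, base.values)

    def test_grid_mismatch(self, plane_pair):
        a = VolumeImage(np.zeros((6, 6, 6)), np.eye(4), kind="probability")
        b = VolumeImage(np.zeros((5, 5, 5)), np.eye(4), kind="probability")
        with pytest.raises(ValueError, match="inconsistent"):
            winner_take_all([a, b], plane_pair)


class TestCompositeMap:
    def test_max_condition_above_threshold(self):
        maps = [VertexMap(np.array([30.0])), VertexMap(np.array([10.0]))]
        assert composite_map(maps, 25.0).values[0] == 1

    def test_below_threshold_unassigned(self):
        maps = [VertexMap(np.array([20.0])), VertexMap(np.array([10.0]))]
        assert composite_map(maps, 25.0).values[0] == 0

    def test_threshold_is_strict(self):
        assert composite_map([VertexMap(np.array([25.0]))], 25.0).values[0] == 0

    def test_empty_condition_list(self):
        with pytest.raises(ValueError, match="empty"):
            composite_map([], 25.0)


class TestOneSampleTMap:
    def _vols(self, stack):
        return [VolumeImage(s, np.eye(4)) for s in stack]

    def test_df_is_n_minus_one(self):
        vols = self._vols(np.random.default_rng(0).normal(
            size=(100, 2, 2, 2)))
        assert one_sample_tmap(vols).df == 99

    def test_all_zero_voxel_flagged_as_zero(self):
        vols = self._vols(np.zeros((3, 2, 2, 2)))
        out = one_sample_tmap(vols)
        assert np.all(out.t_values.data == 0.0)
        assert out.zero_variance.all()

    def test_hand_computed_t(self):
        # values {1,2,3}: t = mean/(sd/sqrt(n)) = 2/(1/sqrt(3)) = 3.4641
        stack = np.zeros((3, 1, 1, 1))
        stack[:, 0, 0, 0] = [1.0, 2.0, 3.0]
        out = one_sample_tmap(self._vols(stack))
        assert out.t_values.data[0, 0, 0] == pytest.approx(2 * np.sqrt(3),
                                                           abs=1e-4)
        assert out.df == 2

    def test_requires_two_subjects(self):
        with pytest.raises(ValueError, match="at least 2"):
            one_sample_tmap(self._vols(np.zeros((1, 2, 2, 2))))
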