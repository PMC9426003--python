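"""Distance maps, the EUL power-mean metric and assistant-structure morphology."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import eulplan as ep
from eulplan._power_mean import power_mean
from eulplan.grid import EmptyStructureError, GeometryMismatchError

from conftest import brute_force_distance_cm, make_mask


class TestDistanceMap:
    def test_axis_distance_isotropic(self):
        ptv = make_mask((1, 1, 8), [(0, 0, 0)])
        dmap = ep.distance_map(ptv)
        assert dmap.values_cm[0, 0, 3] == pytest.approx(3.0)

    def test_zero_inside_source(self):
        ptv = make_mask((4, 4, 4), [(1, 1, 1), (2, 2, 2)])
        dmap = ep.distance_map(ptv)
        assert dmap.values_cm[1, 1, 1] == 0.0
        assert dmap.values_cm[2, 2, 2] == 0.0

    def test_anisotropic_spacing(self):
        ptv = make_mask((2, 3, 2), [(0, 0, 0)], spacing_mm=(10, 20, 10))
        dmap = ep.distance_map(ptv)
        assert dmap.values_cm[0, 1, 0] == pytest.approx(2.0)

    def test_empty_source_rejected(self):
        with pytest.raises(EmptyStructureError):
            ep.distance_map(make_mask((3, 3, 3), []))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        shape = (9, 12, 10)
        vox = rng.random(shape) < 0.04
        vox[4, 6, 5] = True  # guarantee nonempty
        ptv = make_mask(
            shape, np.argwhere(vox), spacing_mm=(3.0, 1.5, 1.5)
        )
        dmap = ep.distance_map(ptv)
        expected = brute_force_distance_cm(ptv)
        np.testing.assert_allclose(dmap.values_cm, expected, atol=1e-9)


class TestEUL:
    def _toy(self):
        # PTV at x=0; organ voxels at 1.0 and 3.0 cm along x.
        ptv = make_mask((1, 1, 5), [(0, 0, 0)])
        oar = make_mask((1, 1, 5), [(0, 0, 1), (0, 0, 3)], label="oar")
        return ep.distance_map(ptv), oar

    def test_arithmetic_mean_at_a1(self):
        dmap, oar = self._toy()
        assert ep.compute_eul(dmap, oar, a=1) == pytest.approx(2.0)

    def test_quadratic_mean(self):
        dmap, oar = self._toy()
        assert ep.compute_eul(dmap, oar, a=2) == pytest.approx(np.sqrt(5.0))

    def test_organ_inside_ptv_gives_zero(self):
        ptv = make_mask((2, 2, 2), [(0, 0, 0), (0, 0, 1)])
        oar = make_mask((2, 2, 2), [(0, 0, 1)], label="oar")
        assert ep.compute_eul(ep.distance_map(ptv), oar, a=1) == 0.0

    def test_a_zero_and_empty_oar_rejected(self):
        dmap, oar = self._toy()
        with pytest.raises(ValueError):
            ep.compute_eul(dmap, oar, a=0)
        with pytest.raises(EmptyStructureError):
            ep.compute_eul(dmap, make_mask((1, 1, 5), [], label="oar"))

    def test_negative_a_with_zero_distance_rejected(self):
        ptv = make_mask((1, 1, 5), [(0, 0, 0)])
        oar = make_mask((1, 1, 5), [(0, 0, 0), (0, 0, 2)], label="oar")
        with pytest.raises(ValueError):
            ep.compute_eul(ep.distance_map(ptv), oar, a=-1)

    def test_a1_equals_mean_distance(self):
        rng = np.random.default_rng(7)
        shape = (6, 8, 8)
        ptv = make_mask(shape, [(3, 4, 4)])
        organ_vox = rng.random(shape) < 0.2
        organ_vox[3, 4, 4] = False
        oar = make_mask(shape, np.argwhere(organ_vox), label="oar")
        dmap = ep.distance_map(ptv)
        assert ep.compute_eul(dmap, oar, a=1) == pytest.approx(
            dmap.values_cm[oar.voxels].mean(), abs=1e-12
        )


@settings(derandomize=True, max_examples=60)
@given(
    st.lists(st.floats(0.05, 50.0), min_size=2, max_size=30).filter(
        lambda xs: max(xs) / min(xs) > 1.001
    )
)
def test_power_mean_strictly_increasing_in_a(values):
    """For non-constant positive data the power mean grows with its order."""
    means = [power_mean(np.array(values), a) for a in (0.5, 1, 2, 4)]
    assert all(lo < hi for lo, hi in zip(means, means[1:]))


class TestDilateRing:
    def test_margin_zero_is_identity(self):
        mask = make_mask((3, 3, 3), [(1, 1, 1)])
        out = ep.dilate(mask, 0.0)
        np.testing.assert_array_equal(out.voxels, mask.voxels)

    def test_margin_one_cm_gives_face_cross(self):
        mask = make_mask((5, 5, 5), [(2, 2, 2)])
        out = ep.dilate(mask, 1.0)
        assert out.n_voxels == 7  # centre + 6 face neighbours at exactly 1 cm

    def test_margin_below_edge_neighbour_distance(self):
        # edge neighbours sit at sqrt(2) ~ 1.414 cm > 1.4 cm
        mask = make_mask((5, 5, 5), [(2, 2, 2)])
        assert ep.dilate(mask, 1.4).n_voxels == 7

    def test_negative_margin_rejected(self):
        mask = make_mask((3, 3, 3), [(1, 1, 1)])
        with pytest.raises(ValueError):
            ep.dilate(mask, -0.1)

    def test_dilate_matches_distance_threshold_oracle(self):
        rng = np.random.default_rng(3)
        shape = (8, 9, 7)
        vox = rng.random(shape) < 0.05
        vox[4, 4, 3] = True
        mask = make_mask(shape, np.argwhere(vox), spacing_mm=(4.0, 2.0, 3.0))
        expected = brute_force_distance_cm(mask) <= 0.75
        np.testing.assert_array_equal(ep.dilate(mask, 0.75).voxels, expected)

    def test_ring_of_single_voxel(self):
        ptv = make_mask((5, 5, 5), [(2, 2, 2)])
        shell = ep.ring(ptv, 0.5, 1.0)
        assert shell.n_voxels == 6  # the face neighbours, centre excluded

    def test_adjacent_rings_disjoint(self):
        ptv = make_mask((7, 7, 7), [(3, 3, 3)])
        r1 = ep.ring(ptv, 0.5, 1.0)
        r2 = ep.ring(ptv, 1.0, 1.5)
        assert not (r1.voxels & r2.voxels).any()

    def test_ring_from_zero_equals_dilation_minus_source(self):
        ptv = make_mask((7, 7, 7), [(3, 3, 3), (3, 3, 4)])
        shell = ep.ring(ptv, 0.0, 1.2)
        expected = ep.dilate(ptv, 1.2).voxels & ~ptv.voxels
        np.testing.assert_array_equal(shell.voxels, expected)

    def test_ring_partition_tiles_full_shell(self):
        ptv = make_mask((16, 16, 16), [(8, 8, 8), (8, 8, 9), (8, 9, 8)])
        bounds = [(0.5, 1.0), (1.0, 1.5), (1.5, 2.5), (2.5, 3.5), (3.5, 4.5)]
        shells = [ep.ring(ptv, lo, hi).voxels for lo, hi in bounds]
        count = sum(s.astype(int) for s in shells)
        assert count.max() <= 1  # pairwise disjoint
        union = np.logical_or.reduce(shells)
        np.testing.assert_array_equal(union, ep.ring(ptv, 0.5, 4.5).voxels)

    def test_inner_not_below_outer_rejected(self):
        ptv = make_mask((3, 3, 3), [(1, 1, 1)])
        with pytest.raises(ValueError):
            ep.ring(ptv, 1.0, 1.0)


class TestPreliminaryAS:
    def _grids(self, dose_values):
        geom = ep.GridGeometry((4, 4, 4), spacing_mm=(5, 5, 5))
        body = ep.StructureMask(geom, np.ones((4, 4, 4), bool), "body")
        return ep.DoseGrid(geom, dose_values), body

    def test_uniform_prescription_covers_body(self):
        dose, body = self._grids(np.full((4, 4, 4), 59.4))
        prelim = ep.preliminary_as(dose, body, rx_gy=59.4)
        assert prelim.n_voxels == body.n_voxels

    def test_zero_dose_gives_empty_mask(self):
        dose, body = self._grids(np.zeros((4, 4, 4)))
        assert ep.preliminary_as(dose, body, rx_gy=59.4).is_empty

    def test_threshold_selects_box(self):
        values = np.full((4, 4, 4), 10.0)
        values[1:3, 1:3, 1:3] = 30.0
        dose, body = self._grids(values)
        prelim = ep.preliminary_as(dose, body, rx_gy=59.4)  # threshold 23.76
        np.testing.assert_array_equal(prelim.voxels, values >= 23.76)

    def test_invalid_prescription_rejected(self):
        dose, body = self._grids(np.zeros((4, 4, 4)))
        with pytest.raises(ValueError):
            ep.preliminary_as(dose, body, rx_gy=0.0)


class TestAssistantStructures:
    def test_empty_preliminary_leaves_only_as4(self, small_phantom_spec):
        masks = ep.build_phantom(small_phantom_spec, seed=0)
        ptv = masks["PTV"]
        prelim = ep.StructureMask(
            ptv.geometry, np.zeros(ptv.geometry.shape, bool), "prelim"
        )
        asset = ep.generate_assistant_structures(ptv, prelim)
        for name in ("as1", "as2", "as3", "as5", "as6"):
            assert getattr(asset, name).is_empty
        np.testing.assert_array_equal(
            asset.as4.voxels, ep.ring(ptv, 3.5, 4.5).voxels
        )

    def test_set_arithmetic_matches_definitions(self, small_phantom_spec):
        """Voxel-by-voxel comparison against the boolean-algebra definitions."""
        masks = ep.build_phantom(small_phantom_spec, seed=4)
        ptv, body = masks["PTV"], masks["body"]
        dose = ep.simulate_ap_pa_dose(masks, 59.4)
        prelim = ep.preliminary_as(dose, body, 59.4)
        asset = ep.generate_assistant_structures(ptv, prelim)

        p = prelim.voxels
        shells = {
            b: ep.ring(ptv, *b).voxels
            for b in [(0.5, 1.0), (1.0, 1.5), (1.5, 2.5), (2.5, 3.5), (3.5, 4.5)]
        }
        np.testing.assert_array_equal(asset.as1.voxels, p & shells[(0.5, 1.0)])
        np.testing.assert_array_equal(asset.as2.voxels, p & shells[(1.0, 1.5)])
        np.testing.assert_array_equal(asset.as3.voxels, p & shells[(1.5, 2.5)])
        np.testing.assert_array_equal(asset.as5.voxels, p & shells[(3.5, 4.5)])
        np.testing.assert_array_equal(
            asset.as4.voxels,
            (p & shells[(2.5, 3.5)]) | (shells[(3.5, 4.5)] & ~p),
        )
        others = (
            asset.as1.voxels | asset.as2.voxels | asset.as3.voxels
            | asset.as4.voxels | asset.as5.voxels
        )
        expected_as6 = p & ~others & ~ep.dilate(ptv, 0.5).voxels
        np.testing.assert_array_equal(asset.as6.voxels, expected_as6)
        union = others | asset.as6.voxels
        assert not (union & ~(p | shells[(3.5, 4.5)])).any()

    def test_invariants_on_randomized_phantoms(self, small_phantom_spec):
        rng = np.random.default_rng(11)
        for i in range(200):
            spec = small_phantom_spec.with_gaps(
                anterior_cm=float(rng.uniform(0.2, 1.6)),
                posterior_cm=float(rng.uniform(0.2, 1.6)),
            )
            masks = ep.build_phantom(spec, seed=i)
            dose = ep.simulate_ap_pa_dose(masks, 59.4)
            prelim = ep.preliminary_as(dose, masks["body"], 59.4)
            asset = ep.generate_assistant_structures(masks["PTV"], prelim)
            asset.validate(masks["PTV"])  # raises on overlap / PTV contact

    def test_geometry_mismatch_rejected(self, small_phantom_spec):
        masks = ep.build_phantom(small_phantom_spec, seed=0)
        other = ep.GridGeometry((4, 4, 4), spacing_mm=(5, 5, 5))
        prelim = ep.StructureMask(other, np.zeros((4, 4, 4), bool))
        with pytest.raises(GeometryMismatchError):
            ep.generate_assistant_structures(masks["PTV"], prelim)
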