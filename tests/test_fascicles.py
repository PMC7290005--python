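"""Slab placement, intersection windows, and pathway-unit counting."""

import numpy as np
import pytest

from conftest import flood_fill_components
from thmorph.counting import SphereParams
from thmorph.fascicles import (SlabSpec, SlabConstraintError, LocalizationError,
                               locate_rostral_limit, place_slab,
                               find_intersection_windows, count_pathway_units,
                               defasciculation_metrics, measure_pathway_units)
from thmorph.phantom import (PhantomSpec, TractSpec, OpticsSpec, generate_phantom,
                             rasterize_tube, default_study_spec)
from thmorph.segmentation import SegmentationParams, segment
from thmorph.volume import Volume3D, ReferenceCuboid, crop


def seg_params(threshold=0.5):
    return SegmentationParams(threshold=threshold, threshold_percentile=None,
                              min_component_voxels=1)


def tract_phantom(n, seed, dlo=10.0, dhi=12.0):
    """Disjoint-lane fascicles, no nuclei, no fibers."""
    return PhantomSpec(tract=TractSpec(n_fascicles=n, fascicle_diameter_um=(dlo, dhi),
                                       n_dispersed_fibers=0), seed=seed)


class TestLocateRostralLimit:
    def test_single_voxel_mask(self):
        data = np.zeros((6, 10, 6), np.float32)
        data[3, 7, 2] = 1.0
        mask = segment(Volume3D(data, (1, 1, 1)), seg_params())
        assert locate_rostral_limit(mask) == pytest.approx(7.5)  # center of voxel 7

    def test_empty_mask_raises(self):
        mask = segment(Volume3D(np.zeros((4, 4, 4), np.float32), (1, 1, 1)),
                       seg_params())
        with pytest.raises(LocalizationError):
            locate_rostral_limit(mask)

    def test_matches_generator_ground_truth(self):
        spec = default_study_spec(seed=21)
        vol, truth = generate_phantom(spec)
        from thmorph.segmentation import subtract_background

        bg = subtract_background(vol, 80.0)
        a_roi = ReferenceCuboid("A11_13", (110, 140, 110), (230, 270, 250))
        mask = segment(crop(bg, a_roi), seg_params(threshold=40))
        limit = locate_rostral_limit(mask)
        # within one voxel spacing of the rostral-most soma surface
        assert abs(limit - truth.a1113_mask_rostral_um) <= spec.voxel_spacing_um[1]

    def test_respects_axis_direction(self):
        data = np.zeros((4, 10, 4), np.float32)
        data[2, 3, 2] = data[2, 8, 2] = 1.0
        low = segment(Volume3D(data, (1, 1, 1), rostral_sign=-1), seg_params())
        high = segment(Volume3D(data, (1, 1, 1), rostral_sign=+1), seg_params())
        assert locate_rostral_limit(low) == pytest.approx(3.5)
        assert locate_rostral_limit(high) == pytest.approx(8.5)


class TestPlaceSlab:
    def test_thickness_equal_to_sphere_diameter_accepted(self):
        spec = SlabSpec(thickness_um=12.0, sphere_params=SphereParams(12.0, 0.5))
        assert spec.thickness_um == 12.0

    def test_thickness_above_sphere_diameter_rejected(self):
        with pytest.raises(SlabConstraintError):
            SlabSpec(thickness_um=12.0 + 1e-6, sphere_params=SphereParams(12.0, 0.5))

    def test_interval_arithmetic_rostral_increasing(self):
        vol = Volume3D(np.zeros((10, 100, 10), np.float32), (10, 10, 10),
                       rostral_sign=+1)
        spec = SlabSpec(thickness_um=12.0, sphere_params=SphereParams(12.0, 0.5))
        slab = place_slab(vol, spec, rostral_limit_um=350.0)
        assert slab.min_um[1] == 350.0 and slab.max_um[1] == 362.0

    def test_slab_extends_rostrally_with_default_direction(self):
        # rostral at low index: the slab lies rostral (below) the limit, so it
        # can never overlap the cell group it is anchored to
        vol = Volume3D(np.zeros((10, 100, 10), np.float32), (10, 10, 10))
        spec = SlabSpec(thickness_um=12.0, sphere_params=SphereParams(12.0, 0.5))
        slab = place_slab(vol, spec, rostral_limit_um=350.0)
        assert slab.min_um[1] == 338.0 and slab.max_um[1] == 350.0


class TestIntersectionWindows:
    def make_mask(self, n_tubes, merge=False):
        vol = Volume3D(np.zeros((30, 80, 100), np.float32), (7, 5, 5))
        for i in range(n_tubes):
            x = 50 + 55 * i
            if merge and i == 1:
                line = [(100, 390, x), (100, 180, 55), (100, 30, x)]
            else:
                line = [(100, 390, x), (100, 30, x)]
            vol = rasterize_tube(line, 14.0, vol, 100.0)
        return segment(vol, seg_params(threshold=50))

    def slab(self):
        return ReferenceCuboid("slab", (0, 174, 0), (210, 186, 500))

    def spec(self):
        return SlabSpec(thickness_um=12.0, sphere_params=SphereParams(12.0, 0.5),
                        min_fascicle_diameter_um=8.0)

    def test_no_fascicles_in_slab(self):
        mask = self.make_mask(0)
        assert find_intersection_windows(mask, self.slab(), self.spec()) == []

    def test_seven_disjoint_tubes_seven_windows(self):
        mask = self.make_mask(7)
        windows = find_intersection_windows(mask, self.slab(), self.spec())
        assert len(windows) == 7
        # cross-check against the flood-fill oracle on the clipped mask
        clipped = mask.labels[:, 35:38, :] > 0  # y centers 177.5..187.5
        assert len(flood_fill_components(clipped, 26)) == 7

    def test_tubes_merging_inside_slab_are_one_window(self):
        mask = self.make_mask(2, merge=True)
        windows = find_intersection_windows(mask, self.slab(), self.spec())
        assert len(windows) == 1

    def test_min_intensity_rule_drops_dim_components(self):
        vol = Volume3D(np.zeros((30, 80, 100), np.float32), (7, 5, 5))
        vol = rasterize_tube([(100, 390, 50), (100, 30, 50)], 14.0, vol, 100.0)
        vol = rasterize_tube([(100, 390, 300), (100, 30, 300)], 14.0, vol, 30.0)
        mask = segment(vol, seg_params(threshold=20))
        spec = self.spec()
        assert len(find_intersection_windows(mask, self.slab(), spec)) == 2
        spec.min_fascicle_intensity = 60.0
        assert len(find_intersection_windows(mask, self.slab(), spec)) == 1


class TestCountPathwayUnits:
    def test_empty_window_list(self):
        res = count_pathway_units([], SlabSpec(thickness_um=10.0,
                                               sphere_params=SphereParams(12.0, 0.5)))
        assert res.total_units == 0

    def test_small_window_floor_rule(self):
        # a window far smaller than one sphere still contributes exactly 1 unit
        vol = Volume3D(np.zeros((20, 40, 20), np.float32), (7, 5, 5))
        vol = rasterize_tube([(66.5, 130, 47.5), (66.5, 30, 47.5)], 9.0, vol, 100.0)
        mask = segment(vol, seg_params(threshold=50))
        slab = ReferenceCuboid("slab", (0, 74, 0), (140, 86, 100))
        spec = SlabSpec(thickness_um=12.0, sphere_params=SphereParams(12.0, 0.5),
                        min_fascicle_diameter_um=4.0)
        windows = find_intersection_windows(mask, slab, spec)
        assert len(windows) == 1
        res = count_pathway_units(windows, spec, frame=mask.frame, slab=slab)
        assert res.window_units == [1]

    @pytest.mark.parametrize("n", [3, 7, 12])
    def test_disjoint_fascicles_give_exact_units(self, n):
        spec = tract_phantom(n, seed=77)
        vol, truth = generate_phantom(spec)
        mask = segment(vol, seg_params(threshold=40))
        sspec = SlabSpec(thickness_um=12.0, rostral_limit_um=160.0,
                         sphere_params=SphereParams(12.0, 0.5),
                         min_fascicle_diameter_um=8.0, min_fascicle_intensity=110.0)
        res = measure_pathway_units(mask, sspec)
        assert res.total_units == n == len(truth.fascicles)

    def test_lateral_over_extension_adds_no_units(self):
        spec = tract_phantom(5, seed=13)
        vol, _ = generate_phantom(spec)
        mask = segment(vol, seg_params(threshold=40))
        base = SlabSpec(thickness_um=12.0, rostral_limit_um=160.0,
                        sphere_params=SphereParams(12.0, 0.5),
                        min_fascicle_diameter_um=8.0, min_fascicle_intensity=110.0)
        narrow = SlabSpec(thickness_um=12.0, rostral_limit_um=160.0,
                          sphere_params=SphereParams(12.0, 0.5),
                          min_fascicle_diameter_um=8.0, min_fascicle_intensity=110.0,
                          lateral_bounds_um={0: (0.0, 130.0), 2: (20.0, 340.0)})
        assert (measure_pathway_units(mask, base).total_units
                == measure_pathway_units(mask, narrow).total_units == 5)

    def test_adding_a_fascicle_never_decreases_units(self):
        totals = []
        for n in (4, 5):
            vol, _ = generate_phantom(tract_phantom(n, seed=5))
            mask = segment(vol, seg_params(threshold=40))
            sspec = SlabSpec(thickness_um=12.0, rostral_limit_um=160.0,
                             sphere_params=SphereParams(12.0, 0.5),
                             min_fascicle_diameter_um=8.0)
            totals.append(measure_pathway_units(mask, sspec).total_units)
        assert totals[1] >= totals[0]

    def test_repeat_measurement_identical(self):
        vol, _ = generate_phantom(tract_phantom(6, seed=8))
        mask = segment(vol, seg_params(threshold=40))
        sspec = SlabSpec(thickness_um=12.0, rostral_limit_um=160.0,
                         sphere_params=SphereParams(12.0, 0.5),
                         min_fascicle_diameter_um=8.0)
        r1 = measure_pathway_units(mask, sspec)
        r2 = measure_pathway_units(mask, sspec)
        assert r1.total_units == r2.total_units
        assert r1.window_units == r2.window_units


class TestDefasciculation:
    def _windows(self, xs):
        class W:  # minimal stand-in with the two used fields
            def __init__(self, x):
                self.centroid_um = np.array([50.0, 100.0, x])
                self.voxel_count = 10
        return [W(x) for x in xs]

    def test_single_position_width_zero(self):
        slab = ReferenceCuboid("s", (0, 0, 0), (100, 12, 100))
        m = defasciculation_metrics(self._windows([40.0] * 5), slab)
        assert m.tract_width_um == 0.0

    def test_all_voxels_bundled_fraction_one(self):
        slab = ReferenceCuboid("s", (0, 0, 0), (100, 12, 100))
        m = defasciculation_metrics(self._windows([10, 50, 90]), slab,
                                    admitted_voxels_in_slab=30)
        assert m.bundled_fraction == 1.0

    def test_empty_windows_width_zero_fraction_undefined(self):
        slab = ReferenceCuboid("s", (0, 0, 0), (100, 12, 100))
        m = defasciculation_metrics([], slab)
        assert m.tract_width_um == 0.0
        assert not m.bundled_fraction_defined

    def test_generator_spread_monotonicity(self):
        widths = []
        for mult in (1.0, 3.0):
            tract = TractSpec(n_fascicles=10, n_dispersed_fibers=0,
                              min_fascicle_separation_um=None,
                              spread_um=12.0 * mult)
            vol, _ = generate_phantom(PhantomSpec(tract=tract, seed=17))
            mask = segment(vol, seg_params(threshold=40))
            sspec = SlabSpec(thickness_um=12.0, rostral_limit_um=160.0,
                             sphere_params=SphereParams(12.0, 0.5),
                             min_fascicle_diameter_um=8.0)
            res = measure_pathway_units(mask, sspec)
            widths.append(res.defasciculation.tract_width_um)
        assert widths[1] > widths[0]
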