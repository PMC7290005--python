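"""Phantom generation: determinism, ground-truth fidelity, rasterization."""

import numpy as np
import pytest

from conftest import flood_fill_components
from thmorph.phantom import (PhantomSpec, NucleusSpec, TractSpec, VesselSpec,
                             OpticsSpec, NoiseSpec, GroundTruth, PlacementError,
                             generate_phantom, rasterize_tube,
                             apply_optics_and_noise, default_study_spec)
from thmorph.volume import Volume3D


def clean_spec(**kw):
    """Phantom with optics and noise disabled (pure rasterization)."""
    kw.setdefault("optics", OpticsSpec(blur_sigma_um=(0, 0, 0)))
    kw.setdefault("noise", None)
    return PhantomSpec(**kw)


class TestDeterminism:
    def test_same_spec_and_seed_bit_identical(self):
        spec = default_study_spec(seed=5)
        v1, g1 = generate_phantom(spec)
        v2, g2 = generate_phantom(default_study_spec(seed=5))
        np.testing.assert_array_equal(v1.data, v2.data)
        assert g1.to_json() == g2.to_json()

    def test_different_seeds_differ(self):
        v1, _ = generate_phantom(default_study_spec(seed=5))
        v2, _ = generate_phantom(default_study_spec(seed=6))
        assert not np.array_equal(v1.data, v2.data)

    def test_noise_field_reproducible(self):
        spec = PhantomSpec(volume_shape_voxels=(6, 8, 8), seed=3)
        vol = Volume3D(np.zeros((6, 8, 8), np.float32), spec.voxel_spacing_um)
        n1 = apply_optics_and_noise(vol, spec)
        n2 = apply_optics_and_noise(vol, spec)
        np.testing.assert_array_equal(n1.data, n2.data)


def test_ground_truth_fidelity_component_count():
    # noise/blur off, 25 well-separated somata -> exactly 25 components at
    # half soma intensity, against the flood-fill oracle
    nuc = NucleusSpec("VTA", center_um=(150, 240, 180), semi_axes_um=(80, 110, 110),
                      n_somata=25, min_separation_um=26.0,
                      soma_diameter_jitter_um=0.0, soma_intensity_jitter=0.0)
    spec = clean_spec(nuclei=[nuc], seed=9)
    vol, truth = generate_phantom(spec)
    comps = flood_fill_components(vol.data >= nuc.soma_intensity / 2, 26)
    assert len(comps) == 25
    assert len(truth.somata["VTA"]["centers_um"]) == 25


def test_somata_lie_inside_envelope():
    nuc = NucleusSpec("SN_left", center_um=(150, 240, 180), semi_axes_um=(60, 80, 70),
                      n_somata=40, min_separation_um=14.0)
    _, truth = generate_phantom(clean_spec(nuclei=[nuc], seed=2))
    c = np.array(truth.somata["SN_left"]["centers_um"])
    u = (c - np.array(nuc.center_um)) / np.array(nuc.semi_axes_um)
    assert np.all((u ** 2).sum(axis=1) <= 1.0 + 1e-9)


def test_placement_failure_names_nucleus():
    nuc = NucleusSpec("A11_13", center_um=(100, 100, 100), semi_axes_um=(12, 12, 12),
                      n_somata=200, min_separation_um=14.0)
    with pytest.raises(PlacementError, match="A11_13"):
        generate_phantom(clean_spec(nuclei=[nuc], seed=0,
                                    volume_shape_voxels=(30, 40, 40)))


class TestRasterizeTube:
    def test_cylinder_volume_within_15pct(self):
        vol = Volume3D(np.zeros((40, 150, 40), np.float32), (7, 5, 5))
        line = [(140, 20, 100), (140, 720, 100)]  # 700 um, axis-aligned
        out = rasterize_tube(line, 20.0, vol, 1.0)
        voxel_vol = 7 * 5 * 5
        analytic = np.pi * 10**2 * 700
        assert abs((out.data > 0).sum() * voxel_vol - analytic) / analytic < 0.15

    def test_zero_length_centerline_gives_sphere(self):
        vol = Volume3D(np.zeros((20, 20, 20), np.float32), (1, 1, 1))
        out = rasterize_tube([(10, 10, 10)], 8.0, vol, 1.0)
        zz, yy, xx = np.meshgrid(*[np.arange(20) + 0.5] * 3, indexing="ij")
        dist = np.sqrt((zz - 10) ** 2 + (yy - 10) ** 2 + (xx - 10) ** 2)
        np.testing.assert_array_equal(out.data > 0, dist <= 4.0)

    def test_two_parallel_tubes_are_two_components(self):
        vol = Volume3D(np.zeros((30, 60, 60), np.float32), (1, 1, 1))
        out = rasterize_tube([(15, 5, 15), (15, 55, 15)], 6.0, vol, 1.0)
        out = rasterize_tube([(15, 5, 45), (15, 55, 45)], 6.0, out, 1.0)
        comps = flood_fill_components(out.data >= 0.5, 26)
        assert len(comps) == 2

    def test_tube_is_connected_along_length(self):
        vol = Volume3D(np.zeros((30, 80, 60), np.float32), (7, 5, 5))
        line = [(100, 20, 100), (60, 150, 180), (120, 350, 240)]
        out = rasterize_tube(line, 12.0, vol, 1.0)
        assert len(flood_fill_components(out.data > 0, 26)) == 1

    def test_diameter_below_spacing_rejected(self):
        vol = Volume3D(np.zeros((10, 10, 10), np.float32), (7, 5, 5))
        with pytest.raises(ValueError):
            rasterize_tube([(10, 10, 10), (10, 40, 10)], 6.0, vol, 1.0)


class TestOpticsAndNoise:
    def test_zero_blur_no_noise_is_identity(self, rng):
        data = rng.random((6, 8, 8)).astype(np.float32) * 50
        vol = Volume3D(data, (7, 5, 5))
        spec = PhantomSpec(volume_shape_voxels=(6, 8, 8),
                           optics=OpticsSpec((0, 0, 0)), noise=None, seed=1)
        np.testing.assert_array_equal(apply_optics_and_noise(vol, spec).data, data)

    def test_blur_conserves_total_intensity(self):
        # interior structure, blur only: normalized convolution conserves sum
        data = np.zeros((40, 60, 60), np.float32)
        data[18:22, 28:32, 28:32] = 100.0
        vol = Volume3D(data, (7, 5, 5))
        spec = PhantomSpec(volume_shape_voxels=(40, 60, 60), noise=None, seed=1)
        out = apply_optics_and_noise(vol, spec)
        assert abs(out.data.sum() - data.sum()) / data.sum() < 0.01

    def test_blur_sigma_is_physical(self):
        # same physical sigma, different sampling -> same physical profile width
        spec = PhantomSpec(volume_shape_voxels=(41, 41, 41),
                           voxel_spacing_um=(1, 1, 1),
                           optics=OpticsSpec((0, 4.0, 0)), noise=None)
        data = np.zeros((41, 41, 41), np.float32)
        data[20, 20, 20] = 1.0
        out = apply_optics_and_noise(Volume3D(data, (1, 1, 1)), spec)
        profile = out.data[20, :, 20]
        sigma_est = np.sqrt(np.sum(profile * (np.arange(41) - 20.0) ** 2) / profile.sum())
        assert abs(sigma_est - 4.0) < 0.1


class TestTract:
    def test_centerlines_monotone_in_rostrocaudal_coordinate(self):
        spec = default_study_spec(seed=4)
        _, truth = generate_phantom(spec)
        rc = spec.rostrocaudal_axis
        for f in truth.fascicles:
            coords = np.array(f["centerline_um"])[:, rc]
            assert np.all(np.diff(coords) < 0)  # runs caudal -> rostral

    def test_every_fascicle_crosses_interior_plane_once(self):
        spec = default_study_spec(seed=4)
        _, truth = generate_phantom(spec)
        rc = spec.rostrocaudal_axis
        for plane in (100.0, 250.0, 400.0):
            for f in truth.fascicles:
                coords = np.array(f["centerline_um"])[:, rc]
                crossings = np.sum(np.diff(np.sign(coords - plane)) != 0)
                assert crossings == 1

    def test_spread_widens_lateral_scatter(self):
        base = dict(n_fascicles=10, n_dispersed_fibers=0,
                    min_fascicle_separation_um=None)
        narrow = TractSpec(spread_um=10.0, **base)
        wide = TractSpec(spread_um=30.0, **base)
        widths = []
        for tract in (narrow, wide):
            spec = clean_spec(tract=tract, seed=11)
            _, truth = generate_phantom(spec)
            x = [np.array(f["centerline_um"])[:, 2].mean() for f in truth.fascicles]
            widths.append(np.std(x))
        assert widths[1] > widths[0]


def test_vessel_invariant_length_vs_diameter():
    with pytest.raises(ValueError):
        VesselSpec(n_vessels=1, diameter_um=20.0, length_um=50.0)


def test_ground_truth_json_roundtrip(tmp_path):
    _, truth = generate_phantom(default_study_spec(seed=7))
    truth.to_json(tmp_path / "gt.json")
    back = GroundTruth.from_json(tmp_path / "gt.json")
    assert back.to_json() == truth.to_json()
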