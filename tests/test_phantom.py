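import numpy as np
import pytest

from pulmoct.geometry import voxel_volume_mm3
from pulmoct.phantom import (
    GridSpec,
    NoduleSpec,
    PhantomScene,
    VesselParams,
    WirePhantomSpec,
    _tree_segments,
    assemble_phantom,
    generate_sphere_mask,
    generate_spiked_sphere_mask,
    generate_vessel_tree,
    generate_wire_image,
    make_grid,
)
from scipy import ndimage

CONN26 = np.ones((3, 3, 3), dtype=bool)


class TestMakeGrid:
    def test_uniform_fill_and_extent(self):
        vol = make_grid((10, 10, 10), (1, 1, 1), fill_hu=-875)
        assert np.all(vol.values == -875)
        assert vol.extent_mm() == pytest.approx((10, 10, 10))

    def test_extent_arithmetic(self):
        vol = make_grid((256, 256, 64), (0.13, 0.13, 0.25))
        assert vol.extent_mm() == pytest.approx((33.28, 33.28, 16.0))

    def test_reconstruction_grid_spacing(self):
        vol = make_grid((4, 4, 4), (0.13, 0.13, 0.625))
        assert vol.spacing == (0.13, 0.13, 0.625)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            make_grid((0, 4, 4), (1, 1, 1))
        with pytest.raises(ValueError):
            make_grid((4, 4, 4), (1, -1, 1))


def sphere_volume(d):
    return 4 / 3 * np.pi * (d / 2) ** 3


class TestSphereMask:
    def test_volume_converges_to_closed_form(self, sphere_9mm, fine_grid):
        vol = sphere_9mm.voxel_count * 0.05**3
        assert vol == pytest.approx(sphere_volume(9.0), rel=0.01)

    def test_voxelization_error_decreases_with_spacing(self):
        # worst case over sub-voxel placements, to avoid fortuitous
        # cancellation at lattice-aligned centres
        errs = []
        for s in (0.2, 0.1, 0.05):
            n = int(12 / s) + 2
            grid = GridSpec(shape=(n, n, n), spacing_mm=(s, s, s))
            worst = 0.0
            for off in [(0.0, 0.0, 0.0), (0.37, 0.11, 0.23), (0.5, 0.5, 0.5)]:
                center = tuple(6 + o * s for o in off)
                mask = generate_sphere_mask(
                    NoduleSpec(kind="sphere", diameter_mm=9, center_mm=center), grid
                )
                worst = max(worst, abs(mask.voxel_count * s**3 - sphere_volume(9.0)))
            errs.append(worst)
        assert errs[0] > errs[1] > errs[2]

    def test_subvoxel_sphere_is_at_most_centre_voxel(self):
        grid = GridSpec(shape=(11, 11, 11), spacing_mm=(0.1, 0.1, 0.1))
        spec = NoduleSpec(kind="sphere", diameter_mm=0.05, center_mm=(0.5, 0.5, 0.5))
        assert generate_sphere_mask(spec, grid).voxel_count <= 1

    def test_half_voxel_shift_changes_volume_little(self):
        grid = GridSpec(shape=(200, 200, 200), spacing_mm=(0.05, 0.05, 0.05))
        base = generate_sphere_mask(
            NoduleSpec(kind="sphere", diameter_mm=6, center_mm=(5, 5, 5)), grid
        ).voxel_count
        shifted = generate_sphere_mask(
            NoduleSpec(kind="sphere", diameter_mm=6, center_mm=(5.025, 5, 5)), grid
        ).voxel_count
        assert abs(shifted - base) / base < 0.02

    def test_out_of_bounds_rejected(self):
        grid = GridSpec(shape=(20, 20, 20), spacing_mm=(0.1, 0.1, 0.1))
        spec = NoduleSpec(kind="sphere", diameter_mm=3, center_mm=(0.5, 1.0, 1.0))
        with pytest.raises(ValueError, match="exceeds grid"):
            generate_sphere_mask(spec, grid)


class TestSpikedSphere:
    def test_tiny_spikes_reduce_to_sphere(self):
        grid = GridSpec(shape=(150, 150, 150), spacing_mm=(0.1, 0.1, 0.1))
        sphere = generate_sphere_mask(
            NoduleSpec(kind="sphere", diameter_mm=6, center_mm=(7.5, 7.5, 7.5)), grid
        )
        spiked = generate_spiked_sphere_mask(
            NoduleSpec(
                kind="spiked_sphere",
                diameter_mm=6,
                center_mm=(7.5, 7.5, 7.5),
                spike_length_mm=1e-6,
            ),
            grid,
        )
        np.testing.assert_array_equal(spiked.values, sphere.values)

    def test_spiked_is_strict_superset_of_sphere(self):
        grid = GridSpec(shape=(150, 150, 150), spacing_mm=(0.1, 0.1, 0.1))
        sphere = generate_sphere_mask(
            NoduleSpec(kind="sphere", diameter_mm=6, center_mm=(7.5, 7.5, 7.5)), grid
        )
        spiked = generate_spiked_sphere_mask(
            NoduleSpec(
                kind="spiked_sphere",
                diameter_mm=6,
                center_mm=(7.5, 7.5, 7.5),
                spike_length_mm=2.5,
            ),
            grid,
        )
        assert np.all(spiked.values[sphere.values])
        assert spiked.voxel_count > sphere.voxel_count

    def test_six_axis_spikes_fit_inside_voi(self):
        # d=6 with 2.5 mm spikes: bounding box ~11 mm < VOI of d+6.5 = 12.5 mm
        grid = GridSpec(shape=(150, 150, 150), spacing_mm=(0.1, 0.1, 0.1))
        spec = NoduleSpec(
            kind="spiked_sphere",
            diameter_mm=6,
            center_mm=(7.5, 7.5, 7.5),
            n_spikes=6,
            spike_length_mm=2.5,
        )
        mask = generate_spiked_sphere_mask(spec, grid)
        idx = np.argwhere(mask.values) * 0.1
        extent = idx.max(axis=0) - idx.min(axis=0)
        assert np.all(extent <= 11.1)
        assert np.all(extent <= spec.voi_diameter_mm)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            NoduleSpec(kind="spiked_sphere", diameter_mm=6, center_mm=(0, 0, 0), n_spikes=0)
        with pytest.raises(ValueError, match="fits inside its VOI"):
            NoduleSpec(
                kind="spiked_sphere",
                diameter_mm=6,
                center_mm=(0, 0, 0),
                spike_length_mm=4.0,
            )


class TestVesselTree:
    GRID = GridSpec(shape=(120, 80, 80), spacing_mm=(0.2, 0.2, 0.2))

    def test_depth_one_is_single_connected_tube(self):
        params = VesselParams(depth=1, root_radius_mm=0.8, root_length_mm=10)
        mask = generate_vessel_tree(3, params, self.GRID, start_mm=(2, 8, 8))
        _, n = ndimage.label(mask.values, structure=CONN26)
        assert n == 1

    def test_same_seed_reproduces_identically(self):
        params = VesselParams()
        a = generate_vessel_tree(7, params, self.GRID)
        b = generate_vessel_tree(7, params, self.GRID)
        np.testing.assert_array_equal(a.values, b.values)

    def test_radius_decay_recurrence(self):
        params = VesselParams(depth=4, radius_decay=0.7, root_radius_mm=1.0)
        rng = np.random.default_rng(0)
        segments = _tree_segments(params, rng, (0, 0, 0), (1, 0, 0))
        radii = sorted({round(r, 9) for _, _, r in segments}, reverse=True)
        assert radii == pytest.approx([1.0, 0.7, 0.49, 0.343])

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            VesselParams(depth=0)
        with pytest.raises(ValueError):
            VesselParams(radius_decay=1.5)


class TestAssemblePhantom:
    def small_scene(self, nodules):
        return PhantomScene(
            grid=GridSpec(shape=(240, 160, 120), spacing_mm=(0.1, 0.1, 0.1)),
            nodules=nodules,
            vessel_seed=5,
            vessel_params=VesselParams(depth=2, root_radius_mm=0.6, root_length_mm=6),
            vessel_root_mm=(0.5, 8.0, 6.0),
        )

    def test_empty_nodule_list_gives_vessels_only(self):
        scene = self.small_scene([])
        volume, refs = assemble_phantom(scene)
        assert refs == []
        vessels = generate_vessel_tree(
            5, scene.vessel_params, scene.grid, start_mm=scene.vessel_root_mm
        )
        assert np.all(volume.values[vessels.values] == scene.structure_hu)
        assert np.all(volume.values[~vessels.values] == scene.lung_background_hu)

    def test_histogram_is_bimodal_by_construction(self):
        scene = self.small_scene(
            [NoduleSpec(kind="sphere", diameter_mm=6, center_mm=(8, 8, 6))]
        )
        volume, _ = assemble_phantom(scene)
        assert set(np.unique(volume.values)) == {-580.0, -110.0}

    def test_six_nodules_give_six_connected_references(self):
        nodules = []
        for x, (d, kind) in zip(
            (4.0, 9.0, 14.0, 19.0),
            [(3, "sphere"), (6, "sphere"), (3, "spiked_sphere"), (6, "spiked_sphere")],
        ):
            nodules.append(
                NoduleSpec(kind=kind, diameter_mm=d, center_mm=(x, 8, 6),
                           spike_length_mm=1.5)
            )
        volume, refs = assemble_phantom(self.small_scene(nodules))
        assert len(refs) == 4
        for ref in refs:
            _, n = ndimage.label(ref.values, structure=CONN26)
            assert n == 1

    def test_determinism_bit_identical(self):
        scene = self.small_scene(
            [NoduleSpec(kind="sphere", diameter_mm=6, center_mm=(8, 8, 6))]
        )
        v1, r1 = assemble_phantom(scene)
        v2, r2 = assemble_phantom(scene)
        np.testing.assert_array_equal(v1.values, v2.values)
        np.testing.assert_array_equal(r1[0].values, r2[0].values)


class TestWireImage:
    GRID = GridSpec(shape=(61, 61, 2), spacing_mm=(0.13, 0.13, 0.25))

    @pytest.mark.parametrize("offset", [(0.0, 0.0), (0.037, -0.052), (0.065, 0.065)])
    def test_total_signal_conserved_at_any_subpixel_position(self, offset):
        d = 0.1
        center = (30 * 0.13 + offset[0], 30 * 0.13 + offset[1])
        spec = WirePhantomSpec(
            wire_diameter_mm=d, grid=self.GRID, wire_hu=3000, background_hu=0,
            center_xy_mm=center,
        )
        image = generate_wire_image(spec).values[:, :, 0]
        total = image.sum() * 0.13 * 0.13
        assert total == pytest.approx(3000 * np.pi * (d / 2) ** 2, rel=1e-4)

    def test_equal_contrast_gives_uniform_image(self):
        spec = WirePhantomSpec(
            wire_diameter_mm=0.1, grid=self.GRID, wire_hu=-500, background_hu=-500
        )
        assert np.all(generate_wire_image(spec).values == -500)

    def test_slices_identical_along_z(self):
        spec = WirePhantomSpec(wire_diameter_mm=0.2, grid=self.GRID)
        vol = generate_wire_image(spec)
        np.testing.assert_array_equal(vol.values[:, :, 0], vol.values[:, :, 1])

    def test_oversized_wire_rejected(self):
        with pytest.raises(ValueError):
            generate_wire_image(WirePhantomSpec(wire_diameter_mm=50.0, grid=self.GRID))
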