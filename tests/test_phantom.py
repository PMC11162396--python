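"""Phantom generation and block-face acquisition simulation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cryodist import (
    DepotSpec,
    GeometryError,
    ImagingConfig,
    TissueSpec,
    ground_truth,
    make_phantom,
    simulate_blockface_stack,
)

from _oracles import depth_weighted_projection
from conftest import noise_free_config


class TestMakePhantom:
    def test_sphere_volume_matches_analytic(self, small_tissue):
        depot = DepotSpec(
            shape_kind="sphere",
            center=(2200.0, 2200.0, 1200.0),
            size_params={"radius": 1000.0},
        )
        ph = make_phantom(depot, small_tissue, grid_spacing=20.0, seed=0)
        analytic = 4.0 / 3.0 * math.pi * 1000.0**3
        assert abs(ph.depot.true_volume_um3 - analytic) / analytic < 0.01

    def test_zero_concentration_leaves_autofluorescence_only(self, small_tissue):
        depot = DepotSpec(
            shape_kind="sphere",
            center=(2200.0, 2200.0, 1200.0),
            size_params={"radius": 500.0},
            concentration=0.0,
        )
        no_depot = DepotSpec(
            shape_kind="multilobe",
            center=(2200.0, 2200.0, 1200.0),
            size_params={"lobes": []},
        )
        a = make_phantom(depot, small_tissue, grid_spacing=40.0, seed=5)
        b = make_phantom(no_depot, small_tissue, grid_spacing=40.0, seed=5)
        np.testing.assert_array_equal(a.concentration_field, b.concentration_field)

    def test_same_seed_bit_identical(self, small_tissue, sphere_depot):
        a = make_phantom(sphere_depot, small_tissue, grid_spacing=40.0, seed=3)
        b = make_phantom(sphere_depot, small_tissue, grid_spacing=40.0, seed=3)
        np.testing.assert_array_equal(a.concentration_field, b.concentration_field)
        np.testing.assert_array_equal(a.tissue_mask, b.tissue_mask)

    def test_depot_outside_block_rejected(self, small_tissue):
        depot = DepotSpec(
            shape_kind="sphere",
            center=(200.0, 2200.0, 1200.0),  # overlaps the embedding margin
            size_params={"radius": 500.0},
        )
        with pytest.raises(GeometryError):
            make_phantom(depot, small_tissue)

    def test_nonpositive_grid_spacing_rejected(self, small_tissue, sphere_depot):
        with pytest.raises(ValueError):
            make_phantom(sphere_depot, small_tissue, grid_spacing=0.0)

    def test_concentration_field_nonnegative_and_gated(self, sphere_phantom):
        assert (sphere_phantom.concentration_field >= 0).all()
        # depot contribution confined to the tissue mask
        assert not (sphere_phantom.depot_mask & ~sphere_phantom.tissue_mask).any()

    @pytest.mark.parametrize("kind", ["ellipsoid", "multilobe", "track_set"])
    def test_all_shape_families_voxelize(self, small_tissue, kind):
        params = {
            "ellipsoid": {"semi_axes": (700.0, 500.0, 400.0)},
            "multilobe": {
                "lobes": [
                    {"offset": (0.0, 0.0, 0.0), "radius": 400.0},
                    {"offset": (500.0, 0.0, 200.0), "radius": 300.0},
                ]
            },
            "track_set": {
                "tracks": [
                    {"start": (0.0, 0.0, -600.0), "end": (0.0, 0.0, 600.0),
                     "radius": 150.0},
                    {"start": (-400.0, 0.0, -500.0), "end": (300.0, 200.0, 500.0),
                     "radius": 100.0},
                ]
            },
        }[kind]
        depot = DepotSpec(
            shape_kind=kind, center=(2200.0, 2200.0, 1200.0), size_params=params
        )
        ph = make_phantom(depot, small_tissue, grid_spacing=40.0, seed=1)
        assert ph.depot.true_volume_um3 > 0
        assert ph.depot_mask.any()


class TestGroundTruth:
    def test_unit_microliter_sphere(self, small_tissue):
        # 4/3 π (620.35)³ = 1.0000e9 µm³
        depot = DepotSpec(
            shape_kind="sphere",
            center=(2200.0, 2200.0, 1200.0),
            size_params={"radius": 620.35},
        )
        ph = make_phantom(depot, small_tissue, grid_spacing=20.0, seed=0)
        gt = ground_truth(ph)
        assert abs(gt["true_volume_ul"] - 1.000) < 0.01

    def test_empty_depot_zero_volume(self, small_tissue):
        depot = DepotSpec(
            shape_kind="track_set",
            center=(2200.0, 2200.0, 1200.0),
            size_params={"tracks": []},
        )
        ph = make_phantom(depot, small_tissue, grid_spacing=40.0, seed=0)
        assert ground_truth(ph)["true_volume_ul"] == 0.0

    def test_translation_moves_centroid_not_volume(self, small_tissue):
        base = DepotSpec(
            shape_kind="sphere",
            center=(2000.0, 2000.0, 1000.0),
            size_params={"radius": 400.0},
        )
        shift = (200.0, 120.0, 280.0)  # grid-aligned at 40 µm spacing
        moved = base.model_copy(
            update={"center": tuple(c + d for c, d in zip(base.center, shift))}
        )
        gt0 = ground_truth(make_phantom(base, small_tissue, 40.0, seed=0))
        gt1 = ground_truth(make_phantom(moved, small_tissue, 40.0, seed=0))
        assert gt0["true_volume_ul"] == gt1["true_volume_ul"]
        np.testing.assert_allclose(
            np.subtract(gt1["depot_centroid_um"], gt0["depot_centroid_um"]),
            shift,
            atol=1e-6,
        )


def _thin_phantom(depth: float, spacing: float = 20.0):
    tissue = TissueSpec(
        block_extent=(600.0, 600.0, depth),
        embedding_margin=100.0,
        autofluorescence_sd=0.0,
    )
    depot = DepotSpec(
        shape_kind="multilobe", center=(400.0, 400.0, depth / 2), size_params={"lobes": []}
    )
    return make_phantom(depot, tissue, grid_spacing=spacing, seed=0)


class TestSimulate:
    @pytest.mark.parametrize(
        "depth,expected", [(480.0, 10), (100.0, 3), (48.0, 1), (96.0, 2), (500.0, 11)]
    )
    def test_section_count(self, depth, expected):
        ph = _thin_phantom(depth)
        stack = simulate_blockface_stack(ph, noise_free_config())
        assert stack.n_sections == expected
        assert stack.fluorescence.shape == stack.reflection.shape

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        depth=st.floats(min_value=60.0, max_value=900.0),
        thickness=st.floats(min_value=20.0, max_value=120.0),
    )
    def test_section_count_conservation(self, depth, thickness):
        ph = _thin_phantom(depth, spacing=10.0)
        cfg = noise_free_config(slice_thickness=thickness, pixel_pitch=20.0)
        stack = simulate_blockface_stack(ph, cfg)
        assert stack.n_sections == math.ceil(depth / thickness - 1e-9)

    def test_ideal_imaging_equals_direct_slicing(self, small_tissue, sphere_depot):
        """PSF off, noise off, attenuation 0: stack == sliced field."""
        ph = make_phantom(sphere_depot, small_tissue, grid_spacing=20.0, seed=2)
        cfg = noise_free_config(pixel_pitch=20.0, slice_thickness=60.0)
        stack = simulate_blockface_stack(ph, cfg)
        for k in range(stack.n_sections):
            expected = np.clip(
                np.rint(ph.concentration_field[k * 3]), 0, 65535
            ).astype(np.uint16)
            np.testing.assert_array_equal(stack.fluorescence[k], expected)

    def test_subsurface_depot_bleeds_through(self, small_tissue):
        """A depot below the cut face raises the image over its footprint,
        matching the independent depth-weighted projection oracle."""
        depot = DepotSpec(
            shape_kind="sphere",
            center=(2200.0, 2200.0, 1500.0),
            size_params={"radius": 400.0},
        )
        tissue = small_tissue.model_copy(
            update={"autofluorescence_sd": 0.0, "autofluorescence_mean": 100.0}
        )
        ph = make_phantom(depot, tissue, grid_spacing=20.0, seed=0)
        lam = 60.0
        cfg = noise_free_config(
            pixel_pitch=20.0,
            slice_thickness=40.0,
            bleedthrough_attenuation_length=lam,
        )
        stack = simulate_blockface_stack(ph, cfg)
        # face 20 is at z = 800 µm, fully above the depot (top at 1100 µm)
        k, z_face = 20, 800.0
        oracle = depth_weighted_projection(
            ph.concentration_field, 20.0, z_face, lam
        )
        np.testing.assert_allclose(
            stack.fluorescence[k].astype(float), np.rint(oracle), atol=1.0
        )
        centre_px = int(2200 / 20)
        background = oracle[5, 5]
        assert stack.fluorescence[k, centre_px, centre_px] > background + 50

    def test_monotone_bleedthrough_total_intensity(self, small_tissue):
        depot = DepotSpec(
            shape_kind="sphere",
            center=(2200.0, 2200.0, 1400.0),
            size_params={"radius": 400.0},
        )
        ph = make_phantom(depot, small_tissue, grid_spacing=40.0, seed=4)
        totals = []
        for lam in (0.0, 20.0, 50.0, 100.0):
            cfg = noise_free_config(bleedthrough_attenuation_length=lam)
            stack = simulate_blockface_stack(ph, cfg)
            totals.append(int(stack.fluorescence.sum(dtype=np.int64)))
        assert all(b >= a for a, b in zip(totals, totals[1:]))
        assert totals[-1] > totals[0]

    def test_seeded_determinism(self, sphere_phantom):
        cfg = ImagingConfig(rng_seed=9)
        a = simulate_blockface_stack(sphere_phantom, cfg)
        b = simulate_blockface_stack(sphere_phantom, cfg)
        np.testing.assert_array_equal(a.fluorescence, b.fluorescence)
        np.testing.assert_array_equal(a.reflection, b.reflection)

    def test_reflection_encodes_tissue_border(self, sphere_phantom):
        stack = simulate_blockface_stack(sphere_phantom, noise_free_config())
        refl = stack.reflection[0].astype(float)
        # embedding corner dark, tissue centre bright
        assert refl[2, 2] < 1000
        assert refl[refl.shape[0] // 2, refl.shape[1] // 2] > 10_000
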