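"""Volume, shape, residual-dose and group-statistics quantification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cryodist import (
    EmptyShapeError,
    GeometryError,
    Segmentation,
    fluorescent_volume,
    group_stats,
    per_component_volumes,
    quant_report,
    residual_dose,
    round_half_up,
    shape_metrics,
)

from scipy import ndimage


def seg_from_mask(mask: np.ndarray, voxel=(27.4, 27.4, 35.0)) -> Segmentation:
    labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3)))
    return Segmentation(
        mask=mask.astype(bool), labels=labels, threshold_used=2000.0,
        n_components=int(n), excluded_voxel_count=0, voxel_size=voxel,
    )


def ball_mask(radius_vox: float, voxel=(27.4, 27.4, 35.0), pad=2) -> np.ndarray:
    """Voxelized ball of the given radius (in units of the x voxel size)."""
    dx, dy, dz = voxel
    r_um = radius_vox * dx
    nx = int(2 * (radius_vox + pad)) + 1
    nz = int(2 * (r_um / dz + pad)) + 1
    xs = (np.arange(nx) - nx // 2) * dx
    zs = (np.arange(nz) - nz // 2) * dz
    return (
        xs[None, None, :] ** 2 + xs[None, :, None] ** 2 + zs[:, None, None] ** 2
    ) <= r_um**2


class TestVolume:
    def test_empty_mask_zero_volume(self):
        seg = seg_from_mask(np.zeros((4, 4, 4), dtype=bool))
        assert fluorescent_volume(seg) == 0.0
        assert per_component_volumes(seg) == []

    def test_voxel_count_arithmetic(self):
        # 38 052 voxels × 26 278.6 µm³ ≈ 1.000 µL
        mask = np.zeros(40 * 40 * 24, dtype=bool)
        mask[:38_052] = True
        seg = seg_from_mask(mask.reshape(40, 40, 24))
        assert abs(fluorescent_volume(seg) - 1.000) < 1e-3

    def test_additivity_exact(self):
        rng = np.random.default_rng(1)
        seg = seg_from_mask(rng.random((20, 20, 20)) < 0.2)
        total = fluorescent_volume(seg)
        parts = per_component_volumes(seg)
        assert len(parts) == seg.n_components
        assert total == pytest.approx(sum(parts), abs=1e-12)

    def test_scale_equivariance(self):
        small = ball_mask(6.0)
        big = ball_mask(12.0)
        ratio = seg_from_mask(big).mask.sum() / seg_from_mask(small).mask.sum()
        assert abs(ratio - 8.0) / 8.0 < 0.05

    def test_voxel_size_mismatch_rejected(self):
        seg = seg_from_mask(np.ones((4, 4, 4), dtype=bool))
        with pytest.raises(GeometryError):
            fluorescent_volume(seg, voxel_size=(10.0, 10.0, 10.0))


class TestShape:
    def test_ball_sphericity_near_one(self):
        seg = seg_from_mask(ball_mask(8.0))
        m = shape_metrics(seg)
        assert m.sphericity >= 0.9
        assert m.sphericity <= 1.05  # mesh error budget around the analytic 1.0
        assert m.fragmentation == 1

    def test_single_voxel_extents_equal_voxel_size(self):
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[2, 2, 2] = True
        m = shape_metrics(seg_from_mask(mask))
        assert m.principal_extents_um == pytest.approx((27.4, 27.4, 35.0))
        assert m.max_depth_um == pytest.approx(3 * 35.0)

    def test_two_balls_fragmentation_and_volume(self):
        one = ball_mask(5.0)
        nz, ny, nx = one.shape
        two = np.zeros((nz, ny, 2 * nx + 4), dtype=bool)
        two[:, :, :nx] = one
        two[:, :, nx + 4 :] = one
        seg1, seg2 = seg_from_mask(one), seg_from_mask(two)
        m = shape_metrics(seg2)
        assert m.fragmentation == 2
        assert fluorescent_volume(seg2) == pytest.approx(
            2 * fluorescent_volume(seg1)
        )

    def test_empty_mask_rejected(self):
        with pytest.raises(EmptyShapeError):
            shape_metrics(seg_from_mask(np.zeros((3, 3, 3), dtype=bool)))

    def test_report_bundles_consistently(self):
        seg = seg_from_mask(ball_mask(4.0))
        rep = quant_report(seg)
        assert rep.fluorescent_volume_ul == pytest.approx(
            sum(rep.per_component_volumes_ul)
        )
        assert rep.shape.fragmentation == rep.n_components
        d = rep.to_dict()
        assert d["provenance"]["threshold"] == 2000.0


class TestResidualDose:
    def test_density_mass_gives_one_millilitre(self):
        rd = residual_dose(0.9527)
        assert rd.residual_volume_ul == pytest.approx(1000.0)
        assert rd.residual_fraction_pct == pytest.approx(1000.0)  # of 100 µL
        assert rd.flagged

    def test_conversion_factor_to_four_decimals(self):
        assert residual_dose(0.0).conversion_factor == 1.0496

    def test_one_gram_via_conversion_factor(self):
        rd = residual_dose(1.0)
        assert rd.residual_volume_ul == pytest.approx(1049.6, abs=0.1)

    def test_zero_mass(self):
        rd = residual_dose(0.0)
        assert rd.residual_volume_ul == 0.0
        assert rd.residual_fraction_pct == 0.0
        assert not rd.flagged

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            residual_dose(1.0, density_g_per_ml=0.0)
        with pytest.raises(ValueError):
            residual_dose(-0.1)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(mass=st.floats(min_value=0.0, max_value=5.0, allow_nan=False))
    def test_mass_round_trip(self, mass):
        rd = residual_dose(mass)
        assert rd.residual_volume_ul * rd.density_g_per_ml / 1000.0 == pytest.approx(
            mass, abs=1e-12
        )


class TestGroupStats:
    def test_equal_n_pooled_is_mean_of_group_means(self):
        gs = group_stats({"4bar": [329.0], "5bar": [384.0], "6bar": [489.0]})
        assert gs.pooled_mean == pytest.approx((329 + 384 + 489) / 3)
        assert gs.pooled_mean_rounded == 401

    def test_half_up_rounding_at_tie(self):
        gs = group_stats({"4bar": [210.0], "6bar": [287.0]})
        assert gs.pooled_mean == pytest.approx(248.5)
        assert gs.pooled_mean_rounded == 249  # half-up, not banker's

    def test_single_group(self):
        gs = group_stats({"only": [1.0, 2.0, 3.0]})
        assert gs.pooled_mean == pytest.approx(2.0)
        assert gs.table.loc[0, "sd"] == pytest.approx(1.0)  # sample SD, n−1

    def test_dataframe_input(self):
        df = pd.DataFrame(
            {"group": ["a", "a", "b", "b"], "value": [1.0, 3.0, 5.0, 7.0]}
        )
        gs = group_stats(df)
        assert set(gs.table["group"]) == {"a", "b"}
        assert gs.pooled_mean == pytest.approx(4.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            group_stats({"a": []})
        with pytest.raises(ValueError):
            group_stats({})


@pytest.mark.parametrize(
    "x,expected", [(248.5, 249), (400.6667, 401), (0.5, 1), (2.4999, 2), (-1.5, -2)]
)
def test_round_half_up(x, expected):
    assert round_half_up(x) == expected
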