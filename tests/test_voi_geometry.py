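import numpy as np
import pytest

from nailmorph.phantom import GRID_STAGGER, _symmetric_grid
from nailmorph.voi_geometry import (VOIError, VOIGeometryParams,
                                    assign_quarters_by_slice, build_bent_voi,
                                    build_straight_voi, rasterize_voi,
                                    split_quarters)
from nailmorph.volume_io import LandmarkSet, Volume3D


def _landmarks(cut_straight=30.0, cut_bent=30.0, bcb=(12.0, 0.0, 25.0),
               shaft_point=(0.0, 0.0, -10.0)):
    return LandmarkSet(
        head_apex=[0.0, 0.0, 35.0],
        shaft_axis_point=list(shaft_point),
        shaft_axis_dir=[0.0, 0.0, 1.0],
        lateral_bcb_point=list(bcb),
        head_lower_z=0.0,
        subcortical_cut={"straight": cut_straight, "bent": cut_bent},
    )


def _grid(extent=(16.0, 16.0, 36.0), spacing=0.5, stagger=0.0, z0=None):
    n, origin = _symmetric_grid(np.asarray(extent), spacing, stagger=stagger)
    if z0 is not None:
        origin[2] = z0 + spacing / 2.0
    return Volume3D(np.zeros(tuple(n)), spacing, origin)


def test_straight_axis_aligned_construction():
    voi = build_straight_voi(_landmarks(), VOIGeometryParams())
    np.testing.assert_allclose(voi.entry_point, [0, 0, 30], atol=1e-12)
    np.testing.assert_allclose(voi.axis_dir, [0, 0, -1], atol=1e-12)
    assert voi.proximal_bound - voi.distal_bound == pytest.approx(30.0)
    assert voi.inner_radius == 4.5 and voi.outer_radius == 6.0


def test_straight_equivariance_under_z_rotation():
    lm = _landmarks(shaft_point=(2.0, 1.0, -10.0))
    rot = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
    lm_rot = LandmarkSet(
        head_apex=rot @ lm.head_apex,
        shaft_axis_point=rot @ lm.shaft_axis_point,
        shaft_axis_dir=rot @ lm.shaft_axis_dir,
        lateral_bcb_point=rot @ lm.lateral_bcb_point,
        head_lower_z=lm.head_lower_z,
        subcortical_cut=dict(lm.subcortical_cut),
    )
    voi = build_straight_voi(lm)
    voi_rot = build_straight_voi(lm_rot)
    np.testing.assert_allclose(voi_rot.entry_point, rot @ voi.entry_point,
                               atol=1e-12)
    assert voi_rot.inner_radius == voi.inner_radius


def test_bent_angle_five_degrees():
    voi = build_bent_voi(_landmarks(), VOIGeometryParams(bend_angle=5.0))
    # proximal direction vs shaft axis: cos(5 deg)
    assert np.dot(-voi.axis_dir, [0, 0, 1]) == pytest.approx(
        np.cos(np.deg2rad(5.0)), abs=1e-9)
    # zero AP deviation: axis stays in the y=shaft-axis plane
    assert voi.axis_point_at_z(0.0)[1] == pytest.approx(0.0, abs=1e-12)


def test_bent_axis_lateral_offset_at_lower_border():
    # bcb at x=12, 25 mm above the lower border: x(0) = 12 - 25 tan(5 deg)
    voi = build_bent_voi(_landmarks(bcb=(12.0, 0.0, 25.0)))
    expected = 12.0 - 25.0 * np.tan(np.deg2rad(5.0))
    assert voi.axis_point_at_z(0.0)[0] == pytest.approx(expected, abs=1e-9)
    assert expected == pytest.approx(9.813, abs=5e-4)
    # the AP-projection anchor: x at the bcb level equals bcb.x
    assert voi.axis_point_at_z(25.0)[0] == pytest.approx(12.0, abs=1e-9)


def test_bent_reduces_to_straight_when_angle_zero_and_bcb_on_axis():
    lm = _landmarks(bcb=(0.0, 0.0, 25.0))
    s = build_straight_voi(lm)
    b = build_bent_voi(lm, VOIGeometryParams(bend_angle=0.0))
    np.testing.assert_allclose(b.axis_dir, s.axis_dir, atol=1e-12)
    np.testing.assert_allclose(b.entry_point, s.entry_point, atol=1e-12)
    grid = _grid(z0=-1.0)
    np.testing.assert_array_equal(rasterize_voi(b, grid).labels,
                                  rasterize_voi(s, grid).labels)


def test_rasterized_annulus_volume_within_two_percent():
    lm = _landmarks(cut_straight=20.0)
    voi = build_straight_voi(lm)
    grid = _grid(extent=(16.0, 16.0, 24.0), spacing=0.5,
                 stagger=GRID_STAGGER, z0=-1.0)
    mask = rasterize_voi(voi, grid)
    analytic = np.pi * (6.0 ** 2 - 4.5 ** 2) * 20.0
    measured = np.count_nonzero(mask.labels) * mask.voxel_volume
    assert measured == pytest.approx(analytic, rel=0.02)


def test_solid_cylinder_annulus_area_ratio():
    lm = _landmarks(cut_straight=20.0)
    grid = _grid(extent=(16.0, 16.0, 24.0), spacing=0.5,
                 stagger=GRID_STAGGER, z0=-1.0)
    annulus = rasterize_voi(build_straight_voi(lm), grid)
    solid = rasterize_voi(
        build_straight_voi(lm, VOIGeometryParams(inner_diameter=0.0)), grid)
    ratio = np.count_nonzero(annulus.labels) / np.count_nonzero(solid.labels)
    assert ratio == pytest.approx((36 - 20.25) / 36, rel=0.02)


def test_rasterization_invariant_under_90_degree_grid_rotation():
    # axis deliberately off-center; the symmetric grid maps onto itself
    lm = _landmarks(shaft_point=(2.0, 1.0, -10.0), cut_straight=20.0)
    rot = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
    lm_rot = LandmarkSet(
        head_apex=rot @ lm.head_apex,
        shaft_axis_point=rot @ lm.shaft_axis_point,
        shaft_axis_dir=rot @ lm.shaft_axis_dir,
        lateral_bcb_point=rot @ lm.lateral_bcb_point,
        head_lower_z=lm.head_lower_z,
        subcortical_cut=dict(lm.subcortical_cut),
    )
    grid = _grid(extent=(22.0, 22.0, 24.0), spacing=0.5, z0=-1.0)
    n1 = np.count_nonzero(rasterize_voi(build_straight_voi(lm), grid).labels)
    n2 = np.count_nonzero(
        rasterize_voi(build_straight_voi(lm_rot), grid).labels)
    assert n1 == n2


def test_voi_missing_grid_is_an_error():
    lm = _landmarks(cut_straight=20.0)
    tiny = Volume3D(np.zeros((4, 4, 4)), 0.5, origin=[100.0, 100.0, 100.0])
    with pytest.raises(VOIError):
        rasterize_voi(build_straight_voi(lm), tiny)


def test_quarter_assignment_hand_example():
    # per-slice counts [3, 1, 1, 3] proximal -> distal split into singleton
    # slices with counts 3, 1, 1, 3
    q = assign_quarters_by_slice([3, 1, 1, 3])
    np.testing.assert_array_equal(q, [1, 2, 3, 4])


def test_quarters_uniform_tube_exact_and_partition():
    lm = _landmarks(cut_straight=20.0)
    voi = build_straight_voi(lm)
    grid = _grid(extent=(16.0, 16.0, 24.0), spacing=0.5,
                 stagger=GRID_STAGGER, z0=-1.0)
    mask = rasterize_voi(voi, grid)
    quarters = split_quarters(mask, voi)
    counts = quarters.counts()
    n = sum(counts.values())
    assert set(counts) == {1, 2, 3, 4}
    # partition: same voxels, relabeled
    np.testing.assert_array_equal(quarters.labels > 0, mask.labels > 0)
    # uniform tube: 40 equal slices -> exactly N/4 each
    assert all(c == n // 4 for c in counts.values())
    # quarter order is proximal -> distal along z
    zc = [np.mean(np.nonzero(quarters.labels == q)[2]) for q in (1, 2, 3, 4)]
    assert zc[0] > zc[1] > zc[2] > zc[3]


def test_quarter_isovolumetry_quantization_bound(gradient_phantom, study_cfg):
    vol, lm, _ = gradient_phantom
    for build in (build_straight_voi, build_bent_voi):
        voi = build(lm, study_cfg.voi)
        mask = rasterize_voi(voi, vol)
        quarters = split_quarters(mask, voi)
        counts = quarters.counts()
        n = sum(counts.values())
        idx = np.nonzero(mask.labels)
        slice_counts = np.bincount(idx[2])
        bound = slice_counts.max()
        assert max(abs(c - n / 4) for c in counts.values()) <= bound


def test_split_quarters_needs_four_slices():
    lm = _landmarks(cut_straight=20.0)
    voi = build_straight_voi(lm)
    grid = _grid(extent=(16.0, 16.0, 24.0), spacing=0.5, z0=-1.0)
    mask = rasterize_voi(voi, grid)
    mask.labels[:, :, :] *= 0
    with pytest.raises(VOIError):
        split_quarters(mask, voi)


def test_quarters_along_voi_axis_option(gradient_phantom, study_cfg):
    vol, lm, _ = gradient_phantom
    voi = build_bent_voi(lm, study_cfg.voi)
    mask = rasterize_voi(voi, vol)
    qz = split_quarters(mask, voi, quarter_axis="world_z")
    qa = split_quarters(mask, voi, quarter_axis="voi_axis")
    assert set(qa.counts()) == {1, 2, 3, 4}
    # both rules partition the same voxel set
    assert sum(qa.counts().values()) == sum(qz.counts().values())


from hypothesis import given, settings, strategies as st


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.integers(1, 50), min_size=4, max_size=40))
def test_quarter_assignment_properties(counts):
    """Slice quarter labels are monotone 1..4 proximal to distal and each
    quarter's voxel count deviates from N/4 by at most the largest
    single-slice count (the quantization bound)."""
    q = assign_quarters_by_slice(counts)
    assert ((q >= 1) & (q <= 4)).all()
    assert (np.diff(q) >= 0).all()
    counts = np.asarray(counts)
    n = counts.sum()
    per_quarter = [counts[q == k].sum() for k in (1, 2, 3, 4)]
    assert sum(per_quarter) == n
    assert max(abs(c - n / 4) for c in per_quarter) <= counts.max()
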