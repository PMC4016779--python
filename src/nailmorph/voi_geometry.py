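"""Implant-path volumes of interest: construction, rasterization, quartering.

A VOI is an annular tube (inner diameter 9 mm, outer 12 mm by default) whose
bore models the nail itself.  The *straight* design runs along the extended
humeral shaft axis, entering at the subcortical level under the head apex.
The *bent* design is angulated 5 degrees in the frontal plane: in the lateral
view it projects onto the shaft axis (zero anterior-posterior deviation) and
in the AP view its x-position at the level of the bone-cartilage border
equals that landmark's x.  Both designs end distally at the lower border of
the humeral head (the most distal point of the glenohumeral cartilage) and
proximally at the per-design subcortical cut, so the tube contains
cancellous bone only.

Quarters: the rasterized tube is split into four sub-volumes of (nearly)
equal voxel count along z-slices, numbered 1..4 from proximal to distal.  A
slice whose cumulative voxel-count midpoint falls in ``((k-1) N/4, k N/4]``
belongs to quarter ``k``; cuts land on slice boundaries, so each quarter can
deviate from N/4 by at most the largest single-slice count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volume_io import LandmarkSet, Volume3D


class VOIError(RuntimeError):
    pass


@dataclass
class VOIGeometryParams:
    inner_diameter: float = 9.0
    outer_diameter: float = 12.0
    bend_angle: float = 5.0

    def __post_init__(self) -> None:
        if not 0 <= self.inner_diameter < self.outer_diameter:
            raise ValueError("need 0 <= inner_diameter < outer_diameter")
        if not 0 <= self.bend_angle < 90:
            raise ValueError("bend_angle must lie in [0, 90)")


@dataclass
class TubularVOI:
    """Parametric annular tube between the subcortical cut and the head's
    lower border.  ``axis_dir`` is unit length and points distally
    (negative z component); z increases proximally."""

    design: str
    entry_point: np.ndarray
    axis_dir: np.ndarray
    inner_radius: float
    outer_radius: float
    proximal_bound: float
    distal_bound: float

    def __post_init__(self) -> None:
        self.entry_point = np.asarray(self.entry_point, dtype=float)
        d = np.asarray(self.axis_dir, dtype=float)
        self.axis_dir = d / np.linalg.norm(d)
        if self.axis_dir[2] >= 0:
            raise VOIError("axis_dir must point distally (negative z)")
        if not self.proximal_bound > self.distal_bound:
            raise VOIError("proximal_bound must exceed distal_bound")

    def axis_point_at_z(self, z: float | np.ndarray) -> np.ndarray:
        """Point(s) on the axis at given world z."""
        t = (np.asarray(z) - self.entry_point[2]) / self.axis_dir[2]
        return self.entry_point + np.multiply.outer(t, self.axis_dir)


@dataclass
class QuarteredMask:
    """Voxel labeling of a rasterized VOI: 0 outside, 1..4 quarters
    (proximal to distal); a freshly rasterized mask is all label 1.

    After quartering, ``plane_normal`` and ``quarter_bounds`` describe each
    quarter as a slab ``lo <= normal . x <= hi`` whose cut planes lie on
    slice boundaries; adjacent quarters share their boundary plane exactly.
    """

    labels: np.ndarray
    design: str
    voxel_volume: float
    spacing: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    plane_normal: np.ndarray | None = None
    quarter_bounds: dict[int, tuple[float, float]] | None = None

    def to_volume(self) -> Volume3D:
        return Volume3D(self.labels, self.spacing, self.origin)

    def counts(self) -> dict[int, int]:
        values, counts = np.unique(self.labels[self.labels > 0],
                                   return_counts=True)
        return dict(zip(values.tolist(), counts.tolist()))


def _axis_intersection_z(point: np.ndarray, direction: np.ndarray,
                         z: float) -> np.ndarray:
    if direction[2] == 0:
        raise VOIError("axis is parallel to the bound plane")
    t = (z - point[2]) / direction[2]
    return point + t * direction


def build_straight_voi(lm: LandmarkSet,
                       geom: VOIGeometryParams | None = None) -> TubularVOI:
    """Straight nail path: the extended shaft axis, entered subcortically."""
    geom = geom or VOIGeometryParams()
    cut = lm.subcortical_cut["straight"]
    if not lm.head_lower_z < cut:
        raise VOIError("head lower border must lie below the subcortical cut")
    d = lm.shaft_axis_dir  # unit, +z-ward
    entry = _axis_intersection_z(lm.shaft_axis_point, d, cut)
    return TubularVOI(
        design="straight",
        entry_point=entry,
        axis_dir=-d,
        inner_radius=geom.inner_diameter / 2.0,
        outer_radius=geom.outer_diameter / 2.0,
        proximal_bound=cut,
        distal_bound=lm.head_lower_z,
    )


def build_bent_voi(lm: LandmarkSet,
                   geom: VOIGeometryParams | None = None) -> TubularVOI:
    """Bent nail path: shaft axis tilted ``bend_angle`` about the AP (+y)
    axis so its proximal end points toward the lateral bone-cartilage
    border, whose x-coordinate anchors the axis at that landmark's level."""
    geom = geom or VOIGeometryParams()
    cut = lm.subcortical_cut["bent"]
    if not lm.head_lower_z < cut:
        raise VOIError("head lower border must lie below the subcortical cut")
    alpha = np.deg2rad(geom.bend_angle)

    # the proximal tilt goes toward the bone-cartilage border: the lateral
    # direction is the border point's offset from the shaft axis, projected
    # perpendicular to the axis (in the canonical frame this is +/-x and the
    # tilt is a rotation about the AP (+y) axis)
    z_bcb = lm.lateral_bcb_point[2]
    shaft_at_bcb = _axis_intersection_z(lm.shaft_axis_point,
                                        lm.shaft_axis_dir, z_bcb)
    offset_vec = lm.lateral_bcb_point - shaft_at_bcb
    offset_vec -= (offset_vec @ lm.shaft_axis_dir) * lm.shaft_axis_dir
    offset = float(np.linalg.norm(offset_vec))
    lat_dir = offset_vec / offset if offset > 1e-12 \
        else np.array([1.0, 0.0, 0.0])

    d = np.cos(alpha) * lm.shaft_axis_dir + np.sin(alpha) * lat_dir
    # anchor: lateral position pinned at the border level, no deviation from
    # the shaft axis perpendicular to the lateral plane
    anchor = shaft_at_bcb + offset * lat_dir
    entry = _axis_intersection_z(anchor, d, cut)
    return TubularVOI(
        design="bent",
        entry_point=entry,
        axis_dir=-d,
        inner_radius=geom.inner_diameter / 2.0,
        outer_radius=geom.outer_diameter / 2.0,
        proximal_bound=cut,
        distal_bound=lm.head_lower_z,
    )


def rasterize_voi(voi: TubularVOI, grid: Volume3D) -> QuarteredMask:
    """Label every voxel whose center lies in the annular shell between the
    axial bounds (center-in-shell rule, boundaries inclusive)."""
    spacing, origin = grid.spacing, grid.origin
    shape = grid.data.shape

    # bounding box of the tube, in index space
    ends = np.stack([voi.axis_point_at_z(voi.proximal_bound),
                     voi.axis_point_at_z(voi.distal_bound)])
    lo = ends.min(axis=0) - voi.outer_radius - spacing
    hi = ends.max(axis=0) + voi.outer_radius + spacing
    i0 = np.maximum(0, np.floor((lo - origin) / spacing).astype(int))
    i1 = np.minimum(shape, np.ceil((hi - origin) / spacing).astype(int) + 1)
    if np.any(i0 >= i1):
        raise VOIError("VOI does not intersect the grid")

    coords = [origin[a] + spacing * np.arange(i0[a], i1[a]) for a in range(3)]
    x = coords[0][:, None, None]
    y = coords[1][None, :, None]
    z = coords[2][None, None, :]

    a, u = voi.entry_point, voi.axis_dir
    px, py, pz = x - a[0], y - a[1], z - a[2]
    proj = px * u[0] + py * u[1] + pz * u[2]
    r2 = (px - proj * u[0]) ** 2 + (py - proj * u[1]) ** 2 \
        + (pz - proj * u[2]) ** 2
    inside = (r2 >= voi.inner_radius ** 2) & (r2 <= voi.outer_radius ** 2) \
        & (z >= voi.distal_bound) & (z <= voi.proximal_bound)

    labels = np.zeros(shape, dtype=np.uint8)
    labels[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]] = inside.astype(np.uint8)
    if not labels.any():
        raise VOIError("rasterized VOI is empty on this grid")
    return QuarteredMask(labels=labels, design=voi.design,
                         voxel_volume=spacing ** 3, spacing=spacing,
                         origin=np.asarray(origin, float).copy())


def assign_quarters_by_slice(counts: np.ndarray) -> np.ndarray:
    """Quarter label (1..4) per slice from per-slice voxel counts ordered
    proximal to distal, by the cumulative-midpoint rule."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise VOIError("no occupied slices")
    mid = np.cumsum(counts) - counts / 2.0
    q = np.ceil(mid / (total / 4.0)).astype(int)
    return np.clip(q, 1, 4)


def split_quarters(mask: QuarteredMask, voi: TubularVOI,
                   quarter_axis: str = "world_z") -> QuarteredMask:
    """Partition the rasterized VOI into four equal-count sub-volumes along
    z-slices (or along the VOI axis with ``quarter_axis='voi_axis'``),
    labeled 1..4 proximal to distal."""
    idx = np.nonzero(mask.labels)
    n = idx[0].size
    if n == 0:
        raise VOIError("cannot split an empty mask")

    if quarter_axis == "world_z":
        # slice key: z index, proximal (large z) first; slab coordinate is z
        slice_key = -idx[2].astype(int)
        normal = np.array([0.0, 0.0, 1.0])

        def slice_coord(key):  # center of the slice, on the slab coordinate
            return mask.origin[2] + mask.spacing * (-key)
    elif quarter_axis == "voi_axis":
        centers = mask.origin[:, None] + mask.spacing * np.stack(
            [idx[0], idx[1], idx[2]]).astype(float)
        s = voi.axis_dir @ (centers - voi.entry_point[:, None])
        slice_key = np.floor(s / mask.spacing).astype(int)
        normal = voi.axis_dir.copy()
        s0 = float(voi.axis_dir @ voi.entry_point)

        def slice_coord(key):
            return s0 + mask.spacing * (key + 0.5)
    else:
        raise ValueError(f"unknown quarter_axis '{quarter_axis}'")

    uniq, inverse, counts = np.unique(slice_key, return_inverse=True,
                                      return_counts=True)
    if uniq.size < 4:
        raise VOIError(
            f"only {uniq.size} occupied slice(s); need at least 4 to quarter")
    quarter_of_slice = assign_quarters_by_slice(counts)

    labels = np.zeros_like(mask.labels)
    labels[idx] = quarter_of_slice[inverse].astype(mask.labels.dtype)

    bounds: dict[int, tuple[float, float]] = {}
    half = mask.spacing / 2.0
    for q in np.unique(quarter_of_slice):
        coords = np.array([slice_coord(k) for k in uniq[quarter_of_slice == q]])
        bounds[int(q)] = (float(coords.min() - half),
                          float(coords.max() + half))
    return QuarteredMask(labels=labels, design=mask.design,
                         voxel_volume=mask.voxel_volume,
                         spacing=mask.spacing, origin=mask.origin.copy(),
                         plane_normal=normal, quarter_bounds=bounds)
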