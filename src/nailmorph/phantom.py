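"""Synthetic proximal-humerus phantoms with known trabecular structure.

The phantom stands in for cadaveric HR-pQCT scans: a hemispherical head of
radius ``head_radius`` sits on a cylindrical shaft, wrapped in a closed
cortical shell.  The interior carries a thresholded Gaussian-random-field
texture whose bone fraction is controlled exactly, layer by layer, by a
craniocaudal target profile ``bvtv_profile(z)`` (z in mm, 0 at the head's
lower border, increasing proximally) and an optional multiplicative
*lateral deficit* inside an angular sector around the lateral (+x)
direction — a stand-in for the low-density greater-tubercle region.  The
tubercle region extends from near the apex to below the head equator, so
the sector spans the head's full proximal-distal extent by default.

Gray levels emulate a scanner's native range: bone at ``bone_gray`` on a
``full_scale_gray`` ceiling chosen so that the standard 11%-of-full-scale
segmentation threshold falls roughly midway between the marrow and bone
levels, where partial-volume blur from the reconstruction filter does not
bias the recovered bone fraction.

The texture is *not* a biofidelic trabecular microarchitecture (no
plate/rod morphology); only the volume fraction is controlled, which is
what the morphometry measures.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .voi_geometry import VOIGeometryParams
from .volume_io import LandmarkSet, Volume3D

#: emulated scanner full-scale gray value (native 16-bit-like range)
FULL_SCALE_GRAY = 32767.0


class PhantomError(RuntimeError):
    pass


@dataclass
class PhantomSpec:
    """Parameters of one synthetic proximal humerus.

    ``bvtv_profile`` may be a callable ``z_mm -> fraction``, a constant
    float, or a table of ``(z_mm, fraction)`` pairs (linearly interpolated);
    ``None`` selects the default linear craniocaudal gradient 0.40 (at the
    subcortical level) -> 0.10 (at the head's lower border).
    """

    head_radius: float = 24.0
    shaft_radius: float = 15.0
    shaft_length: float = 10.0
    cortical_thickness: float = 1.5
    spacing: float = 0.4
    texture_corr_length: float = 3.0  # voxels
    bvtv_profile: Callable | float | Sequence | None = None
    lateral_deficit: float = 1.0
    deficit_sector_deg: float = 100.0
    bcb_polar_deg: float = 20.0  # bone-cartilage border, polar angle from apex
    control_band_mm: float = 1.5  # radial width of fraction-control rings
    bone_gray: float = 7500.0
    marrow_gray: float = 0.0
    noise_sd: float = 150.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.spacing > 0:
            raise PhantomError("spacing must be positive")
        if not self.cortical_thickness < self.head_radius:
            raise PhantomError("head too small for the cortical shell")
        if not self.bone_gray > self.marrow_gray:
            raise PhantomError("bone_gray must exceed marrow_gray")
        if not 0.0 < self.lateral_deficit <= 1.0:
            raise PhantomError("lateral_deficit must lie in (0, 1]")

    @property
    def subcortical_z(self) -> float:
        """World z of the straight-design subcortical cut (one cortical
        thickness below the inner cortex surface at the apex)."""
        return self.head_radius - 2.0 * self.cortical_thickness

    def profile_function(self) -> Callable[[np.ndarray], np.ndarray]:
        p = self.bvtv_profile
        if p is None:
            z_top = self.subcortical_z

            def f(z):
                frac = 0.10 + 0.30 * np.clip(np.asarray(z, float) / z_top,
                                             0.0, 1.0)
                return frac
            return f
        if callable(p):
            return lambda z: np.asarray(p(np.asarray(z, float)), float)
        if np.isscalar(p):
            return lambda z: np.full_like(np.asarray(z, float), float(p))
        table = np.asarray(p, dtype=float)
        if table.ndim != 2 or table.shape[1] != 2:
            raise PhantomError("profile table must be (z, fraction) pairs")
        zs, fs = table[:, 0], table[:, 1]
        order = np.argsort(zs)
        return lambda z: np.interp(np.asarray(z, float), zs[order], fs[order])


@dataclass
class PhantomTruth:
    """Generated ground truth: per-z-slab realized trabecular bone fraction
    (the slabs partition the trabecular region), landmarks and seed."""

    slabs: pd.DataFrame  # columns z_lo, z_hi, n_voxels, target, realized
    landmark_set: LandmarkSet
    seed: int

    def realized_fraction(self, z_lo: float | None = None,
                          z_hi: float | None = None) -> float:
        """Voxel-weighted realized fraction over a z range (default: all)."""
        s = self.slabs
        if z_lo is not None:
            s = s[s["z_hi"] > z_lo]
        if z_hi is not None:
            s = s[s["z_lo"] < z_hi]
        n = s["n_voxels"].sum()
        return float((s["realized"] * s["n_voxels"]).sum() / n)


@dataclass
class PhantomPair:
    """Left/right specimens of one synthetic donor."""

    left: tuple[Volume3D, LandmarkSet, PhantomTruth]
    right: tuple[Volume3D, LandmarkSet, PhantomTruth]
    scale_left: float
    scale_right: float


# ---------------------------------------------------------------------------
# solid oracles
# ---------------------------------------------------------------------------

#: generic per-axis sub-voxel stagger (sqrt2-1, sqrt3-1, golden fraction) for
#: solid oracles; it keeps analytic boundaries off lattice symmetry points,
#: where the center-inclusion rule would otherwise be systematically
#: one-sided
GRID_STAGGER = np.array([0.414214, 0.732051, 0.381966])

def _symmetric_grid(extent_xyz: np.ndarray, spacing: float,
                    margin_voxels: int = 2, stagger=0.0):
    """Grid centered on the world origin.  With ``stagger=0`` voxel centers
    sit at half-voxel offsets (symmetric about 0, so an x-mirror maps the
    lattice onto itself); a nonzero stagger shifts centers by that fraction
    of a voxel per axis to avoid boundary/lattice coincidences."""
    n = (np.ceil(extent_xyz / spacing).astype(int)
         + 2 * margin_voxels)
    n += n % 2  # even, keeps centers symmetric about 0
    origin = -(n / 2.0 - 0.5 - np.asarray(stagger)) * spacing
    return n, origin


def make_solid_phantom(shape: str, dims: dict, spacing: float
                       ) -> tuple[Volume3D, float]:
    """Binary voxelization of an analytic solid plus its exact volume.

    ``shape``: ``cube`` (side), ``sphere`` (radius), ``cylinder`` (radius,
    length), ``annular_tube`` (inner_diameter, outer_diameter, length); all
    dims in mm.  A voxel is foreground iff its center lies inside the solid.
    """
    if any(v <= 0 for v in dims.values()):
        raise PhantomError("solid dimensions must be positive")

    if shape == "cube":
        side = dims["side"]
        extent = np.array([side, side, side])
        analytic = side ** 3
    elif shape == "sphere":
        r = dims["radius"]
        extent = np.array([2 * r] * 3)
        analytic = 4.0 / 3.0 * np.pi * r ** 3
    elif shape == "cylinder":
        r, length = dims["radius"], dims["length"]
        extent = np.array([2 * r, 2 * r, length])
        analytic = np.pi * r ** 2 * length
    elif shape == "annular_tube":
        ri = dims["inner_diameter"] / 2.0
        ro = dims["outer_diameter"] / 2.0
        length = dims["length"]
        if ri >= ro:
            raise PhantomError("inner diameter must be below outer diameter")
        extent = np.array([2 * ro, 2 * ro, length])
        analytic = np.pi * (ro ** 2 - ri ** 2) * length
    else:
        raise PhantomError(f"unknown solid shape '{shape}'")

    n, origin = _symmetric_grid(extent, spacing, stagger=GRID_STAGGER)
    x = (origin[0] + spacing * np.arange(n[0]))[:, None, None]
    y = (origin[1] + spacing * np.arange(n[1]))[None, :, None]
    z = (origin[2] + spacing * np.arange(n[2]))[None, None, :]

    if shape == "cube":
        h = dims["side"] / 2.0
        inside = (np.abs(x) <= h) & (np.abs(y) <= h) & (np.abs(z) <= h)
    elif shape == "sphere":
        inside = x ** 2 + y ** 2 + z ** 2 <= dims["radius"] ** 2
    elif shape == "cylinder":
        inside = (x ** 2 + y ** 2 <= dims["radius"] ** 2) \
            & (np.abs(z) <= dims["length"] / 2.0)
    else:
        r2 = x ** 2 + y ** 2 + np.zeros_like(z)
        inside = (r2 >= ri ** 2) & (r2 <= ro ** 2) \
            & (np.abs(z) <= length / 2.0)

    vol = Volume3D(inside.astype(np.uint8), spacing, origin)
    return vol, float(analytic)


# ---------------------------------------------------------------------------
# trabecular phantom
# ---------------------------------------------------------------------------

def _bent_subcortical_z(spec: PhantomSpec,
                        geom: VOIGeometryParams) -> float:
    """Highest z at which the bent tube's full annular cross-section still
    fits inside the inner cortex surface, minus one cortical thickness."""
    R, t = spec.head_radius, spec.cortical_thickness
    theta = np.deg2rad(spec.bcb_polar_deg)
    x_bcb, z_bcb = R * np.sin(theta), R * np.cos(theta)
    tan_a = np.tan(np.deg2rad(geom.bend_angle))
    r_out = geom.outer_diameter / 2.0
    r_in_cortex = R - t

    z = np.linspace(0.0, R, 4096)
    offset = x_bcb - (z_bcb - z) * tan_a
    ok = (np.abs(offset) + r_out) ** 2 + z ** 2 <= r_in_cortex ** 2
    if not ok.any():
        raise PhantomError("bent tube does not fit inside the head")
    z_fit = z[ok].max()
    cut = z_fit - t
    if cut <= 0:
        raise PhantomError("bent subcortical cut falls below the head border")
    return float(cut)


def _select_top(vals: np.ndarray, fraction: float) -> np.ndarray:
    """Boolean mask of the ``round(fraction * n)`` largest entries."""
    n = vals.size
    nsel = int(round(fraction * n))
    chosen = np.zeros(n, dtype=bool)
    if nsel >= n:
        return np.ones(n, dtype=bool)
    if nsel > 0:
        top = np.argpartition(vals, n - nsel)[n - nsel:]
        chosen[top] = True
    return chosen


def build_landmarks(spec: PhantomSpec,
                    geom: VOIGeometryParams | None = None) -> LandmarkSet:
    """Landmarks consistent with the constructed geometry (left side)."""
    geom = geom or VOIGeometryParams()
    R = spec.head_radius
    theta = np.deg2rad(spec.bcb_polar_deg)
    return LandmarkSet(
        head_apex=[0.0, 0.0, R],
        shaft_axis_point=[0.0, 0.0, -spec.shaft_length / 2.0],
        shaft_axis_dir=[0.0, 0.0, 1.0],
        lateral_bcb_point=[R * np.sin(theta), 0.0, R * np.cos(theta)],
        head_lower_z=0.0,
        subcortical_cut={
            "straight": spec.subcortical_z,
            "bent": _bent_subcortical_z(spec, geom),
        },
    )


def _mirror_x(vol: Volume3D, lm: LandmarkSet) -> tuple[Volume3D, LandmarkSet]:
    """Reflect a specimen in x (left <-> right).  The symmetric grid maps
    onto itself, so the origin is unchanged."""
    data = vol.data[::-1].copy()
    lm2 = LandmarkSet(
        head_apex=lm.head_apex * [-1, 1, 1],
        shaft_axis_point=lm.shaft_axis_point * [-1, 1, 1],
        shaft_axis_dir=lm.shaft_axis_dir * [-1, 1, 1],
        lateral_bcb_point=lm.lateral_bcb_point * [-1, 1, 1],
        head_lower_z=lm.head_lower_z,
        subcortical_cut=dict(lm.subcortical_cut),
    )
    return Volume3D(data, vol.spacing, vol.origin.copy()), lm2


def make_trabecular_phantom(spec: PhantomSpec, side: str = "left"
                            ) -> tuple[Volume3D, LandmarkSet, PhantomTruth]:
    """Generate one gray-level phantom, its landmarks and its ground truth.

    Identical ``spec`` (including ``seed``) gives bit-identical output; the
    right side is the mirrored (x -> -x) left-frame construction.
    """
    if side not in ("left", "right"):
        raise PhantomError(f"side must be 'left' or 'right', got '{side}'")
    R, t, s = spec.head_radius, spec.cortical_thickness, spec.spacing
    profile = spec.profile_function()

    margin = 2.0 * s
    extent = np.array([2 * (R + margin), 2 * (R + margin),
                       spec.shaft_length + R + 2 * margin])
    n, origin = _symmetric_grid(extent, s)
    # shift z so the grid spans [-shaft_length - margin, R + margin]
    origin[2] = -(spec.shaft_length + margin) + s / 2.0
    x = (origin[0] + s * np.arange(n[0]))[:, None, None]
    y = (origin[1] + s * np.arange(n[1]))[None, :, None]
    z = (origin[2] + s * np.arange(n[2]))[None, None, :]

    head = (z >= 0) & (x ** 2 + y ** 2 + z ** 2 <= R ** 2)
    shaft = (z < 0) & (z >= -spec.shaft_length) \
        & (x ** 2 + y ** 2 <= spec.shaft_radius ** 2)
    solid = head | shaft

    # cortical shell: solid voxels within one thickness of the exterior
    dist_in = ndimage.distance_transform_edt(solid, sampling=s)
    trab = solid & (dist_in > t)
    cortex = solid & ~trab

    ss = np.random.SeedSequence(spec.seed)
    rng_texture, rng_noise = [np.random.default_rng(c) for c in ss.spawn(2)]
    fld = ndimage.gaussian_filter(rng_texture.standard_normal(tuple(n)),
                                  spec.texture_corr_length)

    half = np.deg2rad(spec.deficit_sector_deg) / 2.0
    sector = (x > 0) & (np.abs(y) <= x * np.tan(half)) & (z >= 0) \
        & np.ones_like(z, dtype=bool)

    # fraction control: within each z layer, concentric radial rings (width
    # control_band_mm, centered on the shaft axis) crossed with the deficit
    # sector each receive exactly round(f * n) bone voxels — the ring's top
    # field values.  Ring edges align with the nail-tube radii, so the
    # fraction seen by a tube quarter is pinned to the target rather than
    # fluctuating with the random field's long-wavelength structure.
    r_band = (np.sqrt(x ** 2 + y ** 2) / spec.control_band_mm).astype(int) \
        + np.zeros(tuple(n), dtype=int)
    bone_trab = np.zeros(tuple(n), dtype=bool)
    slab_rows = []
    z_centers = origin[2] + s * np.arange(n[2])
    for k in range(n[2]):
        layer = trab[:, :, k]
        m = int(layer.sum())
        if m == 0:
            continue
        zc = z_centers[k]
        target = float(profile(np.array([zc]))[0])
        if not 0.0 <= target <= 1.0 or not np.isfinite(target):
            raise PhantomError(f"profile value {target} at z={zc} invalid")
        ii, jj = np.nonzero(layer)
        vals = fld[ii, jj, k]
        in_sector = sector[:, :, k][layer]
        bands = r_band[ii, jj, k]
        chosen = np.zeros(m, dtype=bool)
        for sec_flag, f in ((True, np.clip(target * spec.lateral_deficit,
                                           0.0, 1.0)),
                            (False, target)):
            grp = in_sector == sec_flag
            gb = bands[grp]
            gv = vals[grp]
            gsel = np.zeros(gb.size, dtype=bool)
            for b in np.unique(gb):
                ring = gb == b
                gsel[ring] = _select_top(gv[ring], f)
            chosen[grp] = gsel
        sub = np.zeros_like(layer)
        sub[layer] = chosen
        bone_trab[:, :, k] = sub
        slab_rows.append({
            "z_lo": zc - s / 2.0, "z_hi": zc + s / 2.0, "n_voxels": m,
            "target": target, "realized": float(chosen.sum()) / m,
        })

    bone = cortex | bone_trab
    gray = np.where(bone, spec.bone_gray, spec.marrow_gray) \
        + rng_noise.normal(0.0, spec.noise_sd, size=tuple(n))
    vol = Volume3D(gray, s, origin)
    lm = build_landmarks(spec)
    if side == "right":
        vol, lm = _mirror_x(vol, lm)
    truth = PhantomTruth(slabs=pd.DataFrame(slab_rows), landmark_set=lm,
                         seed=spec.seed)
    return vol, lm, truth


# ---------------------------------------------------------------------------
# left/right pairs
# ---------------------------------------------------------------------------

def draw_pair_scales(rho: float, n_pairs: int, rng: np.random.Generator,
                     sd: float = 0.10) -> np.ndarray:
    """Per-pair multiplicative profile scales ``(n_pairs, 2)`` whose left and
    right columns correlate at ``rho`` in expectation."""
    if not -1.0 <= rho <= 1.0:
        raise PhantomError("rho must lie in [-1, 1]")
    z0 = rng.standard_normal(n_pairs)
    z1 = rng.standard_normal(n_pairs)
    a_left = z0
    a_right = rho * z0 + np.sqrt(max(0.0, 1.0 - rho ** 2)) * z1
    scales = 1.0 + sd * np.column_stack([a_left, a_right])
    return np.clip(scales, 0.2, 2.0)


def make_paired_phantoms(spec: PhantomSpec, rho: float, n_pairs: int,
                         seed: int, profile_perturb_sd: float = 0.10
                         ) -> list[PhantomPair]:
    """Left/right phantom pairs whose density profiles correlate at ``rho``.

    Each pair shares one texture seed (the right side is the mirrored
    geometry), so at ``rho = 1`` the right volume is exactly the left volume
    reflected in x.
    """
    if not -1.0 <= rho <= 1.0:
        raise PhantomError("rho must lie in [-1, 1]")
    if n_pairs < 2:
        raise PhantomError("need at least 2 pairs")
    ss = np.random.SeedSequence(seed)
    scale_rng = np.random.default_rng(ss.spawn(1)[0])
    scales = draw_pair_scales(rho, n_pairs, scale_rng, profile_perturb_sd)
    base = spec.profile_function()

    pairs = []
    pair_seeds = np.random.default_rng(ss.spawn(1)[0]).integers(
        0, 2 ** 31 - 1, size=n_pairs)
    for i in range(n_pairs):
        out = {}
        for j, side in enumerate(("left", "right")):
            scale = float(scales[i, j])
            pspec = dataclasses.replace(
                spec,
                bvtv_profile=_scaled_profile(base, scale),
                seed=int(pair_seeds[i]),
            )
            out[side] = make_trabecular_phantom(pspec, side=side)
        pairs.append(PhantomPair(left=out["left"], right=out["right"],
                                 scale_left=float(scales[i, 0]),
                                 scale_right=float(scales[i, 1])))
    return pairs


def _scaled_profile(base: Callable, scale: float) -> Callable:
    def f(z):
        return np.clip(scale * base(z), 0.0, 1.0)
    return f
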