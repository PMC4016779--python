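"""Reading and writing of 3D volumes, landmark files, study manifests and reports.

Conventions
-----------
* A :class:`Volume3D` stores its voxel data in an array indexed ``[i, j, k]``
  along world x, y, z.  The world position of voxel ``(i, j, k)`` is
  ``origin + spacing * (i, j, k)``; a voxel value represents its center.
* Anatomical axes are fixed: +x lateral, +y anterior, +z proximal.  Files in
  other orientations must be reoriented upstream.
* Spacing is a single isotropic scalar in mm.  Anisotropic files are rejected
  unless an explicit override resamples them (nearest neighbor, with a
  warning), because every geometric tolerance downstream is stated in voxels.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

AXES_CONVENTION = "+x lateral, +y anterior, +z proximal"

#: relative tolerance within which per-axis spacings are considered isotropic
ISOTROPY_RTOL = 1e-3


class VolumeIOError(RuntimeError):
    """Base class for volume/landmark/manifest I/O failures."""


class UnsupportedFormatError(VolumeIOError):
    pass


class AnisotropicSpacingError(VolumeIOError):
    pass


class LandmarkSchemaError(VolumeIOError):
    pass


class ManifestError(VolumeIOError):
    pass


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Volume3D:
    """Isotropic 3D scalar grid: a CT image or a derived binary/label mask."""

    data: np.ndarray
    spacing: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    axes_convention: str = AXES_CONVENTION

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.origin = np.asarray(self.origin, dtype=float)
        self.spacing = float(self.spacing)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError("volume data must be a non-empty 3D array")
        if not self.spacing > 0:
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if np.issubdtype(self.data.dtype, np.floating) and not np.all(
            np.isfinite(self.data)
        ):
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return self.spacing ** 3

    def voxel_centers_1d(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centers along one axis (mm)."""
        n = self.data.shape[axis]
        return self.origin[axis] + self.spacing * np.arange(n)

    def like(self, data: np.ndarray) -> "Volume3D":
        """A new volume on the same grid with different data."""
        if data.shape != self.data.shape:
            raise ValueError("grid shape mismatch")
        return Volume3D(data, self.spacing, self.origin.copy())


@dataclass
class LandmarkSet:
    """Anatomical reference points fixing the specimen frame and VOI placement.

    ``subcortical_cut`` maps each design (``straight``/``bent``) to the world
    z (mm) of the plane below which the VOI contains cancellous bone only; it
    replaces the study's manual cortical separation.
    """

    head_apex: np.ndarray
    shaft_axis_point: np.ndarray
    shaft_axis_dir: np.ndarray
    lateral_bcb_point: np.ndarray
    head_lower_z: float
    subcortical_cut: dict[str, float]

    def __post_init__(self) -> None:
        for name in ("head_apex", "shaft_axis_point", "shaft_axis_dir",
                     "lateral_bcb_point"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (3,) or not np.all(np.isfinite(v)):
                raise LandmarkSchemaError(f"{name} must be a finite 3-vector")
            setattr(self, name, v)
        self.head_lower_z = float(self.head_lower_z)
        norm = float(np.linalg.norm(self.shaft_axis_dir))
        if norm == 0.0:
            raise LandmarkSchemaError("shaft_axis_dir has zero length")
        self.shaft_axis_dir = self.shaft_axis_dir / norm
        cuts = dict(self.subcortical_cut)
        for design in ("straight", "bent"):
            if design not in cuts:
                raise LandmarkSchemaError(
                    f"subcortical_cut missing required design '{design}'")
            cuts[design] = float(cuts[design])
            if not self.head_lower_z < cuts[design]:
                raise LandmarkSchemaError(
                    f"head_lower_z ({self.head_lower_z}) must lie below the "
                    f"{design} subcortical cut ({cuts[design]})")
        self.subcortical_cut = cuts


REQUIRED_LANDMARK_KEYS = (
    "head_apex", "shaft_axis_point", "shaft_axis_dir",
    "lateral_bcb_point", "head_lower_z", "subcortical_cut",
)

MANIFEST_COLUMNS = (
    "specimen_id", "donor_id", "side", "sex", "age",
    "volume_path", "landmark_path",
)


# ---------------------------------------------------------------------------
# volume readers / writers
# ---------------------------------------------------------------------------

def _detect_format(path: Path) -> str:
    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith((".mha", ".mhd")):
        return "metaimage"
    if suffixes.endswith((".nii", ".nii.gz")):
        return "nifti"
    if path.is_dir() or suffixes.endswith((".tif", ".tiff")):
        return "tiff_stack"
    raise UnsupportedFormatError(f"cannot infer volume format of {path}")


def _check_isotropy(spacing_xyz: np.ndarray, path: Path,
                    spacing_override: float | None) -> float:
    spacing_xyz = np.asarray(spacing_xyz, dtype=float)
    mean = float(spacing_xyz.mean())
    if np.max(np.abs(spacing_xyz - mean)) <= ISOTROPY_RTOL * mean:
        return mean
    if spacing_override is not None:
        warnings.warn(
            f"{path}: anisotropic spacing {tuple(spacing_xyz)} overridden to "
            f"{spacing_override} mm without resampling checks", stacklevel=3)
        logger.warning("anisotropy override on %s", path)
        return float(spacing_override)
    raise AnisotropicSpacingError(
        f"{path}: spacing {tuple(spacing_xyz)} is anisotropic beyond "
        f"{ISOTROPY_RTOL:.1%}; pass spacing_override to force")


def read_volume(path, format: str = "auto",
                spacing_override: float | None = None) -> Volume3D:
    """Read a 3D volume from MetaImage, NIfTI-1 or a TIFF slice stack.

    Gray values are preserved bit-exactly for integer inputs.  TIFF stacks
    are directories of per-slice files with a ``spacing.json`` sidecar.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _detect_format(path) if format == "auto" else format

    if fmt == "metaimage":
        import SimpleITK as sitk

        img = sitk.ReadImage(str(path))
        arr = sitk.GetArrayFromImage(img)  # (z, y, x)
        data = np.ascontiguousarray(arr.transpose(2, 1, 0))
        spacing = _check_isotropy(img.GetSpacing(), path, spacing_override)
        origin = np.asarray(img.GetOrigin(), dtype=float)
    elif fmt == "nifti":
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
        zooms = img.header.get_zooms()[:3]
        spacing = _check_isotropy(np.asarray(zooms), path, spacing_override)
        origin = np.asarray(img.affine[:3, 3], dtype=float)
    elif fmt == "tiff_stack":
        import tifffile

        if not path.is_dir():
            raise UnsupportedFormatError(
                f"tiff_stack expects a directory of slices, got {path}")
        sidecar = path / "spacing.json"
        if not sidecar.exists():
            raise VolumeIOError(f"missing spacing sidecar {sidecar}")
        meta = json.loads(sidecar.read_text())
        spacing = float(meta["spacing_mm"]) if spacing_override is None \
            else float(spacing_override)
        origin = np.asarray(meta.get("origin_mm", [0.0, 0.0, 0.0]), float)
        slices = sorted(p for p in path.iterdir()
                        if p.suffix.lower() in (".tif", ".tiff"))
        if not slices:
            raise VolumeIOError(f"no TIFF slices in {path}")
        planes = [tifffile.imread(str(p)) for p in slices]  # each (y, x)
        data = np.stack([p.T for p in planes], axis=2)
    else:
        raise UnsupportedFormatError(f"unsupported volume format '{fmt}'")

    return Volume3D(data, spacing, origin)


def write_volume(vol: Volume3D, path, format: str = "auto") -> None:
    """Write a volume; format inferred from the path unless given."""
    path = Path(path)
    fmt = _detect_format(path) if format == "auto" else format

    if fmt == "metaimage":
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(
            np.ascontiguousarray(vol.data.transpose(2, 1, 0)))
        img.SetSpacing((vol.spacing,) * 3)
        img.SetOrigin(tuple(float(v) for v in vol.origin))
        sitk.WriteImage(img, str(path))
    elif fmt == "nifti":
        import nibabel as nib

        affine = np.diag([vol.spacing] * 3 + [1.0])
        affine[:3, 3] = vol.origin
        nib.save(nib.Nifti1Image(vol.data, affine), str(path))
    elif fmt == "tiff_stack":
        import tifffile

        path.mkdir(parents=True, exist_ok=True)
        (path / "spacing.json").write_text(json.dumps(
            {"spacing_mm": vol.spacing,
             "origin_mm": [float(v) for v in vol.origin]}))
        nz = vol.data.shape[2]
        width = max(4, len(str(nz)))
        for k in range(nz):
            tifffile.imwrite(str(path / f"slice_{k:0{width}d}.tif"),
                             np.ascontiguousarray(vol.data[:, :, k].T))
    else:
        raise UnsupportedFormatError(f"unsupported volume format '{fmt}'")


# ---------------------------------------------------------------------------
# landmarks
# ---------------------------------------------------------------------------

def read_landmarks(path) -> LandmarkSet:
    """Parse a landmark JSON file, validating schema and invariants."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    obj = json.loads(path.read_text())
    missing = [k for k in REQUIRED_LANDMARK_KEYS if k not in obj]
    if missing:
        raise LandmarkSchemaError(
            f"{path}: missing landmark key(s): {', '.join(missing)}")
    return LandmarkSet(
        head_apex=obj["head_apex"],
        shaft_axis_point=obj["shaft_axis_point"],
        shaft_axis_dir=obj["shaft_axis_dir"],
        lateral_bcb_point=obj["lateral_bcb_point"],
        head_lower_z=obj["head_lower_z"],
        subcortical_cut=obj["subcortical_cut"],
    )


def write_landmarks(lm: LandmarkSet, path) -> None:
    obj = {
        "head_apex": [float(v) for v in lm.head_apex],
        "shaft_axis_point": [float(v) for v in lm.shaft_axis_point],
        "shaft_axis_dir": [float(v) for v in lm.shaft_axis_dir],
        "lateral_bcb_point": [float(v) for v in lm.lateral_bcb_point],
        "head_lower_z": lm.head_lower_z,
        "subcortical_cut": dict(lm.subcortical_cut),
    }
    Path(path).write_text(json.dumps(obj, indent=2))


# ---------------------------------------------------------------------------
# manifests and reports
# ---------------------------------------------------------------------------

def read_manifest(path) -> pd.DataFrame:
    """Read and validate a study manifest CSV."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"specimen_id": str, "donor_id": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestError(f"{path}: manifest missing columns {missing}")
    if df["specimen_id"].duplicated().any():
        dupes = df.loc[df["specimen_id"].duplicated(), "specimen_id"].tolist()
        raise ManifestError(f"{path}: duplicate specimen_id(s) {dupes}")
    bad_side = set(df["side"]) - {"left", "right"}
    if bad_side:
        raise ManifestError(f"{path}: invalid side value(s) {bad_side}")
    bad_sex = set(df["sex"]) - {"m", "f"}
    if bad_sex:
        raise ManifestError(f"{path}: invalid sex value(s) {bad_sex}")
    return df


def write_report(results: pd.DataFrame, path, format: str = "csv",
                 stats: dict | None = None) -> None:
    """Write morphometry results (and optionally a stats report) to disk.

    Column order is deterministic and floats carry 12 significant digits, so
    a write/read round trip reproduces values exactly at that precision.
    """
    if results is None or len(results) == 0:
        raise ValueError("results are empty; nothing to report")
    path = Path(path)
    results = results.copy()
    if format == "csv":
        results.to_csv(path, index=False, float_format="%.12g")
    elif format == "json":
        payload: dict = {"results": []}
        for specimen_id, group in results.groupby("specimen_id", sort=True):
            payload["results"].append({
                "specimen_id": specimen_id,
                "rows": json.loads(
                    group.to_json(orient="records", double_precision=12)),
            })
        if stats is not None:
            payload["stats"] = stats
        path.write_text(json.dumps(payload, indent=1))
    else:
        raise UnsupportedFormatError(f"unsupported report format '{format}'")


def read_report(path, format: str = "csv") -> pd.DataFrame:
    path = Path(path)
    if format == "csv":
        return pd.read_csv(path)
    if format == "json":
        payload = json.loads(path.read_text())
        rows = [row for spec in payload["results"] for row in spec["rows"]]
        return pd.DataFrame(rows)
    raise UnsupportedFormatError(f"unsupported report format '{format}'")
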