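"""Volume, mask and table I/O plus the coordinate and unit conventions.

Conventions used throughout the package
---------------------------------------
* Axis order is ``(depth, slow-lateral, fast-lateral)`` — a stack of
  cross-sectional B-scans, depth first.  Voxel indices are 0-based and the
  centre of voxel ``i`` sits at ``(i + 0.5) * spacing`` along each axis.
* All lengths are micrometres (µm), volumes are microlitres
  (1 µl = 1 mm³ = 1e9 µm³) and surface areas are mm² (1 mm² = 1e6 µm²).
  The conversion constants below are the single authoritative definition.
* Volumes are written either as multi-page TIFF (one page per depth slice,
  spacing stored as JSON in the image description) or NIfTI-1 (spacing in
  the header zooms, millimetre units).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "UM3_PER_UL",
    "UM2_PER_MM2",
    "UM_PER_MM",
    "ImageVolume",
    "BinaryMask",
    "Site",
    "Substance",
    "DepositRecord",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "apply_refractive_correction",
    "write_measurements",
    "read_measurements",
    "MEASUREMENT_COLUMNS",
]

UM3_PER_UL = 1e9
UM2_PER_MM2 = 1e6
UM_PER_MM = 1e3


def _validate_spacing(spacing: Sequence[float]) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3:
        raise ValueError(f"spacing must have 3 entries (depth, slow, fast), got {spacing}")
    if any(not np.isfinite(s) or s <= 0 for s in spacing):
        raise ValueError(f"spacing entries must be positive and finite, got {spacing}")
    return spacing  # type: ignore[return-value]


@dataclass
class ImageVolume:
    """A 3D scalar intensity grid with physical voxel spacing.

    Parameters
    ----------
    data
        3D array, axis order (depth, slow-lateral, fast-lateral).
    spacing
        Voxel spacing ``(d_depth, d_slow, d_fast)`` in µm, all positive.
    meta
        Free-form provenance (applied corrections, source path, ...).
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(
                f"expected a 3D volume (depth, slow, fast); got {self.data.ndim} dimensions"
            )
        self.spacing = _validate_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_um3(self) -> float:
        dz, dy, dx = self.spacing
        return dz * dy * dx

    @property
    def extent_um(self) -> tuple[float, float, float]:
        """Physical size of the grid along each axis in µm."""
        return tuple(n * s for n, s in zip(self.shape, self.spacing))  # type: ignore[return-value]


@dataclass
class BinaryMask:
    """Boolean deposit-occupancy grid sharing shape and spacing with a volume."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(
                f"expected a 3D mask (depth, slow, fast); got {self.data.ndim} dimensions"
            )
        if self.data.dtype != bool:
            uniq = np.unique(self.data)
            if not np.isin(uniq, (0, 1)).all():
                raise ValueError("mask data must be boolean or contain only {0, 1}")
            self.data = self.data.astype(bool)
        self.spacing = _validate_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_um3(self) -> float:
        dz, dy, dx = self.spacing
        return dz * dy * dx

    def voxel_count(self) -> int:
        return int(self.data.sum())

    def volume_ul(self) -> float:
        """Occupied volume in µl (voxel count × voxel volume)."""
        return self.voxel_count() * self.voxel_volume_um3 / UM3_PER_UL

    def check_compatible(self, other: "BinaryMask | ImageVolume") -> None:
        if self.shape != other.shape:
            raise ValueError(f"shape mismatch: {self.shape} vs {other.shape}")
        if not np.allclose(self.spacing, other.spacing):
            raise ValueError(f"spacing mismatch: {self.spacing} vs {other.spacing}")


class Site(str, Enum):
    """Dorsal injection sites, cranial/caudal × left/right."""

    A_left_cranial = "A_left_cranial"
    B_right_cranial = "B_right_cranial"
    C_left_caudal = "C_left_caudal"
    D_right_caudal = "D_right_caudal"


class Substance(str, Enum):
    """Injected materials: two test hydrogels, a commercial HA filler and
    the 0.5% sodium-HA control."""

    Hydrogel1 = "Hydrogel1"
    Hydrogel2 = "Hydrogel2"
    PRV = "PRV"
    Control = "Control"


@dataclass(frozen=True)
class DepositRecord:
    """Identity of one deposit observation: animal, site, substance, week."""

    animal_id: str
    site: Site
    substance: Substance
    timepoint: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "site", Site(self.site))
        object.__setattr__(self, "substance", Substance(self.substance))
        if self.timepoint is not None:
            if self.timepoint < 0:
                raise ValueError(f"timepoint must be non-negative, got {self.timepoint}")
            object.__setattr__(self, "timepoint", float(self.timepoint))

    def key(self) -> tuple[str, str, float | None]:
        return (self.animal_id, self.site.value, self.timepoint)


# ---------------------------------------------------------------------------
# Volume / mask file I/O
# ---------------------------------------------------------------------------

_TIFF_SUFFIXES = {".tif", ".tiff"}
_NIFTI_SUFFIXES = {".nii"}


def _is_nifti(path: Path) -> bool:
    return path.suffix in _NIFTI_SUFFIXES or path.name.endswith(".nii.gz")


def write_volume(volume: ImageVolume, path: str | Path) -> Path:
    """Write a volume as multi-page TIFF or NIfTI-1, spacing in the header.

    TIFF stores spacing (µm) as JSON in the image description; NIfTI stores
    it in the header zooms in millimetres, the format's conventional unit.
    """
    path = Path(path)
    if _is_nifti(path):
        import nibabel as nib

        zooms_mm = tuple(s / UM_PER_MM for s in volume.spacing)
        affine = np.diag(list(zooms_mm) + [1.0])
        img = nib.Nifti1Image(np.asarray(volume.data), affine)
        img.header.set_zooms(zooms_mm)
        img.header.set_xyzt_units(xyz="mm")
        nib.save(img, str(path))
    elif path.suffix in _TIFF_SUFFIXES:
        import tifffile

        desc = json.dumps({"spacing_um": list(volume.spacing), "axes": "ZYX"})
        tifffile.imwrite(
            str(path), np.asarray(volume.data), description=desc, photometric="minisblack"
        )
    else:
        raise ValueError(f"unsupported volume format {path.suffix!r}; use .tif/.tiff or .nii")
    return path


def read_volume(path: str | Path, spacing_override: Sequence[float] | None = None) -> ImageVolume:
    """Read a multi-page TIFF or NIfTI volume.

    Spacing comes from the file header; if the header carries no physical
    units an explicit ``spacing_override`` (µm) is required — silently
    unitless volumes are refused because every downstream quantity is
    physical.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if _is_nifti(path):
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
        if data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got {data.ndim}D data in {path}")
        if spacing_override is not None:
            spacing = _validate_spacing(spacing_override)
        else:
            zooms = img.header.get_zooms()[:3]
            if any(z <= 0 for z in zooms):
                raise ValueError(
                    f"{path} has no positive voxel sizes in its header; pass spacing_override"
                )
            spacing = _validate_spacing(tuple(z * UM_PER_MM for z in zooms))
        return ImageVolume(data, spacing, meta={"source": str(path)})
    if path.suffix in _TIFF_SUFFIXES:
        import tifffile

        with tifffile.TiffFile(str(path)) as tif:
            data = tif.asarray()
            desc = tif.pages[0].description
        if data.ndim == 2:
            data = data[None]
        if data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got {data.ndim}D data in {path}")
        if data.shape[0] == 1 and spacing_override is None:
            raise ValueError(f"{path} holds a single 2D page; a 3D volume is required")
        spacing = None
        if desc:
            try:
                parsed = json.loads(desc)
                spacing = _validate_spacing(parsed["spacing_um"])
            except (json.JSONDecodeError, KeyError, TypeError, ValueError):
                spacing = None
        if spacing_override is not None:
            spacing = _validate_spacing(spacing_override)
        if spacing is None:
            raise ValueError(
                f"{path} carries no voxel-spacing metadata; pass spacing_override=(dz, dy, dx) in µm"
            )
        return ImageVolume(data, spacing, meta={"source": str(path)})
    raise ValueError(f"unsupported volume format {path.suffix!r}; use .tif/.tiff or .nii")


def write_mask(mask: BinaryMask, path: str | Path) -> Path:
    """Write a binary mask in the same formats as volumes, values {0, 1}."""
    vol = ImageVolume(mask.data.astype(np.uint8), mask.spacing, meta=dict(mask.meta))
    return write_volume(vol, path)


def read_mask(path: str | Path, spacing_override: Sequence[float] | None = None) -> BinaryMask:
    vol = read_volume(path, spacing_override=spacing_override)
    return BinaryMask(vol.data, vol.spacing, meta=dict(vol.meta))


def apply_refractive_correction(volume: ImageVolume, n_tissue: float) -> ImageVolume:
    """Convert the optical depth axis to geometric depth.

    OCT measures optical path length along depth; dividing the depth
    spacing by the tissue group refractive index ``n_tissue`` converts it
    to geometric length.  Lateral spacing is unaffected.  The correction is
    opt-in and the applied index is recorded in ``meta``.
    """
    if n_tissue < 1:
        raise ValueError(f"refractive index must be >= 1, got {n_tissue}")
    dz, dy, dx = volume.spacing
    meta = dict(volume.meta)
    meta["refractive_index_applied"] = float(n_tissue)
    return replace(volume, spacing=(dz / n_tissue, dy, dx), meta=meta)


# ---------------------------------------------------------------------------
# Measurement tables
# ---------------------------------------------------------------------------

MEASUREMENT_COLUMNS = [
    "animal_id",
    "site",
    "substance",
    "week",
    "volume_ul",
    "surface_mm2",
    "sphericity",
    "centroid_depth_um",
    "centroid_slow_um",
    "centroid_fast_um",
    "estimator",
]


def write_measurements(records: Iterable[tuple[DepositRecord, "object"]], path: str | Path) -> Path:
    """Write per-deposit morphometry to CSV with the documented schema.

    ``records`` pairs a :class:`DepositRecord` with a ``MorphometryResult``
    (duck-typed: needs volume_ul, surface_mm2, sphericity, centroid_um,
    estimator).  Duplicate (animal, site, week) keys are an error.
    """
    rows = []
    seen: set[tuple] = set()
    for rec, morph in records:
        key = rec.key()
        if key in seen:
            raise ValueError(f"duplicate measurement key (animal, site, week) = {key}")
        seen.add(key)
        cz, cy, cx = morph.centroid_um if morph.centroid_um is not None else (np.nan,) * 3
        rows.append(
            {
                "animal_id": rec.animal_id,
                "site": rec.site.value,
                "substance": rec.substance.value,
                "week": rec.timepoint,
                "volume_ul": morph.volume_ul,
                "surface_mm2": morph.surface_mm2,
                "sphericity": morph.sphericity,
                "centroid_depth_um": cz,
                "centroid_slow_um": cy,
                "centroid_fast_um": cx,
                "estimator": morph.estimator,
            }
        )
    df = pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def read_measurements(path: str | Path) -> pd.DataFrame:
    """Read a measurements CSV written by :func:`write_measurements`."""
    df = pd.read_csv(path)
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"measurement table {path} is missing columns {missing}")
    keys = list(zip(df["animal_id"], df["site"], df["week"]))
    if len(keys) != len(set(keys)):
        raise ValueError(f"measurement table {path} contains duplicate (animal, site, week) keys")
    for s in df["site"].dropna():
        Site(s)
    for s in df["substance"].dropna():
        Substance(s)
    return df
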