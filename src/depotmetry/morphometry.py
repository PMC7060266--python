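"""Volume, surface area and sphericity of binary deposit masks.

The shape descriptor reported per deposit is the sphericity

    S = pi^(1/3) * (6 V)^(2/3) / A,

the surface area of the sphere with the deposit's volume V divided by the
deposit's actual surface area A.  A perfect sphere has S = 1; any other
shape has S < 1.  V is taken in mm^3 (= µl) and A in mm^2 so S is
dimensionless.

Surface-area estimation on a voxel grid is the delicate part.  Three
estimators are provided:

``naive_faces``
    Sum of exposed voxel faces.  Simple, but it measures the staircase
    surface rather than the underlying smooth one: for a digitized sphere
    it converges to 3/2 of the true area (the average of |nx|+|ny|+|nz|
    over the unit sphere is 3/2), so it is kept only as a documented
    baseline and is excluded from sphericity-range guarantees.

``weighted_config`` (default)
    Counts local 2x2x2 voxel configurations along the boundary and sums
    per-configuration weights.  The weights were calibrated once by
    non-negative least squares so that digitized spheres with radii of
    5-50 voxels reproduce 4*pi*r^2 (see scripts/calibrate_surface_weights.py);
    the resulting constants are frozen below.  Anisotropic grids are
    handled by re-digitizing the implicit surface (below) on an isotropic
    grid at the finest spacing.

``isosurface_mesh``
    Area of the triangulated implicit surface (marching cubes, physical
    spacing honoured).  Used as the independent oracle for the
    configuration-weighted estimator in the test suite.

The implicit surface shared by the latter two is the 0.5 level set of the
occupancy indicator after mild Gaussian smoothing (sigma = 1.2 x the
finest spacing).  Smoothing regularizes the staircase with a boundary
displacement of order sigma^2 x curvature — negligible for deposits tens
of voxels across — and empirically keeps both estimators within ~0.5% of
closed-form sphere/spheroid areas at >= 20 voxels per semi-axis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage import measure as _skmeasure

from .io import BinaryMask, UM2_PER_MM2

__all__ = [
    "MorphometryResult",
    "SURFACE_ESTIMATORS",
    "compute_volume",
    "compute_surface_area",
    "compute_sphericity",
    "measure",
]

SURFACE_ESTIMATORS = ("naive_faces", "weighted_config", "isosurface_mesh")

#: Per-configuration area weights for the 2x2x2 boundary-configuration
#: estimator, indexed by the number of foreground voxels (1..7) in the
#: local cell, in units of (isotropic voxel side)^2.  Calibrated against
#: digitized spheres of radii 5-50 voxels; regenerate with
#: scripts/calibrate_surface_weights.py.
_CONFIG_WEIGHTS = np.array([
    0.0,         # 0 foreground voxels: no surface
    0.36399641,  # 1
    0.59041808,  # 2
    0.83860326,  # 3
    1.04843873,  # 4
    0.83860326,  # 5  (complement symmetry with 3)
    0.59041808,  # 6  (complement symmetry with 2)
    0.36399641,  # 7  (complement symmetry with 1)
    0.0,         # 8: interior
])


class EmptyMaskError(ValueError):
    """Raised when an operation requires a nonempty mask."""


@dataclass(frozen=True)
class MorphometryResult:
    """Per-deposit morphometry: V (µl), A (mm²), S, and localization."""

    volume_ul: float
    surface_mm2: float
    sphericity: float
    centroid_um: tuple[float, float, float] | None
    bounding_box: tuple[tuple[int, int], ...] | None
    estimator: str
    n_voxels: int

    @property
    def is_empty(self) -> bool:
        return self.n_voxels == 0

    @classmethod
    def no_deposit(cls, estimator: str = "weighted_config") -> "MorphometryResult":
        """Explicit 'no deposit found' result (never silent zeros for A/S)."""
        return cls(0.0, float("nan"), float("nan"), None, None, estimator, 0)


def compute_volume(mask: BinaryMask) -> float:
    """Deposit volume in µl: voxel count times physical voxel volume."""
    return mask.volume_ul()


def _exposed_face_area_um2(mask: np.ndarray, spacing: Sequence[float]) -> float:
    """Sum of exposed voxel-face areas; faces exposed toward out-of-grid count."""
    dz, dy, dx = spacing
    face_area = (dy * dx, dz * dx, dz * dy)
    m = np.pad(mask, 1, constant_values=False).astype(np.int8)
    total = 0.0
    for axis, a in enumerate(face_area):
        n_faces = int(np.abs(np.diff(m, axis=axis)).sum())
        total += n_faces * a
    return total


def _config_counts(mask: np.ndarray) -> np.ndarray:
    """Histogram of foreground counts over all 2x2x2 cells of the padded grid."""
    p = np.pad(mask, 1, constant_values=False).astype(np.uint8)
    c = (
        p[:-1, :-1, :-1] + p[1:, :-1, :-1] + p[:-1, 1:, :-1] + p[:-1, :-1, 1:]
        + p[1:, 1:, :-1] + p[1:, :-1, 1:] + p[:-1, 1:, 1:] + p[1:, 1:, 1:]
    )
    return np.bincount(c.ravel(), minlength=9)[:9]


#: Smoothing scale of the implicit surface, in units of the finest spacing.
_IMPLICIT_SIGMA = 1.2


def _implicit_field(mask: np.ndarray, spacing: Sequence[float]) -> np.ndarray:
    """Gaussian-smoothed occupancy on the background-padded grid.

    The physical smoothing scale is isotropic (sigma = 1.2 x finest
    spacing); the per-axis voxel sigmas compensate for anisotropy.
    """
    spacing = np.asarray(spacing, dtype=float)
    sigma_vox = _IMPLICIT_SIGMA * spacing.min() / spacing
    padded = np.pad(mask, 2, constant_values=False).astype(np.float32)
    return ndimage.gaussian_filter(padded, sigma_vox)


def _resample_isotropic(mask: np.ndarray, spacing: Sequence[float]) -> tuple[np.ndarray, float]:
    """Re-digitize the mask on an isotropic grid at the finest spacing.

    The smoothed occupancy field is interpolated tri-linearly and
    re-thresholded at 0.5, which preserves the implicit surface far better
    than nearest-neighbour resampling of the labels.
    """
    spacing = np.asarray(spacing, dtype=float)
    h = float(spacing.min())
    if np.allclose(spacing, h):
        return mask, h
    field = _implicit_field(mask, spacing)  # grid padded by two voxels
    extent = np.array(field.shape) * spacing
    new_shape = np.maximum(np.round(extent / h).astype(int), 1)
    grids = np.meshgrid(
        *[(np.arange(n) + 0.5) * h / s - 0.5 for n, s in zip(new_shape, spacing)],
        indexing="ij",
    )
    iso = ndimage.map_coordinates(field, np.stack(grids), order=1, mode="nearest") >= 0.5
    return iso, h


def compute_surface_area(mask: BinaryMask, estimator: str = "weighted_config") -> float:
    """Deposit surface area in mm² with the chosen estimator.

    A voxel face counts as boundary when its 6-neighbour across that face
    is background or outside the grid (the grid is padded with background).
    """
    if estimator not in SURFACE_ESTIMATORS:
        raise ValueError(f"unknown estimator {estimator!r}; choose from {SURFACE_ESTIMATORS}")
    data = mask.data
    if not data.any():
        raise EmptyMaskError("cannot compute the surface area of an empty mask")

    if estimator == "naive_faces":
        area_um2 = _exposed_face_area_um2(data, mask.spacing)
    elif estimator == "weighted_config":
        iso, h = _resample_isotropic(data, mask.spacing)
        counts = _config_counts(iso)
        area_um2 = float(counts @ _CONFIG_WEIGHTS) * h * h
    else:  # isosurface_mesh
        field = _implicit_field(data, mask.spacing)
        verts, faces, _, _ = _skmeasure.marching_cubes(field, level=0.5, spacing=mask.spacing)
        area_um2 = float(_skmeasure.mesh_surface_area(verts, faces))
    return area_um2 / UM2_PER_MM2


def compute_sphericity(volume_ul: float, surface_mm2: float) -> float:
    """Sphericity S = pi^(1/3) (6 V)^(2/3) / A for V in µl (= mm³), A in mm².

    S equals 1 exactly when A is the area of the sphere of volume V and is
    smaller for any other shape.  Unit consistency (mm³ vs mm²) is the
    caller's responsibility.
    """
    if volume_ul <= 0:
        raise ValueError(f"volume must be positive, got {volume_ul}")
    if surface_mm2 <= 0:
        raise ValueError(f"surface area must be positive, got {surface_mm2}")
    return float(np.pi ** (1.0 / 3.0) * (6.0 * volume_ul) ** (2.0 / 3.0) / surface_mm2)


def measure(mask: BinaryMask, estimator: str = "weighted_config") -> MorphometryResult:
    """Bundle volume, surface area, sphericity, centroid and bounding box.

    An empty mask yields an explicit no-deposit result (V = 0, A and S NaN)
    rather than an error, so pipelines can record segmentation misses.
    """
    data = mask.data
    if not data.any():
        return MorphometryResult.no_deposit(estimator)
    v_ul = compute_volume(mask)
    a_mm2 = compute_surface_area(mask, estimator=estimator)
    s = compute_sphericity(v_ul, a_mm2)
    # A sphere maximizes S analytically; with the calibrated estimators any
    # overshoot beyond 1 is pure surface-digitization error (<~0.5%), so it
    # is clipped at the physical bound.  naive_faces is uncalibrated and
    # reports its raw (biased) value.
    if estimator != "naive_faces":
        s = min(s, 1.0)
    idx = np.nonzero(data)
    centroid = tuple(
        float((coords.mean() + 0.5) * d) for coords, d in zip(idx, mask.spacing)
    )
    bbox = tuple((int(coords.min()), int(coords.max()) + 1) for coords in idx)
    return MorphometryResult(
        volume_ul=v_ul,
        surface_mm2=a_mm2,
        sphericity=s,
        centroid_um=centroid,  # type: ignore[arg-type]
        bounding_box=bbox,
        estimator=estimator,
        n_voxels=int(data.sum()),
    )
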