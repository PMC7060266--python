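"""Classical intensity-based deposit segmentation and mask editing.

Hydrogel deposits scatter far less than the surrounding dermis, so they
appear as a dark, compact region inside a bright speckled background.  The
segmenter exploits exactly that contrast:

1. *Detection*: heavy Gaussian smoothing (physical sigma in µm, converted
   per axis to voxels) averages the speckle until the histogram is
   bimodal, and a global Otsu threshold isolates the dark class;
2. *Refinement*: the boundary of the heavily smoothed mask is biased by
   about the smoothing scale, so the final threshold — the midpoint of
   the dark/bright class means — is re-applied to a lightly smoothed
   volume, which restores the boundary to sub-voxel accuracy (an
   intensity edge between two plateaus crosses its midpoint at the true
   interface regardless of the smoothing scale);
3. morphological closing then opening with an ellipsoidal structuring
   element specified in µm;
4. largest 26-connected component;
5. a minimum-volume floor (default 0.5 µl, well below the ~12–37 µl
   deposits of interest) below which an *empty* mask is returned rather
   than a speckle artifact.

A contrast guard additionally rejects volumes whose "dark class" is not
actually dark (mean(dark)/mean(bright) above a ratio threshold), which is
what happens when Otsu is forced to split a deposit-free speckle
histogram down its middle.

Masks drawn or fixed by an operator can replace, extend or restrict the
automatic result via :func:`merge_manual_correction`.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .io import BinaryMask, ImageVolume

__all__ = [
    "SegmentationParams",
    "segment_deposit",
    "merge_manual_correction",
    "largest_component",
    "dice_coefficient",
]


@dataclass(frozen=True)
class SegmentationParams:
    """Tunables of the classical segmenter (all lengths physical, in µm)."""

    detect_sigma_um: float = 150.0
    refine_sigma_um: float = 60.0
    morph_radius_um: float = 120.0
    min_volume_ul: float = 0.5
    contrast_ratio_max: float = 0.5
    max_anisotropy: float = 20.0

    def __post_init__(self) -> None:
        if min(self.detect_sigma_um, self.refine_sigma_um, self.morph_radius_um) < 0:
            raise ValueError("smoothing sigmas and morphological radius must be >= 0")
        if self.min_volume_ul < 0:
            raise ValueError("min_volume_ul must be >= 0")
        if not 0 < self.contrast_ratio_max <= 1:
            raise ValueError("contrast_ratio_max must be in (0, 1]")


def _ellipsoid_footprint(radius_um: float, spacing: tuple[float, float, float]) -> np.ndarray:
    """Ellipsoidal structuring element of physical radius, per-axis voxels."""
    r_vox = np.maximum(np.floor(radius_um / np.asarray(spacing)).astype(int), 0)
    if (r_vox == 0).all():
        return np.ones((1, 1, 1), dtype=bool)
    axes = [np.arange(-r, r + 1) * s for r, s in zip(r_vox, spacing)]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij", sparse=True)
    return zz**2 + yy**2 + xx**2 <= radius_um**2


def segment_deposit(
    volume: ImageVolume, params: SegmentationParams | None = None
) -> BinaryMask:
    """Segment the (single) dark deposit in an intensity volume.

    Returns the largest dark 26-connected component after smoothing,
    Otsu thresholding and morphological cleanup, or an *empty* mask when
    no candidate passes the minimum-volume floor and contrast guard.
    Deterministic for fixed inputs.
    """
    params = params or SegmentationParams()
    spacing = np.asarray(volume.spacing, dtype=float)
    if spacing.max() / spacing.min() > params.max_anisotropy:
        raise ValueError(
            f"voxel anisotropy {spacing.max() / spacing.min():.1f} exceeds "
            f"{params.max_anisotropy}; structuring elements degenerate — resample the "
            "volume toward isotropic spacing first"
        )
    data = np.asarray(volume.data, dtype=np.float32)
    empty = BinaryMask(
        np.zeros(volume.shape, dtype=bool), volume.spacing, meta={"segmentation": "empty"}
    )

    def _smooth(sigma_um: float) -> np.ndarray:
        if sigma_um <= 0:
            return data
        return ndimage.gaussian_filter(data, sigma_um / spacing)

    coarse = _smooth(params.detect_sigma_um)
    try:
        thr = threshold_otsu(coarse)
    except ValueError:  # constant image: nothing to separate
        return empty
    detected = coarse < thr
    if not detected.any() or detected.all():
        return empty
    # contrast guard: a genuine deposit is much darker than the tissue;
    # on a deposit-free volume Otsu merely splits the speckle mode in two
    mean_dark = float(coarse[detected].mean())
    mean_bright = float(coarse[~detected].mean())
    if mean_bright <= 0 or mean_dark / mean_bright > params.contrast_ratio_max:
        return empty

    # Boundary refinement: re-threshold a lightly smoothed volume at the
    # midpoint of the deposit/background plateau levels.  The levels are
    # estimated away from the boundary halo (eroded interior, dilated
    # exterior) so the midpoint sits at the true interface.
    refined = _smooth(params.refine_sigma_um)
    halo = _ellipsoid_footprint(2.0 * params.detect_sigma_um, volume.spacing)
    interior = ndimage.binary_erosion(detected, structure=halo)
    exterior = ~ndimage.binary_dilation(detected, structure=halo)
    level_dark = float(refined[interior].mean()) if interior.any() else mean_dark
    level_bright = float(refined[exterior].mean()) if exterior.any() else mean_bright
    dark = refined < 0.5 * (level_dark + level_bright)
    if not dark.any():
        return empty

    if params.morph_radius_um > 0:
        footprint = _ellipsoid_footprint(params.morph_radius_um, volume.spacing)
        dark = ndimage.binary_closing(dark, structure=footprint)
        dark = ndimage.binary_opening(dark, structure=footprint)
    if not dark.any():
        return empty

    candidate = largest_component(
        BinaryMask(dark, volume.spacing), connectivity=26
    )
    if candidate.volume_ul() < params.min_volume_ul:
        return empty
    candidate.meta.update(
        {
            "segmentation": "otsu_dark_refined",
            "detect_sigma_um": params.detect_sigma_um,
            "refine_sigma_um": params.refine_sigma_um,
            "morph_radius_um": params.morph_radius_um,
            "otsu_threshold": float(thr),
            "refine_threshold": 0.5 * (level_dark + level_bright),
            "min_volume_ul": params.min_volume_ul,
        }
    )
    return candidate


def merge_manual_correction(auto: BinaryMask, manual: BinaryMask, mode: str = "replace") -> BinaryMask:
    """Combine an automatic mask with an operator-drawn correction.

    ``mode`` is 'replace' (use the manual mask), 'union' or 'intersection'.
    Provenance (mode and sources) is recorded in the result's metadata.
    """
    auto.check_compatible(manual)
    if mode == "replace":
        data = manual.data.copy()
    elif mode == "union":
        data = auto.data | manual.data
    elif mode == "intersection":
        data = auto.data & manual.data
    else:
        raise ValueError(f"unknown merge mode {mode!r}; use replace/union/intersection")
    return BinaryMask(
        data,
        auto.spacing,
        meta={"correction_mode": mode, "auto_meta": dict(auto.meta), "manual_meta": dict(manual.meta)},
    )


_CONNECTIVITY_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def largest_component(mask: BinaryMask, connectivity: int = 26) -> BinaryMask:
    """Keep only the largest connected component.

    ``connectivity`` is 6, 18 or 26 (face / face+edge / full neighbours).
    Size ties are broken toward the component containing the
    lexicographically smallest voxel index, so the choice is deterministic.
    An empty mask passes through unchanged.
    """
    if connectivity not in _CONNECTIVITY_STRUCTS:
        raise ValueError(f"connectivity must be one of {sorted(_CONNECTIVITY_STRUCTS)}")
    labels, n = ndimage.label(mask.data, structure=_CONNECTIVITY_STRUCTS[connectivity])
    if n == 0:
        return BinaryMask(np.zeros(mask.shape, dtype=bool), mask.spacing, meta=dict(mask.meta))
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    best = np.flatnonzero(sizes == sizes.max()) + 1
    if best.size > 1:
        # tie-break: first label encountered in scan order among the tied ones
        flat = labels.ravel()
        tied = flat[np.isin(flat, best)]
        label = int(tied[0])
    else:
        label = int(best[0])
    return BinaryMask(labels == label, mask.spacing, meta=dict(mask.meta))


def dice_coefficient(a: BinaryMask | np.ndarray, b: BinaryMask | np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); defined as 1.0 for two empty masks."""
    da = a.data if isinstance(a, BinaryMask) else np.asarray(a, dtype=bool)
    db = b.data if isinstance(b, BinaryMask) else np.asarray(b, dtype=bool)
    if da.shape != db.shape:
        raise ValueError(f"shape mismatch: {da.shape} vs {db.shape}")
    total = int(da.sum()) + int(db.sum())
    if total == 0:
        return 1.0
    return 2.0 * int((da & db).sum()) / total
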