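"""Synthetic OCT-like phantoms and longitudinal volume series.

Real dermal OCT volumes of hydrogel deposits show a speckled, scattering
tissue background with an embedded, nearly non-scattering deposit that
appears almost homogeneously dark.  The phantom generator emulates exactly
those features on the study's scan geometry — a 10 mm × 10 mm lateral
field stacked as cross-sectional B-scans — and returns the exact
ground-truth occupancy mask alongside the intensity volume, so that
segmentation and morphometry can be validated without animal data.

What is emulated: deposit/background contrast, fully developed
multiplicative speckle (gamma-distributed with unit mean; contrast = 1
reproduces the exponential intensity law of coherent imaging),
anisotropic voxel spacing, two deposit geometries — a flat ellipsoid
(low-viscosity commercial filler) and a nodular union of overlapping
spherical lobes (the higher-viscosity test hydrogels).  What is *not*
emulated: depth-dependent attenuation, confocal gating, refraction at the
skin surface, and skin-layer anatomy; see docs/methods.md.

Longitudinal volume series follow the trajectory observed in vivo: a
linear swelling ramp up to the peak at ``t_max`` followed by first-order
(exponential) degradation, with multiplicative lognormal measurement
noise.  Only the post-peak exponential form is constrained by the
half-life analysis; the pre-peak ramp is a simulator choice.

The default test grid (64 × 128 × 128) is a downscaled version of the
instrument geometry (512 × 1500 × 1536 voxels over 10 mm × 10 mm); the
full geometry runs through the same code path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .io import BinaryMask, DepositRecord, ImageVolume, Site, Substance
from .kinetics import VolumeSeries

__all__ = [
    "PhantomSpec",
    "KineticsSimSpec",
    "SubstanceKinetics",
    "STUDY_SUBSTANCES",
    "STUDY_TIMEPOINTS",
    "DEFAULT_GRID",
    "DEFAULT_SPACING",
    "generate_phantom",
    "generate_deposit_mask",
    "generate_nodular_mask",
    "simulate_volume_series",
    "simulate_cohort",
    "digitize_ellipsoid",
]

#: Downscaled test grid (depth, slow, fast) and its spacing in µm.  The
#: lateral spacing covers the instrument's 10 mm scan range; the depth
#: extent of the instrument is not tied to a published physical length, so
#: the depth spacing is a free parameter chosen to cover ~2.5 mm of skin.
DEFAULT_GRID = (64, 128, 128)
DEFAULT_SPACING = (50.0, 78.125, 78.125)

#: Measurement schedule in weeks: injection day then follow-ups.
STUDY_TIMEPOINTS = (0.0, 2.0, 4.0, 6.0, 8.0, 10.0, 12.0, 16.0, 20.0, 24.0)


@dataclass(frozen=True)
class PhantomSpec:
    """Specification of one synthetic deposit phantom.

    ``size_params`` is the ellipsoid semi-axes (µm, depth/slow/fast order)
    for ``deposit_kind='flat_ellipsoid'`` and
    ``(n_lobes, lobe_radius_um, scatter_radius_um)`` for ``'nodular'``.
    Intensities are in [0, 1]; ``speckle_contrast`` is the coefficient of
    variation of the multiplicative speckle (1 = fully developed).
    """

    grid_shape: tuple[int, int, int] = DEFAULT_GRID
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    deposit_kind: str = "flat_ellipsoid"
    deposit_center: tuple[float, float, float] | None = None
    size_params: tuple = (500.0, 2500.0, 2500.0)
    background_mean: float = 0.45
    deposit_mean: float = 0.05
    speckle_contrast: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.deposit_kind not in ("flat_ellipsoid", "nodular"):
            raise ValueError(f"unknown deposit_kind {self.deposit_kind!r}")
        if len(self.grid_shape) != 3 or any(int(n) <= 0 for n in self.grid_shape):
            raise ValueError(f"grid_shape must be 3 positive ints, got {self.grid_shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive floats, got {self.spacing}")
        if not (0 <= self.deposit_mean < self.background_mean <= 1):
            raise ValueError(
                "need 0 <= deposit_mean < background_mean <= 1 (deposits are the dark phase); "
                f"got deposit_mean={self.deposit_mean}, background_mean={self.background_mean}"
            )
        if self.speckle_contrast < 0:
            raise ValueError("speckle_contrast must be >= 0")
        if self.deposit_kind == "nodular":
            if len(self.size_params) != 3:
                raise ValueError(
                    "nodular size_params = (n_lobes, lobe_radius_um, scatter_radius_um)"
                )
            n_lobes, lobe_r, scatter_r = self.size_params
            if int(n_lobes) < 1 or lobe_r <= 0 or scatter_r < 0:
                raise ValueError(f"invalid nodular size_params {self.size_params}")
        else:
            if len(self.size_params) != 3 or any(a <= 0 for a in self.size_params):
                raise ValueError("flat_ellipsoid size_params = 3 positive semi-axes in µm")

    @property
    def extent_um(self) -> tuple[float, float, float]:
        return tuple(n * s for n, s in zip(self.grid_shape, self.spacing))  # type: ignore[return-value]

    @property
    def center_um(self) -> tuple[float, float, float]:
        if self.deposit_center is not None:
            return self.deposit_center
        return tuple(e / 2.0 for e in self.extent_um)  # type: ignore[return-value]


def _axis_coords(spec: PhantomSpec) -> list[np.ndarray]:
    """Physical voxel-centre coordinates per axis ((i + 0.5) * spacing)."""
    return [
        (np.arange(n) + 0.5) * s for n, s in zip(spec.grid_shape, spec.spacing)
    ]


def digitize_ellipsoid(
    grid_shape: Sequence[int],
    spacing: Sequence[float],
    center_um: Sequence[float],
    semiaxes_um: Sequence[float],
) -> np.ndarray:
    """Boolean grid of voxels whose centres lie inside the ellipsoid."""
    axes = [(np.arange(n) + 0.5) * s - c for n, s, c in zip(grid_shape, spacing, center_um)]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij", sparse=True)
    a, b, c = semiaxes_um
    return (zz / a) ** 2 + (yy / b) ** 2 + (xx / c) ** 2 <= 1.0


def _check_inside(mask: np.ndarray, spec: PhantomSpec) -> None:
    faces = [mask[0], mask[-1], mask[:, 0], mask[:, -1], mask[:, :, 0], mask[:, :, -1]]
    if any(f.any() for f in faces):
        raise ValueError(
            "deposit touches the grid boundary; enlarge grid_shape or shrink/center the "
            f"deposit (grid extent {spec.extent_um} µm, center {spec.center_um} µm)"
        )
    if not mask.any():
        raise ValueError("deposit lies entirely outside the grid")


def generate_nodular_mask(spec: PhantomSpec, _rng: np.random.Generator | None = None) -> BinaryMask:
    """Ground-truth mask of a nodular deposit: union of overlapping spheres.

    Lobe centres are drawn with the seeded generator uniformly from a ball
    of ``scatter_radius`` around the deposit centre (the first lobe sits at
    the centre itself).  The union must form a single 26-connected
    component; disconnected draws are re-drawn up to 10 times before an
    error is raised.
    """
    if spec.deposit_kind != "nodular":
        raise ValueError("generate_nodular_mask requires deposit_kind='nodular'")
    from scipy import ndimage

    rng = _rng if _rng is not None else np.random.default_rng(spec.seed)
    n_lobes, lobe_r, scatter_r = int(spec.size_params[0]), *spec.size_params[1:]
    center = np.asarray(spec.center_um, dtype=float)
    for _attempt in range(10):
        centers = [center]
        for _ in range(n_lobes - 1):
            # uniform in the scatter ball by rejection
            while True:
                u = rng.uniform(-1.0, 1.0, size=3)
                if u @ u <= 1.0:
                    break
            centers.append(center + u * scatter_r)
        mask = np.zeros(spec.grid_shape, dtype=bool)
        for c in centers:
            mask |= digitize_ellipsoid(spec.grid_shape, spec.spacing, c, (lobe_r,) * 3)
        n_comp = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=bool))[1]
        if n_comp == 1:
            _check_inside(mask, spec)
            return BinaryMask(mask, spec.spacing, meta={"kind": "nodular", "seed": spec.seed})
    raise ValueError(
        "could not draw a 26-connected nodular deposit in 10 attempts; "
        "reduce scatter radius or increase lobe radius"
    )


def generate_deposit_mask(spec: PhantomSpec, _rng: np.random.Generator | None = None) -> BinaryMask:
    """Ground-truth mask for either deposit geometry."""
    if spec.deposit_kind == "nodular":
        return generate_nodular_mask(spec, _rng=_rng)
    mask = digitize_ellipsoid(spec.grid_shape, spec.spacing, spec.center_um, spec.size_params)
    _check_inside(mask, spec)
    return BinaryMask(mask, spec.spacing, meta={"kind": "flat_ellipsoid", "seed": spec.seed})


def generate_phantom(spec: PhantomSpec) -> tuple[ImageVolume, BinaryMask]:
    """Generate an intensity phantom and its exact ground-truth mask.

    The noiseless image is ``deposit_mean`` inside the deposit and
    ``background_mean`` outside; speckle multiplies the whole volume with
    i.i.d. gamma factors of unit mean and CV ``speckle_contrast`` (the
    deposit's residual internal reflectors are speckled too).  Identical
    spec + seed gives bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    mask = generate_deposit_mask(spec, _rng=rng)
    img = np.where(mask.data, np.float32(spec.deposit_mean), np.float32(spec.background_mean))
    if spec.speckle_contrast > 0:
        k = 1.0 / spec.speckle_contrast**2
        speckle = rng.gamma(shape=k, scale=1.0 / k, size=spec.grid_shape).astype(np.float32)
        img = img * speckle
    volume = ImageVolume(
        img.astype(np.float32),
        spec.spacing,
        meta={
            "synthetic": True,
            "deposit_kind": spec.deposit_kind,
            "seed": spec.seed,
            "speckle_contrast": spec.speckle_contrast,
        },
    )
    return volume, mask


# ---------------------------------------------------------------------------
# Longitudinal volume-series simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KineticsSimSpec:
    """Simulated swelling-then-decay trajectory of one deposit.

    Noiseless form: v0·(1 + swell_fraction·t/t_max) for t ≤ t_max, then
    v0·(1 + swell_fraction)·exp(−λ·(t − t_max)); both pieces meet at t_max.
    Multiplicative lognormal noise with coefficient of variation
    ``noise_cv`` (unit mean) is applied per timepoint.
    """

    v0: float = 20.0
    swell_fraction: float = 0.8
    t_max: float = 4.0
    decay_rate: float = math.log(2.0) / 25.0
    timepoints: tuple[float, ...] = STUDY_TIMEPOINTS
    noise_cv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.v0 <= 0:
            raise ValueError("v0 must be positive")
        if self.decay_rate < 0:
            raise ValueError("decay_rate must be >= 0")
        if self.swell_fraction < 0:
            raise ValueError("swell_fraction must be >= 0")
        if self.t_max <= 0:
            raise ValueError("t_max must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        t = np.asarray(self.timepoints, dtype=float)
        if t.size < 1 or t[0] != 0 or np.any(np.diff(t) <= 0):
            raise ValueError("timepoints must be strictly increasing and start at 0")

    def noiseless(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        v_peak = self.v0 * (1.0 + self.swell_fraction)
        ramp = self.v0 * (1.0 + self.swell_fraction * t / self.t_max)
        decay = v_peak * np.exp(-self.decay_rate * (t - self.t_max))
        return np.where(t <= self.t_max, ramp, decay)


def simulate_volume_series(
    spec: KineticsSimSpec, deposit: DepositRecord | None = None
) -> VolumeSeries:
    """Draw one noisy volume series from the swell-then-decay trajectory."""
    rng = np.random.default_rng(spec.seed)
    t = np.asarray(spec.timepoints, dtype=float)
    v = spec.noiseless(t)
    if spec.noise_cv > 0:
        sigma2 = math.log(1.0 + spec.noise_cv**2)
        noise = rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2), size=t.size)
        v = v * noise
    return VolumeSeries(t, v, deposit=deposit)


# ---------------------------------------------------------------------------
# Study-like cohort
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SubstanceKinetics:
    """Group-level generating parameters for one substance.

    Values mirror the in-vivo study conditions: initial volumes of roughly
    12–25 µl after an intended 30 µl injection, peaks 75–95% above
    baseline reached after 3–5 weeks, and half-lifes of 21–32 weeks with
    ~50% between-animal spread.
    """

    v0_mean: float
    v0_sd: float
    swell_fraction: float
    t_max: float
    t_half: float
    t_half_cv: float = 0.5
    swell_cv: float = 0.4

    @property
    def decay_rate(self) -> float:
        return math.log(2.0) / self.t_half


STUDY_SUBSTANCES: dict[Substance, SubstanceKinetics] = {
    Substance.Hydrogel1: SubstanceKinetics(21.2, 4.2, 0.75, 4.6, 27.2),
    Substance.Hydrogel2: SubstanceKinetics(17.7, 3.9, 0.77, 5.0, 31.5),
    Substance.PRV: SubstanceKinetics(20.1, 6.4, 0.95, 3.3, 21.4),
}

_COHORT_SITES = (Site.A_left_cranial, Site.B_right_cranial, Site.C_left_caudal, Site.D_right_caudal)


def simulate_cohort(
    seed: int = 0,
    n_mice: int = 22,
    substances: dict[Substance, SubstanceKinetics] | None = None,
    timepoints: Sequence[float] = STUDY_TIMEPOINTS,
    noise_cv: float = 0.05,
) -> tuple[list[VolumeSeries], pd.DataFrame]:
    """Simulate a study-like cohort of longitudinal volume series.

    Each mouse receives one deposit per substance at a randomized dorsal
    site.  Per-deposit parameters are drawn around the group values:
    lognormal half-life (CV ``t_half_cv``), truncated-normal baseline
    volume and swell fraction.  Returns the series plus a ground-truth
    table with the per-deposit generating parameters.
    """
    subs = substances if substances is not None else STUDY_SUBSTANCES
    rng = np.random.default_rng(seed)
    series_list: list[VolumeSeries] = []
    truth_rows = []
    for i in range(n_mice):
        animal = f"m{i + 1:02d}"
        site_order = rng.permutation(len(_COHORT_SITES))
        for j, (substance, g) in enumerate(subs.items()):
            site = _COHORT_SITES[site_order[j]]
            v0 = float(np.clip(rng.normal(g.v0_mean, g.v0_sd), 0.3 * g.v0_mean, None))
            swell = float(np.clip(rng.normal(g.swell_fraction, g.swell_cv * g.swell_fraction),
                                  0.1, None))
            sigma2 = math.log(1.0 + g.t_half_cv**2)
            t_half = float(g.t_half * rng.lognormal(-sigma2 / 2.0, math.sqrt(sigma2)))
            lam = math.log(2.0) / t_half
            spec = KineticsSimSpec(
                v0=v0,
                swell_fraction=swell,
                t_max=g.t_max,
                decay_rate=lam,
                timepoints=tuple(timepoints),
                noise_cv=noise_cv,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            record = DepositRecord(animal, site, substance, None)
            series_list.append(simulate_volume_series(spec, deposit=record))
            truth_rows.append(
                {
                    "animal_id": animal,
                    "site": site.value,
                    "substance": substance.value,
                    "v0_true": v0,
                    "swell_fraction_true": swell,
                    "t_max_true": g.t_max,
                    "decay_rate_true": lam,
                    "t_half_true": t_half,
                }
            )
    return series_list, pd.DataFrame(truth_rows)


def phantom_spec_for_volume(target_ul: float, base: PhantomSpec | None = None) -> PhantomSpec:
    """Scale a phantom spec homothetically so its mask volume hits a target.

    All deposit lengths scale by the cube root of the volume ratio (for
    nodular deposits the seeded lobe directions are unchanged, so the
    shape merely rescales).  Accurate to digitization error (<~1% for
    deposits tens of voxels across); raises if the scaled deposit no
    longer fits the grid.
    """
    if target_ul <= 0:
        raise ValueError("target volume must be positive")
    base = base if base is not None else PhantomSpec()
    v_base = generate_deposit_mask(base).volume_ul()
    f = (target_ul / v_base) ** (1.0 / 3.0)
    if base.deposit_kind == "nodular":
        n, lobe_r, scatter_r = base.size_params
        size = (n, lobe_r * f, scatter_r * f)
    else:
        size = tuple(a * f for a in base.size_params)
    spec = replace(base, size_params=size)
    generate_deposit_mask(spec)  # bounds check at the new size
    return spec


def cohort_measurements_table(series_list: Sequence[VolumeSeries]) -> pd.DataFrame:
    """Arrange simulated volume series in the per-deposit measurement schema.

    Surface area and sphericity are NaN — the series simulator models
    volumes only; image-derived tables fill every column.
    """
    rows = []
    for s in series_list:
        if s.deposit is None:
            raise ValueError("series must carry DepositRecord identities")
        for t, v in zip(s.times, s.volumes):
            rows.append(
                {
                    "animal_id": s.deposit.animal_id,
                    "site": s.deposit.site.value,
                    "substance": s.deposit.substance.value,
                    "week": float(t),
                    "volume_ul": float(v),
                    "surface_mm2": np.nan,
                    "sphericity": np.nan,
                    "centroid_depth_um": np.nan,
                    "centroid_slow_um": np.nan,
                    "centroid_fast_um": np.nan,
                    "estimator": "simulated",
                }
            )
    return pd.DataFrame(rows)
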