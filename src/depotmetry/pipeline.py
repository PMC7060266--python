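"""Study-level pipeline: volumes → masks → morphometry → kinetics → stats.

A configuration (dict or YAML file) lists, per (animal, site, week), either
an intensity volume to segment or a precomputed/corrected mask, plus the
substance assignment.  Alternatively a measurements CSV produced earlier
(or by another tool) can be fed in directly, skipping the imaging stages.
The pipeline emits

* ``measurements``   — per deposit and week: volume (µl), surface (mm²),
  sphericity, centroid;
* ``kinetics``       — per deposit: V0, V_max, T_max, V_increase,
  V_max_rel, decay rate, T_1/2, fit diagnostics;
* ``group_summary``  — per substance: mean ± SD of each kinetic parameter;
* ``pairwise_half_life`` — ANOVA + Tukey HSD on the half-lifes;
* ``sphericity_by_week`` — per substance and week: mean ± SD sphericity,
  with the per-week ANOVA p-value across substances.

Everything is deterministic given the inputs; reruns write byte-identical
CSVs.  Deposits without a week-0 (baseline) measurement or with fewer
than three post-peak points are skipped from kinetics with a logged
reason, never silently.

Example configuration::

    spacing_um: [50, 78.125, 78.125]   # fallback when file headers lack units
    refractive_index: 1.4              # optional depth correction
    estimator: weighted_config
    segmentation: {detect_sigma_um: 150, min_volume_ul: 0.5}
    inputs:
      - {animal_id: m01, site: A_left_cranial, substance: Hydrogel1,
         week: 0, volume: m01_A_w00.tif}
      - {animal_id: m01, site: A_left_cranial, substance: Hydrogel1,
         week: 2, mask: m01_A_w02_corrected.nii}
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import io as dio
from .io import DepositRecord, Site, Substance
from .kinetics import (
    KineticsResult,
    UnderdeterminedFitError,
    VolumeSeries,
    fit_half_life,
    summarize_group,
)
from .morphometry import measure
from .segmentation import SegmentationParams, merge_manual_correction, segment_deposit
from .stats import anova_tukey

__all__ = ["StudyReport", "run_pipeline", "load_config"]

REPORT_FILES = {
    "measurements": "deposit_measurements.csv",
    "kinetics": "kinetics.csv",
    "group_summary": "group_summary.csv",
    "pairwise_half_life": "pairwise_half_life.csv",
    "sphericity_by_week": "sphericity_by_week.csv",
}


@dataclass
class StudyReport:
    """All tables produced by one pipeline run, plus the processing log."""

    measurements: pd.DataFrame
    kinetics: pd.DataFrame
    group_summary: pd.DataFrame
    pairwise_half_life: pd.DataFrame
    sphericity_by_week: pd.DataFrame
    config: dict
    logs: list[str] = field(default_factory=list)

    def write(self, out_dir: str | Path, plots: bool = False) -> dict[str, Path]:
        """Write every table as CSV (byte-identical across reruns)."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        for attr, fname in REPORT_FILES.items():
            df: pd.DataFrame = getattr(self, attr)
            p = out / fname
            df.to_csv(p, index=isinstance(df.index, pd.MultiIndex) or df.index.name is not None,
                      float_format="%.10g")
            paths[attr] = p
        log_path = out / "pipeline_log.txt"
        log_path.write_text("\n".join(self.logs) + "\n")
        paths["log"] = log_path
        if plots:
            from .plotting import plot_sphericity_course, plot_volume_course

            for name, fn in (("volume_vs_time", plot_volume_course),
                             ("sphericity_vs_time", plot_sphericity_course)):
                fig = fn(self.measurements)
                p = out / f"{name}.png"
                fig.savefig(p, dpi=120)
                paths[name] = p
        return paths


def load_config(config: str | Path | Mapping[str, Any]) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            cfg = yaml.safe_load(fh)
        if not isinstance(cfg, dict):
            raise ValueError(f"configuration file {config} must hold a mapping")
        cfg.setdefault("_base_dir", str(Path(config).parent))
        return cfg
    return dict(config)


def _resolve(path: str, cfg: dict) -> Path:
    p = Path(path)
    if not p.is_absolute() and "_base_dir" in cfg:
        p = Path(cfg["_base_dir"]) / p
    return p


def _measure_inputs(cfg: dict, logs: list[str]) -> pd.DataFrame:
    spacing = cfg.get("spacing_um")
    estimator = cfg.get("estimator", "weighted_config")
    seg_params = SegmentationParams(**cfg.get("segmentation", {}))
    n_tissue = cfg.get("refractive_index")
    records: list[tuple[DepositRecord, Any]] = []
    for entry in cfg["inputs"]:
        rec = DepositRecord(
            str(entry["animal_id"]), Site(entry["site"]), Substance(entry["substance"]),
            float(entry["week"]),
        )
        where = f"(animal={rec.animal_id}, site={rec.site.value}, week={rec.timepoint:g})"
        try:
            if "mask" in entry:
                mask = dio.read_mask(_resolve(entry["mask"], cfg), spacing_override=spacing)
            elif "volume" in entry:
                vol = dio.read_volume(_resolve(entry["volume"], cfg), spacing_override=spacing)
                if n_tissue is not None:
                    vol = dio.apply_refractive_correction(vol, float(n_tissue))
                mask = segment_deposit(vol, seg_params)
                if "manual" in entry:
                    manual = dio.read_mask(_resolve(entry["manual"], cfg), spacing_override=spacing)
                    mask = merge_manual_correction(mask, manual, entry.get("mode", "replace"))
                    logs.append(f"manual correction ({entry.get('mode', 'replace')}) applied {where}")
            else:
                raise ValueError(f"input entry needs a 'volume' or 'mask' path {where}")
        except FileNotFoundError as exc:
            raise FileNotFoundError(f"missing input file {exc} for entry {where}") from exc
        if not mask.data.any():
            logs.append(f"no deposit found {where}; recorded as empty")
        records.append((rec, measure(mask, estimator=estimator)))
        logs.append(f"measured {where}: V={records[-1][1].volume_ul:.4g} ul")
    rows = []
    for rec, morph in records:
        cz, cy, cx = morph.centroid_um if morph.centroid_um else (np.nan,) * 3
        rows.append({
            "animal_id": rec.animal_id, "site": rec.site.value,
            "substance": rec.substance.value, "week": rec.timepoint,
            "volume_ul": morph.volume_ul, "surface_mm2": morph.surface_mm2,
            "sphericity": morph.sphericity, "centroid_depth_um": cz,
            "centroid_slow_um": cy, "centroid_fast_um": cx, "estimator": morph.estimator,
        })
    df = pd.DataFrame(rows, columns=dio.MEASUREMENT_COLUMNS)
    keys = list(zip(df["animal_id"], df["site"], df["week"]))
    if len(keys) != len(set(keys)):
        raise ValueError("duplicate (animal, site, week) entries in inputs")
    return df


def _series_from_measurements(df: pd.DataFrame, logs: list[str]) -> list[VolumeSeries]:
    series = []
    for (animal, site, substance), grp in df.groupby(["animal_id", "site", "substance"], sort=True):
        grp = grp.sort_values("week")
        ident = f"(animal={animal}, site={site})"
        usable = grp[grp["volume_ul"] > 0]
        dropped = len(grp) - len(usable)
        if dropped:
            logs.append(f"{ident}: dropped {dropped} empty/zero-volume timepoints")
        if len(usable) < 3:
            logs.append(f"{ident}: skipped kinetics — fewer than 3 usable timepoints")
            continue
        if usable["week"].iloc[0] != 0:
            logs.append(f"{ident}: skipped kinetics — no baseline (week 0) measurement")
            continue
        rec = DepositRecord(animal, Site(site), Substance(substance), None)
        series.append(VolumeSeries(usable["week"].to_numpy(), usable["volume_ul"].to_numpy(),
                                   deposit=rec))
    return series


def _sphericity_by_week(df: pd.DataFrame, alpha: float, logs: list[str]) -> pd.DataFrame:
    rows = []
    for week, wgrp in df.dropna(subset=["sphericity"]).groupby("week", sort=True):
        by_sub = {s: g["sphericity"].to_numpy() for s, g in wgrp.groupby("substance")}
        p_anova = np.nan
        if len(by_sub) >= 2 and all(v.size >= 2 for v in by_sub.values()):
            try:
                p_anova = anova_tukey(by_sub, alpha=alpha).p_anova
            except ValueError as exc:
                logs.append(f"week {week:g}: sphericity ANOVA skipped ({exc})")
        for sub, vals in sorted(by_sub.items()):
            rows.append({
                "week": week, "substance": sub, "n": vals.size,
                "sphericity_mean": float(vals.mean()),
                "sphericity_sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                "p_anova_week": p_anova,
            })
    return pd.DataFrame(rows)


def run_pipeline(config: str | Path | Mapping[str, Any]) -> StudyReport:
    """Execute the full analysis described by ``config``; see module docs."""
    cfg = load_config(config)
    logs: list[str] = [f"pipeline config: { {k: v for k, v in sorted(cfg.items()) if k != '_base_dir'} }"]
    alpha = float(cfg.get("alpha", 0.05))

    if "inputs" in cfg:
        measurements = _measure_inputs(cfg, logs)
    elif "measurements" in cfg:
        measurements = dio.read_measurements(_resolve(cfg["measurements"], cfg))
        logs.append(f"loaded {len(measurements)} measurements from {cfg['measurements']}")
    else:
        raise ValueError("config needs either 'inputs' (volumes/masks) or 'measurements' (CSV)")

    series = _series_from_measurements(measurements, logs)
    fit_kwargs = {"fix_peak": bool(cfg.get("fix_peak", False)),
                  "method": cfg.get("fit_method", "loglinear")}
    results: list[KineticsResult] = []
    for s in series:
        try:
            results.append(fit_half_life(s, **fit_kwargs))
        except UnderdeterminedFitError as exc:
            d = s.deposit
            logs.append(f"(animal={d.animal_id}, site={d.site.value}): kinetics fit skipped — {exc}")
    kinetics_df = pd.DataFrame([r.as_dict() for r in results])

    if results:
        group_summary = summarize_group(results)
        n_censored = int(sum(r.censored for r in results))
        if n_censored:
            logs.append(f"{n_censored} censored half-life(s) excluded from group means")
    else:
        group_summary = pd.DataFrame()
        logs.append("no kinetics results; group summary empty")

    by_sub = {
        sub: [r.t_half for r in results
              if r.deposit.substance.value == sub and np.isfinite(r.t_half)]
        for sub in sorted({r.deposit.substance.value for r in results})
    }
    by_sub = {k: v for k, v in by_sub.items() if len(v) >= 2}
    if len(by_sub) >= 2:
        pairwise = anova_tukey(by_sub, alpha=alpha).pairwise
    else:
        pairwise = pd.DataFrame(columns=["group1", "group2", "mean_diff", "p_tukey", "significant"])
        logs.append("half-life comparison skipped: need >=2 groups with >=2 uncensored fits")

    sph = _sphericity_by_week(measurements, alpha, logs)
    return StudyReport(
        measurements=measurements,
        kinetics=kinetics_df,
        group_summary=group_summary,
        pairwise_half_life=pairwise,
        sphericity_by_week=sph,
        config={k: v for k, v in cfg.items() if k != "_base_dir"},
        logs=logs,
    )
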