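"""Per-deposit longitudinal volume analysis: swelling peak and decay half-life.

Injected hydrogel deposits swell during the first weeks after injection
(water uptake) and are degraded steadily afterwards.  The longitudinal
summary computed per deposit is:

* ``v0`` — volume at the injection-day measurement (t = 0), µl
* ``v_max``, ``t_max`` — observed peak volume and its timepoint
* ``v_increase`` = v_max − v0 (µl); ``v_max_rel`` = 100·v_max/v0 (%)
* ``decay_rate`` λ (per week) from an exponential fit V(t) = V̂·exp(−λ(t−t_max))
  to the measurements at t ≥ t_max, and the half-life t_half = ln 2 / λ —
  the time from the peak to half of the peak volume.

The fit is ordinary least squares on log-volumes (deterministic and
closed-form; adequate at the few-percent measurement noise typical for the
volumetry), with an optional nonlinear refinement.  By default the peak
amplitude is re-estimated as a free intercept in log space; ``fix_peak=True``
anchors the curve exactly at the observed (t_max, v_max).  A non-decaying
tail (λ ≤ 0) yields a *censored* result with an infinite half-life — never
a negative one.

The module follows the Model/Results idiom: build an
:class:`ExponentialDecayModel` from a :class:`VolumeSeries`, call
``fit()``, get a :class:`KineticsResult` with estimates, diagnostics and a
``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import DepositRecord

__all__ = [
    "VolumeSeries",
    "ExponentialDecayModel",
    "KineticsResult",
    "UnderdeterminedFitError",
    "locate_maximum",
    "fit_half_life",
    "summarize_group",
    "KINETIC_PARAMETERS",
]

#: Parameters summarized per substance group, in reporting order.
KINETIC_PARAMETERS = ("v0", "v_increase", "v_max", "v_max_rel", "t_max", "t_half")


class UnderdeterminedFitError(ValueError):
    """Fewer than three usable points at or after the volume peak."""


@dataclass
class VolumeSeries:
    """One deposit's (time, volume) trajectory in weeks and µl.

    Times must be non-negative and strictly increasing; volumes must be
    positive (log-volumes are fitted).  Baseline quantities (v0,
    v_max_rel, v_increase) refer to the series' first timepoint; whether
    that first point really is the week-0 (injection-day) measurement is
    reported by :attr:`has_baseline` and enforced where it matters (the
    study pipeline skips kinetics for deposits without a baseline).
    """

    times: np.ndarray
    volumes: np.ndarray
    deposit: DepositRecord | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.volumes = np.asarray(self.volumes, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.volumes.shape:
            raise ValueError("times and volumes must be 1-D arrays of equal length")
        if self.times.size == 0:
            raise ValueError("empty volume series")
        if self.times[0] < 0:
            raise ValueError(f"times must be non-negative, got t0={self.times[0]}")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(~np.isfinite(self.volumes)) or np.any(self.volumes <= 0):
            raise ValueError("volumes must be positive and finite (log-volumes are fitted)")

    @property
    def has_baseline(self) -> bool:
        """True when the series starts at the injection-day measurement."""
        return self.times[0] == 0

    def __len__(self) -> int:
        return self.times.size


def locate_maximum(series: VolumeSeries) -> tuple[float, float]:
    """Observed (t_max, v_max); the earliest timepoint wins ties."""
    i = int(np.argmax(series.volumes))  # argmax returns the first maximum
    return float(series.times[i]), float(series.volumes[i])


@dataclass(frozen=True)
class KineticsResult:
    """Estimates and diagnostics of one deposit's volume kinetics."""

    v0: float
    v_max: float
    t_max: float
    v_increase: float
    v_max_rel: float
    decay_rate: float
    t_half: float
    v_max_hat: float
    fit_r2: float
    n_fit_points: int
    censored: bool
    method: str
    deposit: DepositRecord | None = None

    def as_dict(self) -> dict:
        d = {
            "v0": self.v0,
            "v_max": self.v_max,
            "t_max": self.t_max,
            "v_increase": self.v_increase,
            "v_max_rel": self.v_max_rel,
            "decay_rate": self.decay_rate,
            "t_half": self.t_half,
            "v_max_hat": self.v_max_hat,
            "fit_r2": self.fit_r2,
            "n_fit_points": self.n_fit_points,
            "censored": self.censored,
            "method": self.method,
        }
        if self.deposit is not None:
            d = {
                "animal_id": self.deposit.animal_id,
                "site": self.deposit.site.value,
                "substance": self.deposit.substance.value,
                **d,
            }
        return d

    def summary(self) -> str:
        """Human-readable fit report."""
        lines = ["Deposit volume kinetics", "=" * 43]
        if self.deposit is not None:
            lines.append(
                f"deposit: {self.deposit.animal_id} / {self.deposit.site.value} "
                f"/ {self.deposit.substance.value}"
            )
        rows = [
            ("V0 (ul)", f"{self.v0:.2f}"),
            ("V_max (ul)", f"{self.v_max:.2f}"),
            ("T_max (weeks)", f"{self.t_max:.1f}"),
            ("V_increase (ul)", f"{self.v_increase:.2f}"),
            ("V_max_rel (%)", f"{self.v_max_rel:.1f}"),
            ("decay rate (1/week)", f"{self.decay_rate:.5f}"),
            ("T_1/2 (weeks)", f"{self.t_half:.2f}" if np.isfinite(self.t_half) else "inf"),
            ("fit R2 (log scale)", f"{self.fit_r2:.4f}"),
            ("fit points", str(self.n_fit_points)),
            ("censored", str(self.censored)),
            ("method", self.method),
        ]
        lines += [f"{k:<22}{v:>21}" for k, v in rows]
        return "\n".join(lines)


class ExponentialDecayModel:
    """Exponential post-peak decay model for one deposit's volume series.

    Parameters
    ----------
    series
        The deposit's longitudinal (weeks, µl) measurements.
    fix_peak
        If True, anchor the decay curve at the observed (t_max, v_max)
        instead of estimating the log-space intercept.
    """

    def __init__(self, series: VolumeSeries, fix_peak: bool = False) -> None:
        self.series = series
        self.fix_peak = fix_peak
        self.t_max, self.v_max = locate_maximum(series)
        tail = series.times >= self.t_max
        self.tail_times = series.times[tail] - self.t_max
        self.tail_volumes = series.volumes[tail]

    def _censored_result(self, method: str) -> KineticsResult:
        v0 = float(self.series.volumes[0])
        return KineticsResult(
            v0=v0,
            v_max=self.v_max,
            t_max=self.t_max,
            v_increase=self.v_max - v0,
            v_max_rel=100.0 * self.v_max / v0,
            decay_rate=0.0,
            t_half=float("inf"),
            v_max_hat=self.v_max,
            fit_r2=float("nan"),
            n_fit_points=int(self.tail_times.size),
            censored=True,
            method=method + ("+fixed_peak" if self.fix_peak else ""),
            deposit=self.series.deposit,
        )

    def fit(self, method: str = "loglinear") -> KineticsResult:
        """Fit the decay; ``method`` is 'loglinear' or 'nonlinear'.

        The nonlinear option refines the log-linear solution by least
        squares on the volume scale (Levenberg–Marquardt).
        """
        if method not in ("loglinear", "nonlinear"):
            raise ValueError(f"unknown fit method {method!r}")
        t, v = self.tail_times, self.tail_volumes
        if t.size < 3:
            if self.t_max == self.series.times[-1]:
                # the deposit never started decaying within the study window:
                # a censored observation, not a fit failure
                return self._censored_result(method)
            raise UnderdeterminedFitError(
                f"need >= 3 points at t >= t_max for the exponential fit, have {t.size}"
            )
        logv = np.log(v)
        if self.fix_peak:
            denom = float(t @ t)
            slope = float(t @ (logv - np.log(self.v_max))) / denom
            intercept = float(np.log(self.v_max))
        else:
            slope, intercept = np.polyfit(t, logv, 1)
        lam = -float(slope)
        v_max_hat = float(np.exp(intercept))

        if method == "nonlinear" and lam > 0:
            from scipy.optimize import curve_fit

            def _decay(tt, vm, ll):
                return vm * np.exp(-ll * tt)

            try:
                if self.fix_peak:
                    popt, _ = curve_fit(
                        lambda tt, ll: _decay(tt, self.v_max, ll), t, v, p0=[lam]
                    )
                    lam = float(popt[0])
                else:
                    popt, _ = curve_fit(_decay, t, v, p0=[v_max_hat, lam])
                    v_max_hat, lam = float(popt[0]), float(popt[1])
            except RuntimeError:
                pass  # keep the closed-form log-linear solution

        fitted = np.log(v_max_hat) - lam * t
        ss_res = float(np.sum((logv - fitted) ** 2))
        ss_tot = float(np.sum((logv - logv.mean()) ** 2))
        fit_r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0

        # numerical zero: a flat tail fits slope ~1e-17, which is no decay
        censored = not (lam > 1e-12)
        t_half = float(np.log(2.0) / lam) if not censored else float("inf")

        v0 = float(self.series.volumes[0])
        return KineticsResult(
            v0=v0,
            v_max=self.v_max,
            t_max=self.t_max,
            v_increase=self.v_max - v0,
            v_max_rel=100.0 * self.v_max / v0,
            decay_rate=lam,
            t_half=t_half,
            v_max_hat=v_max_hat,
            fit_r2=fit_r2,
            n_fit_points=int(t.size),
            censored=censored,
            method=method + ("+fixed_peak" if self.fix_peak else ""),
            deposit=self.series.deposit,
        )


def fit_half_life(series: VolumeSeries, fix_peak: bool = False, method: str = "loglinear") -> KineticsResult:
    """Convenience wrapper: build the decay model and fit it."""
    return ExponentialDecayModel(series, fix_peak=fix_peak).fit(method=method)


def summarize_group(
    results: Iterable[KineticsResult],
    parameters: Sequence[str] = KINETIC_PARAMETERS,
) -> pd.DataFrame:
    """Per-substance mean ± SD of the kinetic parameters.

    Relative quantities (v_max_rel) are averaged per deposit (mean of
    ratios), so a group mean can exceed the ratio of group-mean volumes.
    Censored half-lifes are excluded from the t_half mean/SD and counted in
    ``n_censored``.  SD is the sample SD (ddof = 1); a single value yields
    SD = 0 by convention.
    """
    results = list(results)
    if not results:
        raise ValueError("no kinetics results to summarize")
    rows = []
    by_substance: dict[str, list[KineticsResult]] = {}
    for r in results:
        if r.deposit is None:
            raise ValueError("summarize_group needs results carrying a DepositRecord")
        by_substance.setdefault(r.deposit.substance.value, []).append(r)

    def _mean_sd(vals: np.ndarray) -> tuple[float, float]:
        if vals.size == 0:
            return float("nan"), float("nan")
        return float(vals.mean()), float(vals.std(ddof=1)) if vals.size > 1 else 0.0

    for substance in sorted(by_substance):
        grp = by_substance[substance]
        row: dict[str, object] = {"substance": substance, "n": len(grp)}
        for p in parameters:
            vals = np.array([getattr(r, p) for r in grp], dtype=float)
            if p == "t_half":
                vals = vals[np.isfinite(vals)]
            m, sd = _mean_sd(vals)
            row[f"{p}_mean"] = m
            row[f"{p}_sd"] = sd
        row["n_censored"] = sum(r.censored for r in grp)
        rows.append(row)
    return pd.DataFrame(rows).set_index("substance")
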