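"""Longitudinal course plots: volume and sphericity vs time per substance."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_volume_course", "plot_sphericity_course", "plot_series"]


def _course(df: pd.DataFrame, column: str, ylabel: str, ax=None):
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for substance, grp in df.dropna(subset=[column]).groupby("substance"):
        agg = grp.groupby("week")[column].agg(["mean", "std", "count"])
        sd = agg["std"].fillna(0.0)
        ax.errorbar(agg.index, agg["mean"], yerr=sd, marker="o", capsize=3, label=substance)
    ax.set_xlabel("time after injection (weeks)")
    ax.set_ylabel(ylabel)
    if ax.get_legend_handles_labels()[0]:
        ax.legend()
    ax.figure.tight_layout()
    return ax.figure


def plot_volume_course(measurements: pd.DataFrame, ax=None):
    """Mean ± SD deposit volume (µl) over time, one line per substance."""
    return _course(measurements, "volume_ul", "deposit volume (µl)", ax=ax)


def plot_sphericity_course(measurements: pd.DataFrame, ax=None):
    """Mean ± SD sphericity over time, one line per substance."""
    return _course(measurements, "sphericity", "sphericity S", ax=ax)


def plot_series(series, result=None, ax=None):
    """One deposit's volume series, optionally with its fitted decay curve."""
    import numpy as np

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ax.plot(series.times, series.volumes, "o", label="measured")
    if result is not None and np.isfinite(result.t_half):
        t = np.linspace(result.t_max, series.times[-1], 100)
        ax.plot(t, result.v_max_hat * np.exp(-result.decay_rate * (t - result.t_max)),
                "-", label=f"fit: T_1/2 = {result.t_half:.1f} wk")
    ax.set_xlabel("time after injection (weeks)")
    ax.set_ylabel("deposit volume (µl)")
    ax.legend()
    ax.figure.tight_layout()
    return ax.figure
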