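"""QC and result figures: predicted-vs-actual scatters and the window-scan bars."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np

from .predictor import NestedLOOCVResults
from .scan import WindowScanResult


def plot_prediction_scatter(result: NestedLOOCVResults, ax=None, title: str | None = None):
    """Scatter of out-of-fold predicted vs actual target with r and P."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(result.actual, result.fittedvalues, s=25, color="k", alpha=0.7)
    lo = min(result.actual.min(), result.fittedvalues.min())
    hi = max(result.actual.max(), result.fittedvalues.max())
    ax.plot([lo, hi], [lo, hi], ls="--", lw=0.8, color="grey")
    ax.set_xlabel("actual")
    ax.set_ylabel("predicted (out-of-fold)")
    ax.set_title(title or f"r = {result.pearson_r:.2f}, P = {result.p_value:.2g}")
    return ax


def plot_window_scan(scan: WindowScanResult, ax=None):
    """Per-window correlation bars; dark-phase windows shaded, FDR hits starred."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    windows = scan.table.index.to_numpy()
    r = scan.table["r"].to_numpy()
    colors = ["0.2" if ph == "dark" else "0.7" for ph in scan.table["phase"]]
    ax.bar(windows, r, color=colors)
    for w in scan.significant_windows():
        ax.annotate("*", (w, scan.table.loc[w, "r"]), ha="center", fontsize=14)
    ax.set_xlabel("3 h window (1 = closest to sampling)")
    ax.set_ylabel("Pearson r (actual vs predicted)")
    ax.axhline(0, lw=0.5, color="k")
    return ax


def plot_trace(trace, ax=None):
    """Daily-total actogram-style QC line for one mouse."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 2.5))
    bins_per_day = int(round(24.0 / trace.bin_hours))
    n_days = int(trace.duration_days)
    daily = trace.distances[: n_days * bins_per_day].reshape(n_days, bins_per_day).sum(axis=1)
    ax.plot(np.arange(n_days), daily / 100.0, color="k", lw=1)
    ax.set_xlabel("day")
    ax.set_ylabel("distance (m/day)")
    ax.set_title(trace.mouse_id)
    return ax
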