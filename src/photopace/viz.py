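"""Plot helpers (imported lazily by the CLI and the analysis drivers)."""

from __future__ import annotations

import numpy as np

from .types import ActivationMap, OrientationSummary, StressTrace

__all__ = ["plot_stress_trace", "plot_isochrones", "plot_orientation_histogram"]


def _axes():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def plot_stress_trace(trace: StressTrace, path, peaks=None) -> None:
    plt = _axes()
    fig, ax = plt.subplots(figsize=(8, 3))
    ax.plot(trace.times, trace.stress / 1e3, lw=0.8)
    if peaks is not None:
        ax.plot(peaks, np.interp(peaks, trace.times, trace.stress) / 1e3, "rv", ms=4)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("film stress (kPa)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_isochrones(amap: ActivationMap, path, n_levels: int = 12) -> None:
    plt = _axes()
    T = np.where(amap.valid, amap.T, np.nan)
    fig, ax = plt.subplots(figsize=(5, 3))
    im = ax.imshow(1e3 * (T - np.nanmin(T)), cmap="viridis")
    ax.contour(1e3 * (T - np.nanmin(T)), levels=n_levels, colors="w", linewidths=0.5)
    fig.colorbar(im, ax=ax, label="activation time (ms)")
    ax.set_xticks([])
    ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_orientation_histogram(summary: OrientationSummary, path) -> None:
    plt = _axes()
    fig, ax = plt.subplots(figsize=(4, 3))
    centers = 0.5 * (summary.bin_edges[:-1] + summary.bin_edges[1:])
    ax.bar(centers, summary.counts, width=9.0, color="0.4")
    if summary.mean_defined:
        ax.axvline(summary.mean_angle, color="r", lw=1)
    ax.set_xlabel("nuclear orientation (deg)")
    ax.set_ylabel("count")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
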