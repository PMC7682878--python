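"""Figure helpers (PNG output; Agg backend, safe for headless use)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .flow import LogTable, SlopeFit
from .imaging import ConditionSummary

__all__ = ["plot_slope_fit", "plot_condition_histograms", "plot_slope_theory"]


def plot_slope_fit(table: LogTable, fit: SlopeFit, path: str | Path, title: str = "") -> None:
    """Scatter of log10 green vs log10 blue with the fitted line."""
    fig, ax = plt.subplots(figsize=(4.5, 4))
    x = table.data["log_blue"].to_numpy()
    y = table.data["log_green"].to_numpy()
    ax.plot(x, y, ".", ms=1.5, alpha=0.3, rasterized=True)
    if len(x):
        xs = np.linspace(x.min(), x.max(), 10)
        ax.plot(xs, fit.raw_intercept + fit.raw_slope * xs, "r-", lw=1.5,
                label=f"raw {fit.raw_slope:.2f} / rescaled {fit.rescaled_slope:.2f}")
        ax.legend(frameon=False, fontsize=8)
    ax.set_xlabel("log10 blue (expression reporter)")
    ax.set_ylabel("log10 green (complemented)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_condition_histograms(
    summaries: dict[str, ConditionSummary], path: str | Path
) -> None:
    """Replicate-averaged intensity histograms with sd bands per condition."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for name, s in summaries.items():
        centers = 0.5 * (s.bin_edges[:-1] + s.bin_edges[1:])
        ax.plot(centers, s.hist_mean, label=name)
        ax.fill_between(
            centers, s.hist_mean - s.hist_sd, s.hist_mean + s.hist_sd, alpha=0.25
        )
    ax.set_xlabel("per-cell median intensity (counts)")
    ax.set_ylabel("density (mean over replicates)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_slope_theory(kd: np.ndarray, slopes: np.ndarray, path: str | Path) -> None:
    """Predicted log-log slope as a function of the dissociation constant."""
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    ax.semilogx(kd, slopes, "-o", ms=3)
    ax.axhline(1.0, color="gray", ls=":", lw=1)
    ax.axhline(2.0, color="gray", ls=":", lw=1)
    ax.set_xlabel("effective $K_D$ (concentration units)")
    ax.set_ylabel("predicted log-log slope")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
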