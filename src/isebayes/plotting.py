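"""Publication-style figures for datasets and fitted results."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

__all__ = ["plot_dataset", "plot_activities", "plot_characterisation"]


def plot_dataset(dataset, path=None):
    """Calibration points per sensor (emf vs log10 activity)."""
    fig, ax = plt.subplots(figsize=(6, 4))
    cal = dataset.calibration_frame()
    for i, grp in cal.groupby("ISEID"):
        ax.plot(grp.log10x, grp.emf, "o-", label=f"ISE #{int(i)}", alpha=0.8)
    ax.set_xlabel("log10 activity")
    ax.set_ylabel("emf (mV)")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig, ax


def plot_activities(results, path=None, ylab="log10 activity", ylim=None,
                    color="steelblue"):
    """Per-sample posterior intervals: thin 95% and thick 50% vertical bars
    with a dash at the median."""
    fig, ax = plt.subplots(figsize=(7, 4))
    for j in results.sample_ids:
        s = results.activity(j)
        ax.vlines(j, s.lower95, s.upper95, color=color, lw=1)
        ax.vlines(j, s.lower50, s.upper50, color=color, lw=3.5)
        ax.plot(j, s.median, marker="_", ms=10, color=color, mew=2)
    ax.set_xlabel("Sample")
    ax.set_ylabel(ylab)
    ax.set_xticks(results.sample_ids)
    if ylim is not None:
        ax.set_ylim(*ylim)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig, ax


def plot_characterisation(results, path=None):
    """Posterior histograms of a, b, c, sigma and log10 LOD per sensor."""
    names = ["a", "b", "c", "sigma", "logLOD"]
    n = results.n_ise
    fig, axes = plt.subplots(n, len(names), figsize=(3 * len(names), 2.2 * n),
                             squeeze=False)
    for row, i in enumerate(range(1, n + 1)):
        for col, p in enumerate(names):
            ax = axes[row][col]
            x = results.draws[f"{p}[{i}]"].ravel()
            if p == "c":
                x = np.log10(x)
                label = "log10 c"
            else:
                label = p
            ax.hist(x, bins=50, color="steelblue")
            ax.set_title(f"ISE #{i}: {label}", fontsize=9)
            ax.set_yticks([])
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig, axes
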