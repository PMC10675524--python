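"""Simple figure export for group time series and cross-correlograms."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def plot_group_timeseries(df: pd.DataFrame, path, measurement: str = "au12") -> None:
    """Per-frame group means with SE error bars, one line per condition."""
    fig, ax = plt.subplots(figsize=(7, 4))
    sub = df[df["measurement"] == measurement]
    for cond, g in sub.groupby("condition"):
        g = g.sort_values("frame")
        ax.errorbar(g["frame"], g["mean"], yerr=g["se"], label=cond, lw=1, elinewidth=0.4)
    ax.set_xlabel("frame")
    ax.set_ylabel("group-average amplitude")
    ax.set_title(measurement)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_crosscorr(df: pd.DataFrame, path) -> None:
    """Group mean cross-correlation against lag, one line per condition."""
    fig, ax = plt.subplots(figsize=(7, 4))
    for cond, g in df.groupby("condition"):
        g = g.sort_values("lag")
        ax.plot(g["lag"], g["r"], label=cond, lw=1.2)
    ax.axvline(0, color="k", lw=0.6)
    ax.set_xlabel("lag (frames; positive = AU12 trails ZM)")
    ax.set_ylabel("cross-correlation r")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
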