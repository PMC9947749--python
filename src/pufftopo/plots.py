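"""Figure helpers: per-user daily histogram panels and mean +/- SE curves."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def plot_user_daily_counts(summaries: pd.DataFrame, path, max_users: int = 60) -> None:
    """Normalized per-user daily puff-count histograms, one panel per user."""
    users = sorted(summaries["device_id"].unique())[:max_users]
    ncols = 6
    nrows = int(np.ceil(len(users) / ncols)) or 1
    fig, axes = plt.subplots(nrows, ncols, figsize=(2.2 * ncols, 1.4 * nrows),
                             squeeze=False, sharex=True)
    for ax in axes.ravel():
        ax.axis("off")
    for i, dev in enumerate(users):
        ax = axes[i // ncols][i % ncols]
        ax.axis("on")
        grp = summaries[summaries["device_id"] == dev]
        counts = grp.set_index("relative_day")["puff_count"]
        peak = counts.max() or 1
        ax.bar(counts.index, counts / peak, width=1.0, color="#3b6ea5")
        ax.set_ylim(0, 1.05)
        ax.set_yticks([])
        ax.set_title(dev, fontsize=6)
    fig.suptitle("Daily puff numbers per user (normalized)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_cohort_series(series: pd.DataFrame, path, max_day: int | None = 21) -> None:
    """Mean +/- SE curves for puffs/day, duration/day and nicotine/day."""
    s = series if max_day is None else series[series["relative_day"] <= max_day]
    panels = [("puffs_mean", "puffs_se", "Puffs per day"),
              ("dur_mean", "dur_se", "Puff duration (s)"),
              ("nic_mean", "nic_se", "Nicotine (mg/day)")]
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.2))
    for ax, (mean_col, se_col, label) in zip(axes, panels):
        x = s["relative_day"]
        m = s[mean_col]
        se = s[se_col].fillna(0.0)
        ax.plot(x, m, color="#b5493a")
        ax.fill_between(x, m - se, m + se, alpha=0.3, color="#b5493a")
        ax.set_xlabel("Relative day")
        ax.set_ylabel(label)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
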