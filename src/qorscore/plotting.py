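"""Simple per-group recovery trajectory charts."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["plot_group_trajectories"]


def plot_group_trajectories(composites: pd.DataFrame, ax=None):
    """Median composite per group over days, with interquartile bands.

    Returns the matplotlib axes (created on demand).
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for group, sub in composites.groupby("group"):
        agg = sub.groupby("day")["total"].agg(
            median="median",
            q1=lambda s: np.percentile(s, 25),
            q3=lambda s: np.percentile(s, 75),
        )
        ax.plot(agg.index, agg["median"], marker="o", label=group)
        ax.fill_between(agg.index, agg["q1"], agg["q3"], alpha=0.15)
    ax.set_xlabel("post-operative day")
    ax.set_ylabel("quality-of-recovery composite (0-18)")
    ax.set_ylim(0, 18.5)
    ax.legend(fontsize=8)
    return ax
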