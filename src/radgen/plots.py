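"""Basic plotting: Kaplan-Meier curves per group and the feature-importance
profile.  Matplotlib figures only; callers save or show them."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .stats import km_estimate


def plot_km_by_group(time, event, group, ax=None):
    """One KM curve per group with the log-rank-ready survival data."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    df = pd.DataFrame({"time": np.asarray(time, dtype=float),
                       "event": np.asarray(event, dtype=int),
                       "group": np.asarray(group)})
    for g, sub in df.groupby("group"):
        kmf = km_estimate(sub["time"], sub["event"])
        kmf.plot_survival_function(ax=ax, label=f"{g} (n={len(sub)})")
    ax.set_xlabel("months")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    return ax


def plot_feature_importance(importance: pd.DataFrame, top: int = 20, ax=None):
    """Horizontal bars of the aggregated inter-centroid distance."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.3 * top + 1))
    sub = importance.head(top).iloc[::-1]
    ax.barh(sub.index, sub["aggregate"])
    ax.set_xlabel("aggregated centroid inter-distance")
    return ax
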