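"""Figure helpers for trajectories and assay tables (matplotlib)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def plot_chip_timecourse(chip_df: pd.DataFrame, ax=None):
    """Occupancy vs time, one line per amplicon (long-format ChIP table)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for probe, grp in chip_df.groupby("probe"):
        g = grp.sort_values("timepoint")
        ax.plot(g["timepoint"], g["value"], marker="o", label=probe)
    ax.set_xlabel("time after UV (h)")
    ax.set_ylabel("ChIP occupancy (pre-UV = 1)")
    ax.legend(title="amplicon", fontsize=8)
    return ax


def plot_em_lengths(lengths_nm: np.ndarray, ax=None, **hist_kw):
    """Histogram of Miller-spread transcript lengths."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    ax.hist(lengths_nm, bins=hist_kw.pop("bins", 30), **hist_kw)
    ax.set_xlabel("ternary complex length (nm)")
    ax.set_ylabel("count")
    return ax


def plot_psoralen_fractions(frac_by_time: dict, ax=None):
    """Stacked open/intermediate/closed fractions over time.

    ``frac_by_time``: {time_h: {'open': f, 'intermediate': f, 'closed': f}}.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    times = sorted(frac_by_time)
    bottom = np.zeros(len(times))
    for label in ("open", "intermediate", "closed"):
        vals = np.array([frac_by_time[t][label] for t in times])
        ax.bar([str(t) for t in times], vals, bottom=bottom, label=label)
        bottom += vals
    ax.set_xlabel("time after UV (h)")
    ax.set_ylabel("fraction of gene copies")
    ax.legend(fontsize=8)
    return ax
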