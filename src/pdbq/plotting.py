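"""Matplotlib views of the quality trends and impact correlations."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def plot_mean_score_over_time(
    temporal_scores: pd.DataFrame,
    records: pd.DataFrame,
    measure: str = "p_q1_td",
    ax: plt.Axes | None = None,
) -> plt.Axes:
    """Mean quality percentile per deposition year, one line per group."""
    df = temporal_scores.merge(records[["pdb_id", "deposition_date"]], on="pdb_id")
    df["year"] = df["deposition_date"].dt.year
    if ax is None:
        _, ax = plt.subplots()
    for group, sub in df.groupby("group"):
        series = sub.groupby("year")[measure].mean()
        ax.plot(series.index, series.values, label=group)
    ax.set_xlabel("deposition year")
    ax.set_ylabel(f"mean {measure} (%)")
    ax.legend()
    return ax


def plot_impact_correlation(correlation: pd.DataFrame, ax: plt.Axes | None = None) -> plt.Axes:
    """Spearman rho between journal quality and impact, per year."""
    if ax is None:
        _, ax = plt.subplots()
    ax.plot(correlation["year"], correlation["rho_ipp"], marker="o", label="IPP")
    ax.plot(correlation["year"], correlation["rho_snip"], marker="s", label="SNIP")
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.set_xlabel("year")
    ax.set_ylabel("Spearman rho")
    ax.legend()
    return ax
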