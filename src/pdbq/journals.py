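"""Journal rankings, significance tests, and journal-impact correlations.

Journals are ranked by the mean time/resolution-conditioned quality
percentile of the deposits citing them; each journal's deposits are compared
against the rest of the archive with Welch's t-test under a Bonferroni
correction.  Rankings can be restricted to a date cutoff (retrospective
tables), to rolling multi-year windows, or correlated per year against
bibliometric impact indicators (IPP, SNIP) with Spearman's rank correlation.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

MEASURES = {"p_q1_td", "p_q1_t", "p_q1", "p_q1_min"}


def resolution_means(resolutions) -> tuple[float, float, float]:
    """Arithmetic, geometric, and V-mean (Å⁻³ power mean) of resolutions.

    The geometric mean is the log-average exp(mean(log d)); the V-mean
    averages in reciprocal volume units, (mean(d⁻³))^(−1/3), weighting
    sharper structures more heavily.  For positive inputs
    V-mean ≤ G-mean ≤ arithmetic mean.
    """
    arr = np.asarray(resolutions, dtype=float)
    if arr.size == 0:
        raise ValueError("empty resolution collection")
    if np.any(arr <= 0):
        raise ValueError("resolutions must be positive")
    arithmetic = float(arr.mean())
    geometric = float(np.exp(np.log(arr).mean()))
    vmean = float(np.mean(arr**-3.0) ** (-1.0 / 3.0))
    return arithmetic, geometric, vmean


def _join(temporal_scores: pd.DataFrame, records: pd.DataFrame) -> pd.DataFrame:
    cols = ["pdb_id", "journal", "deposition_date", "resolution"]
    if "issn" in records.columns:
        cols.append("issn")
    if "journal" not in records.columns:
        raise ValueError("records need a canonical 'journal' column; run clean_journal_names")
    return temporal_scores.merge(records[cols], on="pdb_id", how="inner")


def rank_journals(
    temporal_scores: pd.DataFrame,
    records: pd.DataFrame,
    measure: str = "p_q1_td",
    min_count: int = 100,
    alpha: float = 0.001,
    bonferroni: bool = True,
    date_cutoff=None,
) -> pd.DataFrame:
    """All-time (or date-restricted) journal ranking table.

    One row per journal with at least ``min_count`` qualifying deposits:
    mean of ``measure``, the three resolution means, the structure count,
    and a two-sided Welch's t-test of the journal's deposits against all
    other deposits, flagged significant after Bonferroni correction over
    the number of journals tested.  ``date_cutoff`` restricts the input to
    deposits made strictly before the cutoff (retrospective rankings).
    "To be published" is treated as a venue like any other.
    """
    df = _join(temporal_scores, records)
    if date_cutoff is not None:
        df = df[df["deposition_date"] < pd.Timestamp(date_cutoff)]
    counts = df.groupby("journal")["pdb_id"].size()
    eligible = counts[counts >= min_count].index
    if len(eligible) == 0:
        logger.warning("no journal meets min_count=%d", min_count)

    rows = []
    for journal in eligible:
        in_journal = df["journal"] == journal
        sample = df.loc[in_journal, measure].to_numpy()
        rest = df.loc[~in_journal, measure].to_numpy()
        mean_res, gmean_res, vmean_res = resolution_means(df.loc[in_journal, "resolution"])
        if len(rest) >= 2:
            t_stat, p_value = stats.ttest_ind(sample, rest, equal_var=False)
        else:
            t_stat, p_value = np.nan, np.nan
        rows.append(
            {
                "journal": journal,
                "mean_score": float(sample.mean()),
                "mean_resolution": mean_res,
                "gmean_resolution": gmean_res,
                "vmean_resolution": vmean_res,
                "count": int(in_journal.sum()),
                "t_statistic": float(t_stat),
                "p_value": float(p_value),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "journal", "mean_score", "mean_resolution", "gmean_resolution",
            "vmean_resolution", "count", "t_statistic", "p_value",
        ],
    )
    if len(table):
        threshold = alpha / len(table) if bonferroni else alpha
        table["significant"] = table["p_value"] < threshold
        table = table.sort_values(
            ["mean_score", "journal"], ascending=[False, True]
        ).reset_index(drop=True)
        table.insert(0, "rank", table["mean_score"].rank(method="dense", ascending=False).astype(int))
    else:
        table["significant"] = pd.Series(dtype=bool)
        table.insert(0, "rank", pd.Series(dtype=int))
    table.attrs["measure"] = measure
    table.attrs["n_tested"] = len(table)
    return table


def windowed_ranking(
    temporal_scores: pd.DataFrame,
    records: pd.DataFrame,
    measure: str = "p_q1_td",
    window_years: int = 5,
    min_count: int = 30,
) -> pd.DataFrame:
    """Per-window journal ranks over consecutive multi-year intervals.

    Windows partition the time axis into ``window_years``-year intervals
    anchored so the last window ends at the dataset's final year.  A journal
    appears in a window only with at least ``min_count`` in-window deposits;
    ranks are dense by descending mean ``measure``.
    """
    df = _join(temporal_scores, records)
    years = df["deposition_date"].dt.year
    last = int(years.max())
    first = int(years.min())
    n_windows = int(np.ceil((last - first + 1) / window_years))
    starts = [last - window_years * (k + 1) + 1 for k in reversed(range(n_windows))]

    rows = []
    for start in starts:
        end = start + window_years - 1
        in_window = df[(years >= start) & (years <= end)]
        grouped = in_window.groupby("journal").agg(
            mean_score=(measure, "mean"), count=("pdb_id", "size")
        )
        grouped = grouped[grouped["count"] >= min_count]
        if grouped.empty:
            continue
        grouped = grouped.sort_values("mean_score", ascending=False)
        grouped["rank"] = grouped["mean_score"].rank(method="dense", ascending=False).astype(int)
        for journal, row in grouped.iterrows():
            rows.append(
                {
                    "window_start": start,
                    "window_end": end,
                    "journal": journal,
                    "mean_score": float(row["mean_score"]),
                    "count": int(row["count"]),
                    "rank": int(row["rank"]),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["window_start", "window_end", "journal", "mean_score", "count", "rank"],
    )


def correlate_impact(
    temporal_scores: pd.DataFrame,
    records: pd.DataFrame,
    bibliometrics: pd.DataFrame,
    measure: str = "p_q1_td",
    min_per_year: int = 5,
) -> pd.DataFrame:
    """Per-year Spearman correlation between journal quality and impact.

    For each calendar year covered by the bibliometric table, every journal
    with at least ``min_per_year`` deposits dated that year contributes one
    point (impact indicator for that year, mean ``measure`` of those
    deposits); Spearman's rho is computed for IPP and SNIP separately.
    Years with fewer than 3 journal points get ``NaN`` and a log entry.
    """
    df = _join(temporal_scores, records)
    if "issn" not in df.columns:
        raise ValueError("records need an 'issn' column to join bibliometrics")
    df["year"] = df["deposition_date"].dt.year
    per_jy = (
        df[df["issn"].astype(str).str.len() > 0]
        .groupby(["issn", "year"])
        .agg(mean_score=(measure, "mean"), count=("pdb_id", "size"))
        .reset_index()
    )
    per_jy = per_jy[per_jy["count"] >= min_per_year]
    joined = per_jy.merge(bibliometrics, on=["issn", "year"], how="inner")

    rows = []
    for year in sorted(bibliometrics["year"].unique()):
        pts = joined[joined["year"] == year]
        if len(pts) < 3:
            logger.warning("year %d has %d journal points; rho undefined", year, len(pts))
            rows.append({"year": int(year), "n_journals": len(pts),
                         "rho_ipp": np.nan, "rho_snip": np.nan})
            continue
        rho_ipp = stats.spearmanr(pts["ipp"], pts["mean_score"]).statistic
        rho_snip = stats.spearmanr(pts["snip"], pts["mean_score"]).statistic
        rows.append(
            {
                "year": int(year),
                "n_journals": int(len(pts)),
                "rho_ipp": float(rho_ipp),
                "rho_snip": float(rho_snip),
            }
        )
    return pd.DataFrame(rows, columns=["year", "n_journals", "rho_ipp", "rho_snip"])
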