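"""Time- and resolution-conditioned quality percentiles.

P_Q1(t) ranks a deposit's composite score against the deposits of its
molecule group that entered the archive strictly before it (plus itself);
P_Q1(t,d) additionally restricts the reference population to the deposit's
resolution bin — resolution rounded to the nearest 0.1 Å and capped at
1 and 4 Å.  Both are computed in a single chronological sweep that never
looks at later deposits, so scores are stable under future growth of the
archive.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right, insort

import numpy as np
import pandas as pd


def resolution_bin(resolution) -> np.ndarray | float:
    """Resolution rounded half-up to 0.1 Å and capped into [1.0, 4.0] Å."""
    arr = np.asarray(resolution, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("resolution must be positive")
    binned = np.floor(arr * 10.0 + 0.5) / 10.0
    binned = np.clip(binned, 1.0, 4.0)
    return float(binned) if np.isscalar(resolution) else binned


def _cohort_percentile(pool: list, value: float, n_prior: int,
                       include_self: bool, convention: str) -> tuple[float, int]:
    """Percentile of ``value`` against a sorted pool of prior scores."""
    count_less = bisect_left(pool, value)
    count_eq = bisect_right(pool, value) - count_less
    if include_self:
        n = n_prior + 1
        avg_rank = count_less + (count_eq + 2) / 2.0
    else:
        if n_prior == 0:
            return 100.0, 0
        n = n_prior
        avg_rank = count_less + (count_eq + 1) / 2.0
    if convention == "inclusive":
        return 100.0 * avg_rank / n, n
    return 100.0 * (avg_rank - 0.5) / n, n


def temporal_percentile(
    scores: pd.DataFrame,
    records: pd.DataFrame | None = None,
    q1_column: str = "q1",
    include_self: bool = True,
    convention: str = "inclusive",
) -> pd.DataFrame:
    """Per-deposit P_Q1(t) and P_Q1(t,d).

    Parameters
    ----------
    scores
        Output of :func:`pdbq.quality.compute_q1` (needs ``pdb_id``,
        ``group``, and the chosen composite column).
    records
        Deposit table supplying ``deposition_date`` and ``resolution``;
        may be omitted if those columns are already present in ``scores``.
    q1_column
        Composite to re-rank: ``"q1"`` (averaging) or ``"q1_min"``.
    include_self
        If True (default) the reference population is the prior deposits
        plus the deposit itself, making the percentile well defined for
        the first deposit of a group (it scores 100).  If False the
        deposit is ranked against the prior deposits only, with the first
        deposit conventionally at 100.

    Notes
    -----
    "Prior" means strictly earlier ``deposition_date``; deposits sharing a
    date are excluded from each other's reference populations.  Year-only
    dates order by year, with the PDB id as a deterministic tie-break of
    processing (not of populations).
    """
    df = scores.copy()
    if records is not None:
        meta = records.set_index("pdb_id")[["deposition_date", "resolution"]]
        df = df.join(meta, on="pdb_id")
    for col in ("deposition_date", "resolution", q1_column, "group"):
        if col not in df.columns:
            raise ValueError(f"missing column {col!r}")
    if df["deposition_date"].isna().any():
        raise ValueError("undated deposits cannot be ranked temporally")

    df["resolution_bin"] = resolution_bin(df["resolution"].to_numpy())
    order = np.lexsort((df["pdb_id"].to_numpy(), df["deposition_date"].to_numpy()))
    df = df.iloc[order]

    p_t = np.empty(len(df))
    p_td = np.empty(len(df))
    n_t = np.empty(len(df), dtype=int)
    n_td = np.empty(len(df), dtype=int)

    pools_t: dict = {}
    pools_td: dict = {}
    values = df[q1_column].to_numpy(dtype=float)
    groups = df["group"].to_numpy()
    bins = df["resolution_bin"].to_numpy()
    dates = df["deposition_date"].to_numpy()

    i = 0
    n = len(df)
    while i < n:
        # Same-date cohort: scored against the pre-cohort state, then merged.
        j = i
        while j < n and dates[j] == dates[i]:
            j += 1
        for k in range(i, j):
            pool_t = pools_t.setdefault(groups[k], [])
            pool_td = pools_td.setdefault((groups[k], bins[k]), [])
            p_t[k], n_t[k] = _cohort_percentile(
                pool_t, values[k], len(pool_t), include_self, convention
            )
            p_td[k], n_td[k] = _cohort_percentile(
                pool_td, values[k], len(pool_td), include_self, convention
            )
        for k in range(i, j):
            insort(pools_t[groups[k]], values[k])
            insort(pools_td[(groups[k], bins[k])], values[k])
        i = j

    out = pd.DataFrame(
        {
            "pdb_id": df["pdb_id"].to_numpy(),
            "group": groups,
            "resolution_bin": bins,
            "p_q1_t": p_t,
            "p_q1_td": p_td,
            "reference_count_t": n_t,
            "reference_count_td": n_td,
        }
    )
    return out.set_index(df.index).loc[scores.index].reset_index(drop=True)
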