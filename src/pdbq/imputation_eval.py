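"""Masking-based evaluation of imputation methods.

The protocol mirrors how the real archive was analysed: take the complete
portion of the data, hide observed cells at the archive's per-metric
missingness rates, impute with each candidate method on the *same* mask,
and score the imputations at the hidden cells with MAD, MAE, and RMSE.
Repeating with fresh masks yields paired per-repetition scores, compared
with a Friedman rank test and a Nemenyi post hoc.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from pdbq.ingest import METRIC_COLUMNS, PROTEIN_ONLY_METRICS
from pdbq.imputation import impute

logger = logging.getLogger(__name__)

ERROR_MEASURES = ["mad", "mae", "rmse"]

#: A method is a name plus a callable mapping a masked deposit table to a
#: completed one (index-aligned).
MethodSpec = str | tuple[str, Callable[[pd.DataFrame], pd.DataFrame]]


def complete_subset(df: pd.DataFrame) -> pd.DataFrame:
    """Deposits with every applicable metric plus R observed.

    Nucleic-acid-only deposits qualify without Ramachandran/rotamer values
    (those are inapplicable); resolution and year are always present.
    """
    cols = METRIC_COLUMNS + ["r_work"]
    observed = df[cols].notna()
    nucleic = df["molecule_class"] == "nucleic_acid"
    for col in PROTEIN_ONLY_METRICS:
        observed.loc[nucleic, col] = True
    return df[observed.all(axis=1)].copy()


@dataclass
class MaskedDataset:
    """A complete table with artificially hidden cells."""

    masked: pd.DataFrame
    truth: pd.DataFrame
    mask: pd.DataFrame  # boolean, True = hidden
    realized_fractions: dict[str, float]
    any_missing_fraction: float


def _solve_conditional_rates(fractions: np.ndarray, any_fraction: float) -> np.ndarray:
    """Per-metric mask probabilities within affected deposits.

    Solves the fixed point c = 1 − Π(1 − p_m·c/a) so that masking metric m
    with probability q_m = p_m·c/a inside an a-fraction of deposits — after
    rejecting all-clear draws — reproduces both the per-metric marginal
    rates p_m and the any-missing fraction a exactly in expectation.
    """
    from scipy.optimize import brentq

    p, a = fractions, any_fraction
    if p.sum() <= a:
        # Constraints are already compatible with (near-)disjoint masking.
        return np.minimum(p / a, 1.0)

    def g(c: float) -> float:
        q = np.minimum(p * c / a, 1.0)
        return c - (1.0 - np.prod(1.0 - q))

    c = brentq(g, 1e-9, 1.0)
    q = p * c / a
    if np.any(q > 1.0):
        raise ValueError("per-metric rates incompatible with the any-missing target")
    return q


def inject_missingness(
    complete: pd.DataFrame,
    fractions: Mapping[str, float],
    target_any_fraction: float | None = None,
    seed: int = 0,
) -> MaskedDataset:
    """Hide observed cells at the given per-metric rates.

    With ``target_any_fraction=None`` (default) cells are hidden
    independently per metric and the fraction of deposits losing at least
    one metric is emergent.  Supplying a target activates a joint scheme —
    deposits are first selected at the any-missing rate, then receive
    conditional per-metric masks solved so the marginal rates still hold —
    matching archives whose missingness is concentrated on a subset of
    deposits.  ``complete`` must have no missing applicable cells.
    """
    nucleic = complete["molecule_class"] == "nucleic_acid"
    for col, frac in fractions.items():
        if frac < 0 or frac > 1:
            raise ValueError(f"fraction for {col!r} outside [0, 1]")
        applicable = ~nucleic if col in PROTEIN_ONLY_METRICS else pd.Series(True, index=complete.index)
        if frac > 0 and not applicable.any():
            raise ValueError(f"column {col!r} is inapplicable for every deposit")
        if complete.loc[applicable, col].isna().any():
            raise ValueError(f"column {col!r} is not complete")
    rng = np.random.default_rng(seed)
    mask = pd.DataFrame(False, index=complete.index, columns=list(fractions))
    n = len(complete)
    if target_any_fraction is None:
        for col, frac in fractions.items():
            applicable = ~(nucleic & (col in PROTEIN_ONLY_METRICS))
            draws = rng.random(n) < frac
            mask[col] = draws & applicable.to_numpy()
    else:
        if not 0 < target_any_fraction <= 1:
            raise ValueError("target_any_fraction must lie in (0, 1]")
        cols = list(fractions)
        rates = np.array([fractions[c] for c in cols])
        q = _solve_conditional_rates(rates, target_any_fraction)
        affected = rng.random(n) < target_any_fraction
        applicable = np.column_stack(
            [~(nucleic & (c in PROTEIN_ONLY_METRICS)).to_numpy() for c in cols]
        )
        cells = np.zeros((n, len(cols)), dtype=bool)
        pending = affected.copy()
        while pending.any():
            idx = np.flatnonzero(pending)
            draws = (rng.random((len(idx), len(cols))) < q) & applicable[idx]
            cells[idx] = draws
            # redraw deposits that came out all-clear despite being affected
            pending[idx] = ~draws.any(axis=1) & applicable[idx].any(axis=1)
        mask.loc[:, cols] = cells
    masked = complete.copy()
    for col in mask.columns:
        masked.loc[mask[col], col] = np.nan
    applicable_counts = {
        col: int((~(nucleic & (col in PROTEIN_ONLY_METRICS))).sum()) for col in mask.columns
    }
    realized = {
        col: mask[col].sum() / applicable_counts[col] if applicable_counts[col] else 0.0
        for col in mask.columns
    }
    return MaskedDataset(
        masked=masked,
        truth=complete,
        mask=mask,
        realized_fractions=realized,
        any_missing_fraction=float(mask.any(axis=1).mean()),
    )


def error_stats(
    truth: pd.DataFrame,
    imputed: pd.DataFrame,
    mask: pd.DataFrame,
    mad_convention: str = "median_abs_error",
) -> pd.DataFrame:
    """MAD, MAE, and RMSE at the masked cells, per metric.

    MAD defaults to the median absolute error median(|truth − imputed|),
    an error magnitude on the same scale as MAE; set
    ``mad_convention="dispersion"`` for the dispersion-about-median form
    median(|e − median(e)|).  Metrics with no masked cells get ``NaN``.
    """
    if mad_convention not in {"median_abs_error", "dispersion"}:
        raise ValueError("unknown MAD convention")
    rows = {}
    for col in mask.columns:
        cells = mask[col]
        if not cells.any():
            rows[col] = {m: np.nan for m in ERROR_MEASURES}
            continue
        err = (imputed.loc[cells, col] - truth.loc[cells, col]).to_numpy(dtype=float)
        if mad_convention == "median_abs_error":
            mad = float(np.median(np.abs(err)))
        else:
            mad = float(np.median(np.abs(err - np.median(err))))
        rows[col] = {
            "mad": mad,
            "mae": float(np.mean(np.abs(err))),
            "rmse": float(np.sqrt(np.mean(err**2))),
        }
    return pd.DataFrame(rows).T.loc[list(mask.columns), ERROR_MEASURES]


def friedman_nemenyi(scores: np.ndarray) -> tuple[float, pd.DataFrame, np.ndarray]:
    """Friedman test plus Nemenyi post hoc over a (blocks × treatments) array.

    Returns the Friedman p-value, the pairwise Nemenyi p-value matrix, and
    the mean ranks (rank 1 = smallest error).  The Nemenyi p-values come
    from the studentized-range distribution applied to rank-mean
    differences, the standard post hoc companion of the Friedman test.
    """
    n, k = scores.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 blocks and 2 treatments")
    _, p_friedman = stats.friedmanchisquare(*(scores[:, j] for j in range(k)))
    ranks = np.apply_along_axis(stats.rankdata, 1, scores)
    mean_ranks = ranks.mean(axis=0)
    se = np.sqrt(k * (k + 1) / (12.0 * n))
    pmat = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            q = np.abs(mean_ranks[i] - mean_ranks[j]) / se * np.sqrt(2)
            p = float(stats.studentized_range.sf(q, k, np.inf))
            pmat[i, j] = pmat[j, i] = min(1.0, p)
    return float(p_friedman), pd.DataFrame(pmat), mean_ranks


@dataclass
class ImputationEvalReport:
    """Per-method error statistics over repetitions plus significance tests."""

    summary: pd.DataFrame  # columns: measure, method, metric, mean, sd
    friedman: pd.DataFrame  # columns: metric, measure, p_value
    nemenyi: dict = field(default_factory=dict)  # (metric, measure) -> DataFrame
    n_repetitions: int = 0
    methods: list[str] = field(default_factory=list)

    def to_table(self, measure: str = "mae") -> pd.DataFrame:
        """Pivot the summary into an error-measure table (method × metric)."""
        sub = self.summary[self.summary["measure"] == measure]
        return sub.pivot(index="method", columns="metric", values="mean")


def _resolve_methods(methods: Sequence[MethodSpec], seed: int):
    resolved = []
    for spec in methods:
        if isinstance(spec, str):
            name = spec
            resolved.append(
                (name, lambda d, m=name, s=seed: impute(d, m, seed=s).completed)
            )
        else:
            resolved.append(spec)
    return resolved


def run_evaluation(
    complete: pd.DataFrame,
    methods: Sequence[MethodSpec] = ("mean", "median", "mice"),
    n_repetitions: int = 100,
    seed: int = 0,
    fractions: Mapping[str, float] | None = None,
    target_any_fraction: float | None = None,
    mad_convention: str = "median_abs_error",
) -> ImputationEvalReport:
    """Repeated mask–impute–score evaluation with a paired design.

    Every method sees the identical mask within a repetition, which makes
    the repetitions valid blocks for the Friedman test (methods are the
    treatments), applied per metric and error measure, with Nemenyi
    pairwise post hoc p-values.
    """
    from pdbq.synthetic import DEFAULT_MISSING_FRACTIONS

    if n_repetitions < 2:
        raise ValueError("n_repetitions must be >= 2")
    fractions = dict(fractions or DEFAULT_MISSING_FRACTIONS)
    resolved = _resolve_methods(methods, seed)
    names = [name for name, _ in resolved]
    metrics = [c for c in fractions if fractions[c] > 0]

    rng = np.random.default_rng(seed)
    results = np.full((n_repetitions, len(resolved), len(metrics), len(ERROR_MEASURES)), np.nan)
    effective = 0
    for rep in range(n_repetitions):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        masked = inject_missingness(
            complete, fractions, target_any_fraction=target_any_fraction, seed=rep_seed
        )
        try:
            for m_idx, (name, fn) in enumerate(resolved):
                completed = fn(masked.masked)
                errs = error_stats(masked.truth, completed, masked.mask, mad_convention)
                results[rep, m_idx] = errs.loc[metrics, ERROR_MEASURES].to_numpy()
        except Exception as exc:
            logger.warning("repetition %d aborted: %s", rep, exc)
            results[rep] = np.nan
            continue
        effective += 1

    # A repetition may legitimately draw no masked cells for a very rare
    # metric; such holes are skipped per statistic rather than discarding
    # the whole repetition.
    rows = []
    with np.errstate(invalid="ignore"):
        for m_idx, name in enumerate(names):
            for g_idx, metric in enumerate(metrics):
                for e_idx, measure in enumerate(ERROR_MEASURES):
                    vals = results[:, m_idx, g_idx, e_idx]
                    vals = vals[~np.isnan(vals)]
                    rows.append(
                        {
                            "measure": measure,
                            "method": name,
                            "metric": metric,
                            "mean": float(np.mean(vals)) if len(vals) else np.nan,
                            "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan,
                        }
                    )
    summary = pd.DataFrame(rows)

    fried_rows, nemenyi = [], {}
    for g_idx, metric in enumerate(metrics):
        for e_idx, measure in enumerate(ERROR_MEASURES):
            block = results[:, :, g_idx, e_idx]
            block = block[~np.isnan(block).any(axis=1)]
            if len(block) >= 2 and len(names) >= 3:
                p, pmat, _ = friedman_nemenyi(block)
                pmat.index = pmat.columns = names
                nemenyi[(metric, measure)] = pmat
            elif len(block) >= 2 and len(names) == 2:
                _, p = stats.wilcoxon(block[:, 0], block[:, 1])
            else:
                p = np.nan
            fried_rows.append({"metric": metric, "measure": measure, "p_value": p})
    friedman = pd.DataFrame(fried_rows)

    if effective < n_repetitions:
        logger.warning("only %d/%d repetitions completed", effective, n_repetitions)
    return ImputationEvalReport(
        summary=summary,
        friedman=friedman,
        nemenyi=nemenyi,
        n_repetitions=effective,
        methods=names,
    )
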