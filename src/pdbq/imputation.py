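"""Missing-metric imputation: column constants or chained equations (MICE).

All methods operate on the deposit table, treat Ramachandran/rotamer cells of
nucleic-acid deposits as inapplicable (they are neither fitted nor filled),
and clip imputed values into each metric's legal range.  Observed cells are
never modified.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer
from sklearn.linear_model import BayesianRidge

from pdbq.ingest import (
    METRIC_COLUMNS,
    METRIC_RANGES,
    PROTEIN_ONLY_METRICS,
    protein_group_mask,
)

logger = logging.getLogger(__name__)

#: Columns available to the chained-equations regressions: the five quality
#: metrics plus three always-present supporting variables.
IMPUTATION_COLUMNS = METRIC_COLUMNS + ["r_work", "resolution", "year"]

#: Columns that may actually be filled (supporting resolution/year are never
#: missing; R is imputable like the metrics).
FILLABLE_COLUMNS = METRIC_COLUMNS + ["r_work"]


@dataclass
class ImputationResult:
    """A completed deposit table plus per-cell provenance.

    ``provenance`` holds one of ``"observed"``, ``"imputed"``, or
    ``"inapplicable"`` for every fillable cell.
    """

    completed: pd.DataFrame
    provenance: pd.DataFrame
    method: str
    seed: int | None = None
    n_iterations: int | None = None


def _provenance(df: pd.DataFrame) -> pd.DataFrame:
    prov = pd.DataFrame("observed", index=df.index, columns=FILLABLE_COLUMNS)
    missing = df[FILLABLE_COLUMNS].isna()
    prov[missing] = "imputed"
    nucleic = df["molecule_class"] == "nucleic_acid"
    for col in PROTEIN_ONLY_METRICS:
        prov.loc[nucleic, col] = "inapplicable"
    return prov


def _check_columns(df: pd.DataFrame) -> None:
    for col in FILLABLE_COLUMNS:
        applicable = df[col]
        if col in PROTEIN_ONLY_METRICS:
            applicable = df.loc[protein_group_mask(df), col]
        if len(applicable) and applicable.notna().sum() == 0:
            raise ValueError(f"column {col!r} has no observed values")


def _clip(values: pd.Series, column: str) -> pd.Series:
    lo, hi = METRIC_RANGES[column]
    return values.clip(lower=lo, upper=None if np.isinf(hi) else hi)


def impute_constant(df: pd.DataFrame, statistic: str = "mean") -> ImputationResult:
    """Fill missing metrics with the column mean or median.

    Statistics are computed over observed, applicable cells only.
    """
    if statistic not in {"mean", "median"}:
        raise ValueError("statistic must be 'mean' or 'median'")
    _check_columns(df)
    prov = _provenance(df)
    completed = df.copy()
    for col in FILLABLE_COLUMNS:
        observed = df.loc[prov[col] == "observed", col]
        fill = observed.mean() if statistic == "mean" else observed.median()
        target = prov[col] == "imputed"
        completed.loc[target, col] = _clip(pd.Series(fill, index=df.index[target]), col)
    return ImputationResult(completed, prov, method=statistic)


def mice_impute(df: pd.DataFrame, n_iterations: int = 10, seed: int = 0) -> ImputationResult:
    """Chained-equations imputation with a Bayesian ridge regressor.

    Missing cells are initialised with column means, then each incomplete
    column in turn (most-missing first) is regressed on all other columns'
    current values and its missing entries replaced by the posterior-mean
    prediction; the cycle repeats up to ``n_iterations`` times or until the
    imputed values stabilise.  Predictions are clipped to each metric's legal
    range.  Deterministic given ``seed``.

    Protein-group deposits are imputed with all eight variables; nucleic-acid
    deposits separately, without the inapplicable Ramachandran/rotamer
    columns.
    """
    _check_columns(df)
    if df[["resolution", "year"]].isna().any().any():
        raise ValueError("supporting variables resolution/year must be complete")
    prov = _provenance(df)
    completed = df.copy()

    groups = [
        (protein_group_mask(df), IMPUTATION_COLUMNS),
        (df["molecule_class"] == "nucleic_acid",
         [c for c in IMPUTATION_COLUMNS if c not in PROTEIN_ONLY_METRICS]),
    ]
    for mask, columns in groups:
        sub = df.loc[mask, columns]
        if sub.empty or not sub.isna().any().any():
            continue
        fillable = [c for c in columns if c in FILLABLE_COLUMNS]
        lo = np.array([METRIC_RANGES.get(c, (-np.inf, np.inf))[0] for c in columns])
        hi = np.array([METRIC_RANGES.get(c, (-np.inf, np.inf))[1] for c in columns])
        imputer = IterativeImputer(
            estimator=BayesianRidge(),
            max_iter=n_iterations,
            tol=1e-4,
            imputation_order="descending",
            sample_posterior=False,
            initial_strategy="mean",
            min_value=lo,
            max_value=hi,
            random_state=seed,
        )
        try:
            filled = imputer.fit_transform(sub.to_numpy(dtype=float))
        except Exception:  # degenerate design: fall back per column
            logger.warning("chained-equations fit failed; falling back to column means")
            fallback = impute_constant(df.loc[mask], statistic="mean")
            completed.loc[mask, fillable] = fallback.completed[fillable]
            continue
        filled = pd.DataFrame(filled, index=sub.index, columns=columns)
        for col in fillable:
            target = sub.index[sub[col].isna()]
            completed.loc[target, col] = _clip(filled.loc[target, col], col)

    return ImputationResult(
        completed, prov, method="mice", seed=seed, n_iterations=n_iterations
    )


def impute(df: pd.DataFrame, method: str, n_iterations: int = 10, seed: int = 0) -> ImputationResult:
    """Dispatch to :func:`impute_constant` or :func:`mice_impute` by name."""
    if method in {"mean", "median"}:
        return impute_constant(df, statistic=method)
    if method == "mice":
        return mice_impute(df, n_iterations=n_iterations, seed=seed)
    raise ValueError(f"unknown imputation method: {method!r}")
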