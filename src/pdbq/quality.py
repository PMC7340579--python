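"""Tie-averaged quality percentiles, the geometry PCA, and composite scores.

Every deposit is ranked within its molecule group (proteins + protein–
nucleic-acid complexes form the protein group; nucleic-acid-only deposits
form the nucleic group).  For proteins the composite score averages the
percentiles of R_free, RSRZ outliers, and the first principal component of
the three geometry metrics:

    Q1p = (P_Rfree + P_%RSRZ + P_PC1(geometry)) / 3

For nucleic acids the geometry aggregate reduces to clashscore alone:

    Q1n = (P_Rfree + P_%RSRZ + P_Clashscore) / 3

A "minimum" variant replaces the mean by the minimum of the same three
components, judging each structure by its weakest feature.  The final
quality percentile P_Q1 re-ranks the composite within its group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from pdbq.ingest import protein_group_mask

GEOMETRY_METRICS = ["clashscore", "rama_outliers", "rota_outliers"]

#: Deposits beyond any of these thresholds are excluded from *fitting* the
#: geometry PCA (not from scoring): extreme cases would otherwise dominate
#: the covariance.
PCA_OUTLIER_THRESHOLDS = {
    "rota_outliers": 50.0,
    "rama_outliers": 45.0,
    "clashscore": 250.0,
}


def percentile_rank(
    values, better: str = "lower", convention: str = "inclusive"
) -> np.ndarray:
    """Tie-averaged percentile ranks in (0, 100], higher = better quality.

    Deposits are ranked 1..N from worst to best; tied values receive the
    average rank of their group.  The default ("inclusive") convention maps
    rank r to 100·r/N, placing the unique best value at exactly 100; the
    "midpoint" convention uses 100·(r − 0.5)/N.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot rank an empty population")
    if np.isnan(arr).any():
        raise ValueError("missing values present; impute before ranking")
    if better == "lower":
        goodness = -arr
    elif better == "higher":
        goodness = arr
    else:
        raise ValueError("better must be 'lower' or 'higher'")
    ranks = stats.rankdata(goodness, method="average")
    n = arr.size
    if convention == "inclusive":
        return 100.0 * ranks / n
    if convention == "midpoint":
        return 100.0 * (ranks - 0.5) / n
    raise ValueError("convention must be 'inclusive' or 'midpoint'")


@dataclass
class GeometryPCAModel:
    """Standardisation parameters and loadings of the geometry PCA.

    PC1 is oriented so that all three loadings are non-negative: since
    clashscore and the outlier percentages are all "badness" measures,
    a larger PC1 score means worse geometry.
    """

    means: np.ndarray
    sds: np.ndarray
    loadings: np.ndarray  # columns = PCs, rows ordered as GEOMETRY_METRICS
    explained_variance_fractions: np.ndarray
    outlier_ids: list = field(default_factory=list)

    def transform(self, standardized: np.ndarray) -> np.ndarray:
        return standardized @ self.loadings[:, 0]


def fit_geometry_pca(protein_records: pd.DataFrame) -> GeometryPCAModel:
    """Fit the geometry PCA on completed protein-group metrics.

    Deposits beyond the outlier thresholds are excluded from the fit
    (standardisation and loadings) but remain scoreable.  The components
    are the eigenvectors of the covariance matrix of the standardised
    metrics, ordered by explained variance.
    """
    data = protein_records[GEOMETRY_METRICS]
    if data.isna().any().any():
        raise ValueError("geometry metrics must be complete; impute first")
    keep = pd.Series(True, index=protein_records.index)
    for col, threshold in PCA_OUTLIER_THRESHOLDS.items():
        keep &= data[col] <= threshold
    excluded = protein_records.loc[~keep, "pdb_id"].tolist() \
        if "pdb_id" in protein_records.columns else list(protein_records.index[~keep])
    fit_data = data[keep].to_numpy(dtype=float)
    if fit_data.shape[0] < 3:
        raise ValueError("need at least 3 deposits after outlier exclusion")
    means = fit_data.mean(axis=0)
    sds = fit_data.std(axis=0, ddof=1)
    if np.any(sds == 0):
        raise ValueError("zero variance in a geometry metric")
    z = (fit_data - means) / sds
    cov = np.cov(z, rowvar=False, ddof=1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    # Deterministic orientation: PC1 points toward worse geometry (all
    # loadings non-negative for positively correlated badness metrics);
    # remaining PCs get their largest-magnitude loading positive.
    if eigvecs[:, 0].sum() < 0:
        eigvecs[:, 0] = -eigvecs[:, 0]
    for j in range(1, eigvecs.shape[1]):
        pivot = np.argmax(np.abs(eigvecs[:, j]))
        if eigvecs[pivot, j] < 0:
            eigvecs[:, j] = -eigvecs[:, j]
    return GeometryPCAModel(
        means=means,
        sds=sds,
        loadings=eigvecs,
        explained_variance_fractions=eigvals / eigvals.sum(),
        outlier_ids=excluded,
    )


def score_geometry(model: GeometryPCAModel, records: pd.DataFrame) -> np.ndarray:
    """PC1 geometry scores (higher = worse) for completed protein-group rows."""
    data = records[GEOMETRY_METRICS].to_numpy(dtype=float)
    if np.isnan(data).any():
        raise ValueError(
            "geometry metrics incomplete or inapplicable; the geometry PCA "
            "only scores protein-group deposits"
        )
    z = (data - model.means) / model.sds
    return model.transform(z)


def compute_q1(
    records: pd.DataFrame,
    pca: GeometryPCAModel | None = None,
    convention: str = "inclusive",
) -> pd.DataFrame:
    """Composite quality scores and percentiles for a completed deposit table.

    Component percentiles are computed within each molecule group over the
    full table.  Returns one row per deposit with the component percentiles,
    both composite variants (``q1`` averaging, ``q1_min`` minimum), and
    their group-wise percentiles ``p_q1`` / ``p_q1_min``.  If ``pca`` is
    None a geometry PCA is fitted on the protein group.
    """
    required = ["r_free", "rsrz_outliers", "clashscore"]
    if records[required].isna().any().any():
        raise ValueError("metrics incomplete; impute before scoring")

    out = pd.DataFrame(index=records.index)
    out["pdb_id"] = records.get("pdb_id", pd.Series(records.index, index=records.index))
    protein = protein_group_mask(records)
    out["group"] = np.where(protein, "protein", "nucleic")

    for col in ["p_rfree", "p_rsrz", "p_geom", "q1", "q1_min", "p_q1", "p_q1_min"]:
        out[col] = np.nan

    fitted_pca = pca
    for group, mask in (("protein", protein), ("nucleic", ~protein)):
        if not mask.any():
            continue
        sub = records[mask]
        p_rfree = percentile_rank(sub["r_free"], better="lower", convention=convention)
        p_rsrz = percentile_rank(sub["rsrz_outliers"], better="lower", convention=convention)
        if group == "protein":
            if fitted_pca is None:
                fitted_pca = fit_geometry_pca(sub)
            pc1 = score_geometry(fitted_pca, sub)
            p_geom = percentile_rank(pc1, better="lower", convention=convention)
        else:
            p_geom = percentile_rank(sub["clashscore"], better="lower", convention=convention)
        components = np.column_stack([p_rfree, p_rsrz, p_geom])
        q1 = components.mean(axis=1)
        q1_min = components.min(axis=1)
        out.loc[mask, "p_rfree"] = p_rfree
        out.loc[mask, "p_rsrz"] = p_rsrz
        out.loc[mask, "p_geom"] = p_geom
        out.loc[mask, "q1"] = q1
        out.loc[mask, "q1_min"] = q1_min
        out.loc[mask, "p_q1"] = percentile_rank(q1, better="higher", convention=convention)
        out.loc[mask, "p_q1_min"] = percentile_rank(q1_min, better="higher", convention=convention)

    out.attrs["pca"] = fitted_pca
    out.attrs["convention"] = convention
    return out


def q1p_approx(p_rfree, p_rsrz, p_clash, p_rama, p_rota) -> np.ndarray:
    """PCA-free approximation of the protein composite score.

    Exploits the near-equal PC1 loadings of the three geometry metrics:
    their percentiles enter with equal weight 1/3 in place of the PC1
    percentile:

        Q1p ≈ (P_Rfree + P_%RSRZ + (P_Clash + P_Rama + P_Rota)/3) / 3
    """
    arrays = [np.asarray(a, dtype=float) for a in (p_rfree, p_rsrz, p_clash, p_rama, p_rota)]
    for arr in arrays:
        if np.any((arr <= 0) | (arr > 100)):
            raise ValueError("component percentiles must lie in (0, 100]")
    p_rfree, p_rsrz, p_clash, p_rama, p_rota = arrays
    return (p_rfree + p_rsrz + (p_clash + p_rama + p_rota) / 3.0) / 3.0
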