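"""Synthetic deposit tables with the statistical structure the analysis assumes.

The generator draws a latent per-deposit quality from deposition year,
resolution, a journal offset, and Gaussian noise, then maps it through a
Gaussian copula onto each metric's marginal distribution: right-skewed
lognormals for clashscore and the outlier percentages, joint Gaussians for
R and R_free with a configurable correlation.  Marginal means/SDs and
per-metric missingness rates default to the archive-wide values of the real
PDB snapshot the package analyses.  RSRZ missingness is concentrated in early
years (the metric postdates the archive) while averaging its overall rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from pdbq.ingest import METRIC_COLUMNS, PROTEIN_ONLY_METRICS, TO_BE_PUBLISHED

#: Archive-wide metric means and standard deviations (percent units for
#: outlier rates and R factors; clashes per 1000 atoms for clashscore).
DEFAULT_MARGINALS: dict[str, tuple[float, float]] = {
    "clashscore": (8.05, 9.11),
    "rama_outliers": (0.49, 1.26),
    "rota_outliers": (3.26, 3.65),
    "rsrz_outliers": (4.05, 4.06),
    "r_free": (23.35, 3.82),
    "r_work": (19.31, 3.25),
}

#: Archive-wide fractions of missing values per metric.
DEFAULT_MISSING_FRACTIONS: dict[str, float] = {
    "clashscore": 0.0010,
    "rama_outliers": 0.0169,
    "rota_outliers": 0.0172,
    "rsrz_outliers": 0.0956,
    "r_free": 0.0429,
    "r_work": 0.0239,
}

_LOGNORMAL_METRICS = ["clashscore", "rama_outliers", "rota_outliers", "rsrz_outliers"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic PDB snapshot.

    Defaults reproduce the archive-wide marginal moments and missingness
    rates; the latent-quality effects (year drift, resolution dependence,
    journal offsets) default to magnitudes that produce the qualitative
    trends the analysis is designed to detect.
    """

    n_deposits: int = 10_000
    seed: int = 0
    year_range: tuple[int, int] = (1972, 2019)
    metric_marginals: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_MARGINALS)
    )
    missing_fractions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MISSING_FRACTIONS)
    )
    r_rfree_correlation: float = 0.9
    #: copula loading of each metric on the latent quality (0 = independent).
    quality_loading: float = 0.65
    #: latent-quality improvement per deposition year, in latent SD units.
    year_quality_slope: float = 0.03
    #: latent-quality worsening per Å of resolution, in latent SD units.
    resolution_effect: float = 0.8
    n_journals: int = 40
    journal_effect_sd: float = 0.2
    nucleic_fraction: float = 0.06
    complex_fraction: float = 0.05
    tbp_fraction: float = 0.16
    sg_fraction: float = 0.09
    #: early-years multiplier for RSRZ missingness (rate renormalised so the
    #: overall fraction still matches the configured value).
    rsrz_early_weight: float = 4.0
    rsrz_early_cutoff: int = 1995

    def __post_init__(self) -> None:
        if self.n_deposits < 0:
            raise ValueError("n_deposits must be >= 0")
        if not 0 < self.r_rfree_correlation < 1:
            raise ValueError("r_rfree_correlation must be in (0, 1)")
        if self.quality_loading**2 > self.r_rfree_correlation:
            raise ValueError("quality_loading^2 must not exceed r_rfree_correlation")
        for name, frac in self.missing_fractions.items():
            if not 0 <= frac <= 1:
                raise ValueError(f"missing fraction for {name} outside [0, 1]")
        for name, (mean, sd) in self.metric_marginals.items():
            if sd < 0:
                raise ValueError(f"negative SD for {name}")
        for frac in (self.nucleic_fraction, self.complex_fraction,
                     self.tbp_fraction, self.sg_fraction):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Moment-matched (mu, sigma) of a lognormal with the given mean and SD."""
    sigma2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - sigma2 / 2, np.sqrt(sigma2)


def _pdb_ids(n: int) -> np.ndarray:
    digits = "0123456789ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    ids = np.empty(n, dtype=object)
    for i in range(n):
        head = 1 + i // 46656
        tail = i % 46656
        ids[i] = f"{head}{digits[tail // 1296]}{digits[tail // 36 % 36]}{digits[tail % 36]}"
    return ids


def generate_deposits(
    config: SyntheticConfig,
    journal_offsets: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Draw a synthetic deposit table; byte-identical for identical inputs.

    All random draws are made independently of ``journal_offsets``, so
    regenerating with different offsets perturbs only the latent quality
    (and hence the metric values), never the noise, dates, or assignments.

    The returned frame carries the canonical deposit columns plus ``year``
    and a diagnostic ``latent_quality`` column (standardised; higher is
    better) that downstream analytics ignore.
    """
    cfg = config
    n = cfg.n_deposits
    rng = np.random.default_rng(cfg.seed)
    y0, y1 = cfg.year_range

    years = rng.integers(y0, y1 + 1, size=n)
    day_offset = rng.integers(0, 365, size=n)
    dates = pd.to_datetime(years.astype(str)) + pd.to_timedelta(day_offset, unit="D")

    # Resolution: year-conditioned lognormal centred near the archive mean,
    # drifting slightly sharper over time.
    mu_res, sig_res = _lognormal_params(2.13, 0.56)
    year_c = years - (y0 + y1) / 2
    resolution = np.exp(mu_res - 0.002 * year_c + sig_res * rng.standard_normal(n))
    resolution = np.clip(resolution, 0.5, 6.0)

    u = rng.random(n)
    molecule_class = np.where(
        u < cfg.nucleic_fraction,
        "nucleic_acid",
        np.where(u < cfg.nucleic_fraction + cfg.complex_fraction, "complex", "protein"),
    )
    structural_genomics = rng.random(n) < cfg.sg_fraction

    journal_names = [f"J. Synth. Res. {i + 1:03d}" for i in range(cfg.n_journals)]
    issns = {name: f"{1000 + i:04d}-{5000 + i:04d}" for i, name in enumerate(journal_names)}
    weights = 1.0 / np.arange(1, cfg.n_journals + 1)
    weights /= weights.sum()
    journal_idx = rng.choice(cfg.n_journals, size=n, p=weights)
    base_offsets = dict(zip(journal_names, rng.normal(0.0, cfg.journal_effect_sd, cfg.n_journals)))
    tbp = rng.random(n) < cfg.tbp_fraction
    journals = np.where(tbp, TO_BE_PUBLISHED, np.asarray(journal_names, dtype=object)[journal_idx])

    offsets = dict(base_offsets)
    offsets[TO_BE_PUBLISHED] = 0.0
    if journal_offsets:
        unknown = set(journal_offsets) - set(offsets)
        if unknown:
            raise ValueError(f"unknown journals in effect table: {sorted(unknown)}")
        for name, extra in journal_offsets.items():
            offsets[name] += extra

    noise = rng.standard_normal(n)
    per_deposit_offset = np.array([offsets[j] for j in journals])
    quality_raw = (
        cfg.year_quality_slope * (years - (y0 + y1) / 2)
        - cfg.resolution_effect * (resolution - 2.13)
        + per_deposit_offset
        + noise
    )
    scale = quality_raw.std(ddof=0) if n > 1 else 1.0
    quality = (quality_raw - quality_raw.mean()) / (scale or 1.0)

    a = cfg.quality_loading
    b_indep = np.sqrt(1 - a**2)
    # Shared refinement-residual factor gives R/R_free their high correlation.
    shared = rng.standard_normal(n)
    b_shared = np.sqrt(cfg.r_rfree_correlation - a**2)
    c_resid = np.sqrt(1 - cfg.r_rfree_correlation)

    df = pd.DataFrame(
        {
            "pdb_id": _pdb_ids(n),
            "deposition_date": dates,
            "resolution": np.round(resolution, 2),
            "molecule_class": molecule_class,
            "structural_genomics": structural_genomics,
            "journal_raw": journals,
            "issn": np.where(tbp, "", pd.Series(journals).map(issns).fillna("")),
        }
    )

    for metric in _LOGNORMAL_METRICS:
        mean, sd = cfg.metric_marginals[metric]
        mu, sigma = _lognormal_params(mean, sd)
        latent = -a * quality + b_indep * rng.standard_normal(n)
        values = np.exp(mu + sigma * latent)
        if metric != "clashscore":
            values = np.minimum(values, 100.0)
        df[metric] = np.round(values, 2)

    for metric in ("r_free", "r_work"):
        mean, sd = cfg.metric_marginals[metric]
        latent = -a * quality + b_shared * shared + c_resid * rng.standard_normal(n)
        df[metric] = np.round(np.clip(mean + sd * latent, 1e-6, 100 - 1e-6), 2)

    # R_free is never better (lower) than R; enforce the physical ordering
    # softly by swapping the rare inverted pairs.
    inverted = df["r_free"] < df["r_work"]
    df.loc[inverted, ["r_free", "r_work"]] = df.loc[inverted, ["r_work", "r_free"]].values

    # Missingness: independent per metric; RSRZ concentrated in early years.
    for metric, frac in cfg.missing_fractions.items():
        draws = rng.random(n)
        if metric == "rsrz_outliers" and frac > 0 and n > 0:
            w = np.where(years < cfg.rsrz_early_cutoff, cfg.rsrz_early_weight, 1.0)
            rate = np.minimum(frac * w / w.mean(), 1.0)
        else:
            rate = np.full(n, frac)
        df.loc[draws < rate, metric] = np.nan

    nucleic = df["molecule_class"] == "nucleic_acid"
    df.loc[nucleic, PROTEIN_ONLY_METRICS] = np.nan

    df["year"] = years
    df["latent_quality"] = quality
    df.attrs["config"] = cfg
    df.attrs["journal_offsets"] = dict(journal_offsets or {})
    return df


def inject_journal_effects(
    records: pd.DataFrame, effect_table: Mapping[str, float]
) -> pd.DataFrame:
    """Regenerate a synthetic table with per-journal quality offsets added.

    ``records`` must come from :func:`generate_deposits` (the generating
    config travels in ``records.attrs``).  Offsets are added to the latent
    quality before the metric mapping, so everything except the metric
    values — ids, dates, resolutions, journal assignments, missingness —
    is reproduced unchanged.
    """
    cfg = records.attrs.get("config")
    if cfg is None:
        raise ValueError("records were not produced by generate_deposits")
    present = set(records["journal_raw"])
    unknown = set(effect_table) - present
    if unknown:
        raise ValueError(f"unknown journals in effect table: {sorted(unknown)}")
    combined = dict(records.attrs.get("journal_offsets", {}))
    for name, extra in effect_table.items():
        combined[name] = combined.get(name, 0.0) + extra
    return generate_deposits(cfg, journal_offsets=combined)


def write_config(config: SyntheticConfig, path) -> None:
    """Serialise a generator config to YAML."""
    import yaml

    data = {
        k: (list(v) if isinstance(v, tuple) else dict(v) if isinstance(v, Mapping) else v)
        for k, v in config.__dict__.items()
    }
    data["metric_marginals"] = {k: list(v) for k, v in config.metric_marginals.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh)


def read_config(path) -> SyntheticConfig:
    """Load a generator config from YAML."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh)
    if "year_range" in data:
        data["year_range"] = tuple(data["year_range"])
    if "metric_marginals" in data:
        data["metric_marginals"] = {k: tuple(v) for k, v in data["metric_marginals"].items()}
    return SyntheticConfig(**data)
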