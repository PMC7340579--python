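"""Reading and normalising deposit tables, journal names, and bibliometrics.

Deposits live in a :class:`pandas.DataFrame` with one row per PDB entry and
the canonical columns listed in :data:`DEPOSIT_COLUMNS`.  Quality metrics may
be missing (``NaN``); Ramachandran and rotamer outliers are *inapplicable* —
not merely missing — for nucleic-acid-only deposits and are kept as ``NaN``
with the distinction recoverable through :func:`inapplicable_mask`.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The five quality metrics entering the composite score.
METRIC_COLUMNS = [
    "clashscore",
    "rama_outliers",
    "rota_outliers",
    "rsrz_outliers",
    "r_free",
]

#: Supporting variables used by the imputation stage; never missing.
SUPPORT_COLUMNS = ["r_work", "resolution", "year"]

#: Metrics that only make sense for deposits containing protein chains.
PROTEIN_ONLY_METRICS = ["rama_outliers", "rota_outliers"]

MANDATORY_COLUMNS = ["pdb_id", "deposition_date", "resolution", "molecule_class"]

DEPOSIT_COLUMNS = [
    "pdb_id",
    "deposition_date",
    "resolution",
    "molecule_class",
    "structural_genomics",
    "journal_raw",
    "issn",
    "clashscore",
    "rama_outliers",
    "rota_outliers",
    "rsrz_outliers",
    "r_free",
    "r_work",
]

MOLECULE_CLASSES = ("protein", "nucleic_acid", "complex")

#: Placeholder venue the PDB uses for deposits without a primary citation.
TO_BE_PUBLISHED = "To be published"

#: Legal value ranges; metrics outside these on input are rejected, imputed
#: values are clipped into them.  Bounds are (low, high, low_open, high_open).
METRIC_RANGES: dict[str, tuple[float, float]] = {
    "clashscore": (0.0, np.inf),
    "rama_outliers": (0.0, 100.0),
    "rota_outliers": (0.0, 100.0),
    "rsrz_outliers": (0.0, 100.0),
    "r_free": (0.0, 100.0),
    "r_work": (0.0, 100.0),
}


def classify_molecule(entity_composition: Iterable[str]) -> str:
    """Assign a deposit to a molecule class from its declared polymer types.

    Protein-only compositions are ``protein``, nucleic-acid-only are
    ``nucleic_acid``, mixed compositions are ``complex``.  Complexes are
    scored together with proteins throughout, since all five quality metrics
    are defined for them.
    """
    kinds = set()
    for name in entity_composition:
        token = str(name).strip().lower()
        if not token:
            continue
        if token in {"protein", "polypeptide", "polypeptide(l)", "polypeptide(d)"}:
            kinds.add("protein")
        elif token in {"dna", "rna", "na", "nucleic_acid", "nucleic acid",
                       "polyribonucleotide", "polydeoxyribonucleotide"}:
            kinds.add("nucleic")
        else:
            raise ValueError(f"unrecognised polymer type: {name!r}")
    if not kinds:
        raise ValueError("no polymer type declared")
    if kinds == {"protein"}:
        return "protein"
    if kinds == {"nucleic"}:
        return "nucleic_acid"
    return "complex"


def protein_group_mask(df: pd.DataFrame) -> pd.Series:
    """True for deposits scored in the protein group (proteins + complexes)."""
    return df["molecule_class"].isin(["protein", "complex"])


def inapplicable_mask(df: pd.DataFrame) -> pd.DataFrame:
    """Boolean frame marking structurally inapplicable metric cells.

    Ramachandran and rotamer outliers are undefined for nucleic-acid-only
    deposits; such cells are not counted as missing anywhere in the package.
    """
    mask = pd.DataFrame(False, index=df.index, columns=METRIC_COLUMNS)
    nucleic = df["molecule_class"] == "nucleic_acid"
    for col in PROTEIN_ONLY_METRICS:
        mask.loc[nucleic, col] = True
    return mask


def _normalize_venue(raw: str) -> str:
    """Case-fold and strip punctuation/whitespace for journal-name matching."""
    s = re.sub(r"[^\w\s]", " ", str(raw))
    return re.sub(r"\s+", " ", s).strip().casefold()


@dataclass
class JournalAliasMap:
    """Mapping from raw primary-citation strings to canonical journal names.

    Lookup keys are normalised (case-folded, punctuation stripped) so that
    trivially different spellings of one venue collapse without an explicit
    entry.  Canonical names map to themselves, which makes cleaning
    idempotent.
    """

    entries: dict[str, str] = field(default_factory=dict)
    issn: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        normalized = {}
        for raw, canonical in self.entries.items():
            normalized[_normalize_venue(raw)] = canonical
        for canonical in list(normalized.values()):
            normalized.setdefault(_normalize_venue(canonical), canonical)
        self.entries = normalized

    @classmethod
    def from_csv(cls, path: str | Path) -> "JournalAliasMap":
        """Load a 2-column CSV (raw, canonical) with an optional issn column."""
        table = pd.read_csv(path, dtype=str)
        required = {"raw", "canonical"}
        if not required.issubset(table.columns):
            raise ValueError(f"alias map needs columns {sorted(required)}")
        entries = dict(zip(table["raw"], table["canonical"]))
        issn = {}
        if "issn" in table.columns:
            for canonical, code in zip(table["canonical"], table["issn"]):
                if isinstance(code, str) and code.strip():
                    issn[canonical] = code.strip()
        return cls(entries=entries, issn=issn)

    def lookup(self, raw: str) -> str | None:
        return self.entries.get(_normalize_venue(raw))


def clean_journal_names(
    records: pd.DataFrame, alias_map: JournalAliasMap | None = None
) -> pd.DataFrame:
    """Attach a canonical ``journal`` column to the deposit table.

    Raw venue strings found in the alias map are replaced by their canonical
    name (and ISSN where the map provides one); unmapped strings are
    normalised to a title-cased, punctuation-stripped form and passed
    through.  Deposits without a citation get the literal
    ``"To be published"``.  The operation is total and idempotent.
    """
    alias_map = alias_map or JournalAliasMap()
    df = records.copy()
    source = df["journal"] if "journal" in df.columns and "journal_raw" not in df.columns \
        else df.get("journal_raw", pd.Series("", index=df.index))

    def canonicalize(raw: object) -> str:
        if raw is None or (isinstance(raw, float) and np.isnan(raw)):
            return TO_BE_PUBLISHED
        text = str(raw).strip()
        if not text or _normalize_venue(text) == _normalize_venue(TO_BE_PUBLISHED):
            return TO_BE_PUBLISHED
        mapped = alias_map.lookup(text)
        if mapped is not None:
            return mapped
        # Normalisation-only fallback: collapse case/punctuation variants.
        return " ".join(w.upper() if w.isupper() else w.capitalize()
                        for w in _normalize_venue(text).split())

    df["journal"] = [canonicalize(v) for v in source]
    if alias_map.issn:
        mapped_issn = df["journal"].map(alias_map.issn)
        if "issn" in df.columns:
            df["issn"] = mapped_issn.fillna(df["issn"])
        else:
            df["issn"] = mapped_issn
    return df


def _coerce_dates(raw: pd.Series) -> pd.Series:
    """Parse deposition dates, accepting bare years (mapped to Jan 1)."""
    numeric = pd.to_numeric(raw, errors="coerce")
    is_year = numeric.notna() & (numeric == numeric.round()) & numeric.between(1900, 2100)
    parsed = pd.to_datetime(raw.where(~is_year), errors="coerce", format="mixed")
    years = pd.to_datetime(
        numeric.where(is_year).astype("Int64").astype(str), format="%Y", errors="coerce"
    )
    return parsed.fillna(years)


def read_deposit_table(
    path: str | Path,
    schema_config: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read and validate a per-deposit metrics table (CSV or TSV).

    Parameters
    ----------
    path
        Input file; ``.tsv``/``.tab`` extensions switch to tab separation.
        Missing metric values are encoded as empty cells.
    schema_config
        Optional mapping from canonical column names to the file's column
        names (e.g. ``{"pdb_id": "PDB ID"}``).

    Returns
    -------
    DataFrame with the canonical deposit columns plus ``year``.  Rows failing
    validation are dropped, logged, and reported in ``df.attrs["rejected"]``
    as a frame with a per-row ``reason``.  Absence of a mandatory column is a
    hard error.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=True)
    if schema_config:
        rename = {v: k for k, v in schema_config.items()}
        raw = raw.rename(columns=rename)

    missing_cols = [c for c in MANDATORY_COLUMNS if c not in raw.columns]
    if missing_cols:
        raise ValueError(f"mandatory columns absent: {missing_cols}")

    df = pd.DataFrame(index=raw.index)
    df["pdb_id"] = raw["pdb_id"].astype(str).str.strip().str.upper()
    df["deposition_date"] = _coerce_dates(raw["deposition_date"])
    df["resolution"] = pd.to_numeric(raw["resolution"], errors="coerce")
    df["molecule_class"] = raw["molecule_class"].astype(str).str.strip().str.lower()
    if "structural_genomics" in raw.columns:
        df["structural_genomics"] = (
            raw["structural_genomics"].astype(str).str.strip().str.lower()
            .isin(["1", "true", "yes", "y"])
        )
    else:
        df["structural_genomics"] = False
    df["journal_raw"] = raw.get("journal_raw", pd.Series("", index=raw.index)).fillna("")
    df["issn"] = raw.get("issn", pd.Series("", index=raw.index)).fillna("")
    for col in METRIC_COLUMNS + ["r_work"]:
        df[col] = pd.to_numeric(raw.get(col), errors="coerce")

    reasons = pd.Series("", index=df.index, dtype=str)

    def flag(mask: pd.Series, reason: str) -> None:
        reasons[mask & (reasons == "")] = reason

    flag(~df["pdb_id"].str.fullmatch(r"[0-9A-Z]{4}"), "malformed pdb_id")
    flag(df["pdb_id"].duplicated(keep="first"), "duplicate pdb_id")
    flag(df["deposition_date"].isna(), "unparseable deposition date")
    flag(df["resolution"].isna() | (df["resolution"] <= 0), "non-positive resolution")
    flag(~df["molecule_class"].isin(MOLECULE_CLASSES), "unknown molecule class")
    for col, (lo, hi) in METRIC_RANGES.items():
        bad = df[col].notna() & ~df[col].between(lo, hi)
        flag(bad, f"{col} out of range")

    rejected = df[reasons != ""].assign(reason=reasons[reasons != ""])
    if len(rejected):
        logger.warning("rejected %d malformed rows from %s", len(rejected), path)
    df = df[reasons == ""].reset_index(drop=True)

    # Protein-only metrics are inapplicable, not missing, for nucleic acids.
    nucleic = df["molecule_class"] == "nucleic_acid"
    df.loc[nucleic, PROTEIN_ONLY_METRICS] = np.nan
    df["year"] = df["deposition_date"].dt.year
    df.attrs["rejected"] = rejected
    return df


def write_deposit_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a deposit table; missing values become empty cells.

    Together with :func:`read_deposit_table` this round-trips all present
    values and preserves missingness.
    """
    out = df.copy()
    out["deposition_date"] = pd.to_datetime(out["deposition_date"]).dt.strftime("%Y-%m-%d")
    cols = [c for c in DEPOSIT_COLUMNS if c in out.columns]
    cols += [c for c in out.columns if c not in cols and c != "year"]
    sep = "\t" if str(path).lower().endswith((".tsv", ".tab")) else ","
    out[cols].to_csv(path, index=False, sep=sep)


def read_bibliometrics(path: str | Path) -> pd.DataFrame:
    """Read a per-journal-year bibliometric table (issn, year, ipp, snip).

    IPP is the impact per publication (a 3-year citation average); SNIP its
    field-normalised variant.  Rows with malformed or negative indicator
    values are rejected and logged; duplicate (issn, year) pairs are an
    error.
    """
    table = pd.read_csv(path, dtype=str)
    required = {"issn", "year", "ipp", "snip"}
    if not required.issubset(table.columns):
        raise ValueError(f"bibliometrics table needs columns {sorted(required)}")
    df = pd.DataFrame(
        {
            "issn": table["issn"].astype(str).str.strip(),
            "year": pd.to_numeric(table["year"], errors="coerce"),
            "ipp": pd.to_numeric(table["ipp"], errors="coerce"),
            "snip": pd.to_numeric(table["snip"], errors="coerce"),
        }
    )
    bad = (
        df[["year", "ipp", "snip"]].isna().any(axis=1)
        | (df["ipp"] < 0)
        | (df["snip"] < 0)
        | (df["year"] != df["year"].round())
    )
    if bad.any():
        logger.warning("rejected %d malformed bibliometric rows", int(bad.sum()))
    df = df[~bad].reset_index(drop=True)
    df["year"] = df["year"].astype(int)
    if df.duplicated(subset=["issn", "year"]).any():
        raise ValueError("duplicate (issn, year) pairs in bibliometrics table")
    return df
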