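"""Reading and validation of GWAS summary-statistic tables.

Two kinds of table are read: an exposure *instrument* (one row per SNP with
its per-allele effect on the exposure, in SD-of-exposure units) and outcome
summary statistics (per-allele log-odds effects from a case-control GWAS).
Both are tab-delimited text with a header row; gzip compression is accepted.
Column names are remappable so the common dialects (effect_allele vs A1,
beta vs b, ...) can be read without editing files.
"""

from __future__ import annotations

import logging
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("mrkit")

#: canonical column order of an association table
CANONICAL_COLUMNS = ["rsid", "effect_allele", "other_allele", "eaf", "beta", "se"]

_VALID_BASES = frozenset("ACGT")


class ValidationError(ValueError):
    """A row violates an association-table invariant (bad allele, SE <= 0, ...)."""


class ConfigurationError(ValueError):
    """The file/column configuration is wrong (missing column, bad mapping)."""


def _apply_column_map(df: pd.DataFrame, column_map: Mapping[str, str] | None,
                      path: str | Path) -> pd.DataFrame:
    """Rename file columns to canonical names; ``column_map`` maps canonical -> file."""
    if column_map:
        missing_src = [v for v in column_map.values() if v not in df.columns]
        if missing_src:
            raise ConfigurationError(
                f"{path}: mapped column(s) {missing_src} not present in file "
                f"(available: {list(df.columns)})")
        df = df.rename(columns={v: k for k, v in column_map.items()})
    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns and c != "eaf"]
    if missing:
        raise ConfigurationError(
            f"{path}: required column(s) {missing} not found; "
            f"provide a column map (canonical name -> file column)")
    if "eaf" not in df.columns:
        df["eaf"] = np.nan
    return df


def _validate_associations(df: pd.DataFrame, path: str | Path) -> pd.DataFrame:
    df = df.copy()
    df["rsid"] = df["rsid"].astype(str).str.strip()
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.strip().str.upper()
    for col in ("eaf", "beta", "se"):
        df[col] = pd.to_numeric(df[col], errors="coerce")

    if (df["rsid"] == "").any() or df["rsid"].str.lower().eq("nan").any():
        raise ValidationError(f"{path}: empty rsID in table")
    dup = df["rsid"].str.lower().duplicated()
    if dup.any():
        raise ValidationError(
            f"{path}: duplicate rsID(s): {sorted(df.loc[dup, 'rsid'].unique())}")
    bad_allele = ~(df["effect_allele"].isin(_VALID_BASES)
                   & df["other_allele"].isin(_VALID_BASES))
    if bad_allele.any():
        raise ValidationError(
            f"{path}: alleles must be single bases A/C/G/T for "
            f"{df.loc[bad_allele, 'rsid'].tolist()}")
    same = df["effect_allele"] == df["other_allele"]
    if same.any():
        raise ValidationError(
            f"{path}: effect and other allele identical for "
            f"{df.loc[same, 'rsid'].tolist()}")
    bad_se = ~(df["se"] > 0)
    if bad_se.any():
        raise ValidationError(
            f"{path}: non-positive or missing standard error for "
            f"{df.loc[bad_se, 'rsid'].tolist()}")
    if df["beta"].isna().any():
        raise ValidationError(
            f"{path}: missing beta for {df.loc[df['beta'].isna(), 'rsid'].tolist()}")
    bad_eaf = df["eaf"].notna() & ~df["eaf"].between(0, 1)
    if bad_eaf.any():
        raise ValidationError(
            f"{path}: effect-allele frequency outside [0,1] for "
            f"{df.loc[bad_eaf, 'rsid'].tolist()}")
    return df[CANONICAL_COLUMNS].reset_index(drop=True)


def read_instrument(path: str | Path,
                    column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read an exposure-instrument table.

    Parameters
    ----------
    path
        Tab-delimited text file (optionally gzip-compressed) with a header row.
    column_map
        Optional mapping from canonical column names
        (``rsid, effect_allele, other_allele, eaf, beta, se``) to the names
        used in the file.

    Returns
    -------
    pandas.DataFrame
        One validated row per SNP, in file order, with canonical columns.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"instrument file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    df = _apply_column_map(df, column_map, path)
    if len(df) == 0:
        logger.warning("instrument file %s contains a header but no data rows", path)
        return df[CANONICAL_COLUMNS]
    df = _validate_associations(df, path)
    logger.info("read %d instrument SNPs from %s", len(df), path)
    return df


def read_outcome_stats(path: str | Path,
                       wanted_rsids: Iterable[str],
                       column_map: Mapping[str, str] | None = None,
                       ) -> tuple[pd.DataFrame, list[str]]:
    """Read outcome summary statistics, keeping only the instrument's SNPs.

    rsID matching is case-insensitive. Returns the retained rows (file order)
    and the sorted list of wanted rsIDs absent from the file. Raises
    :class:`ValidationError` if *none* of the wanted rsIDs are present.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"outcome summary-statistics file not found: {path}")
    wanted = {str(r).strip().lower(): str(r).strip() for r in wanted_rsids}
    if not wanted:
        raise ConfigurationError("wanted_rsids must be non-empty")
    df = pd.read_csv(path, sep="\t", dtype=str)
    df = _apply_column_map(df, column_map, path)
    keep = df["rsid"].astype(str).str.strip().str.lower().isin(wanted)
    df = df.loc[keep].reset_index(drop=True)
    if len(df) == 0:
        raise ValidationError(
            f"{path}: none of the {len(wanted)} instrument rsIDs are present")
    df = _validate_associations(df, path)
    found = set(df["rsid"].str.lower())
    missing = sorted(orig for low, orig in wanted.items() if low not in found)
    if missing:
        logger.warning("%d instrument SNP(s) absent from %s: %s",
                       len(missing), path, missing)
    logger.info("matched %d / %d instrument SNPs in %s", len(df), len(wanted), path)
    return df, missing


@lru_cache(maxsize=1)
def _urate_instrument_cached() -> pd.DataFrame:
    with resources.as_file(
            resources.files("mrkit").joinpath("data/urate_instrument.tsv")) as p:
        return read_instrument(p)


def load_urate_instrument() -> pd.DataFrame:
    """The packaged 31-SNP plasma-urate instrument.

    Lead SNPs of 31 independent urate-associated loci from European-ancestry
    GWAS meta-analyses; ``beta`` is the SD change in plasma urate per copy of
    the effect allele. This is the instrument used for the urate ->
    Parkinson's disease analysis the package reproduces. Returns a fresh
    copy; the underlying parse is cached.
    """
    return _urate_instrument_cached().copy()
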