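"""Patient cohort table: reading, validation, and age subsetting.

The analysis operates on a table with one row per muscle biopsy carrying the
age at biopsy (*ABx*, decimal years) and the image-derived morphometric
variables: mean myofibre size (*Mean*, um^2), its standard deviation (*Sd*)
and coefficient of variation (*Cov*), myofibre density (*MFD*, fibres/mm^2),
and the area fractions myofibre area (*MFA*), fatty degeneration (*Fat*) and
connective/fibrotic tissue (*CFA*), each on the 0-100 percent scale.

The packaged 38-patient reference cohort ships as ``data/table1_cohort.csv``
and is loaded with :func:`load_reference_cohort`.  Ages in that file are the
published one-decimal values; all downstream results in this package are
defined relative to those printed ages.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import IO, Iterable, Union

import numpy as np
import pandas as pd

logger = logging.getLogger("mfdbp")

__all__ = [
    "CohortError",
    "SchemaError",
    "ValidationError",
    "Cohort",
    "REQUIRED_COLUMNS",
    "OPTIONAL_COLUMNS",
    "parse_cohort_table",
    "load_reference_cohort",
    "compute_exact_age",
    "display_age",
    "subset_by_age",
    "write_cohort",
]


class CohortError(Exception):
    """Base class for cohort input problems."""


class SchemaError(CohortError):
    """A required column is missing or a value cannot be parsed."""


class ValidationError(CohortError):
    """Rows violate the cohort invariants (bounds, consistency checks)."""


#: Columns that must be present in any cohort file.
REQUIRED_COLUMNS = [
    "participant",
    "abx_years",
    "biopsy_year",
    "mean_mfs_um2",
    "cov_mfs",
    "sd_mfs_um2",
    "mfd_fibres_mm2",
    "mfa_pct",
    "fat_pct",
    "cfa_pct",
]

#: Columns that may be absent; absent means "not measured", never imputed.
OPTIONAL_COLUMNS = ["nfa_pct", "rfa_pct", "opaque_pct", "intn_pct", "genotype"]

_NUMERIC_COLUMNS = REQUIRED_COLUMNS[1:] + ["nfa_pct", "rfa_pct", "opaque_pct", "intn_pct"]
_PCT_COLUMNS = ["mfa_pct", "fat_pct", "cfa_pct", "nfa_pct", "rfa_pct", "opaque_pct", "intn_pct"]

#: Relative tolerance for the Cov = Sd / Mean consistency check.  The printed
#: table rounds each quantity independently, so 2% absorbs rounding error.
COV_CONSISTENCY_RTOL = 0.02


@dataclass
class Cohort:
    """An ordered collection of patient records.

    ``records`` is a DataFrame sorted ascending by ``abx_years`` (ties broken
    by ``participant``) with unique participant identifiers.  ``provenance``
    records where the table came from (``"fixture"``, ``"user file"`` or
    ``"synthetic"``).
    """

    records: pd.DataFrame
    provenance: str = "user file"

    def __post_init__(self) -> None:
        df = self.records
        if df["participant"].duplicated().any():
            dupes = df.loc[df["participant"].duplicated(), "participant"].tolist()
            raise ValidationError(f"duplicate participant ids: {dupes}")
        df = df.sort_values(["abx_years", "participant"], kind="mergesort")
        self.records = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def ages(self) -> np.ndarray:
        return self.records["abx_years"].to_numpy(dtype=float)

    @property
    def mfd(self) -> np.ndarray:
        return self.records["mfd_fibres_mm2"].to_numpy(dtype=float)

    def variable(self, name: str) -> np.ndarray:
        if name not in self.records.columns:
            raise SchemaError(f"unknown variable {name!r}")
        return self.records[name].to_numpy(dtype=float)


def _validate(df: pd.DataFrame) -> None:
    problems: list[str] = []
    positive = ["abx_years", "mfd_fibres_mm2", "mean_mfs_um2"]
    for col in positive:
        bad = df.index[~(df[col] > 0)].tolist()
        if bad:
            problems.append(f"{col} must be > 0 (rows {bad})")
    for col in ["sd_mfs_um2", "cov_mfs"]:
        bad = df.index[~(df[col] >= 0)].tolist()
        if bad:
            problems.append(f"{col} must be >= 0 (rows {bad})")
    for col in _PCT_COLUMNS:
        if col not in df.columns:
            continue
        vals = df[col]
        bad = df.index[vals.notna() & ~vals.between(0, 100)].tolist()
        if bad:
            problems.append(f"{col} outside [0, 100] (rows {bad})")
    # Cov should equal Sd / Mean up to independent rounding of the three cells.
    implied = df["sd_mfs_um2"] / df["mean_mfs_um2"]
    rel = (df["cov_mfs"] - implied).abs() / implied.where(implied > 0, np.nan)
    bad = df.index[rel > COV_CONSISTENCY_RTOL].tolist()
    if bad:
        problems.append(
            f"cov_mfs inconsistent with sd/mean beyond {COV_CONSISTENCY_RTOL:.0%} (rows {bad})"
        )
    if problems:
        raise ValidationError("; ".join(problems))


def parse_cohort_table(
    source: Union[str, Path, IO[str], IO[bytes]],
    *,
    provenance: str = "user file",
    sep: str | None = None,
) -> Cohort:
    """Read a delimited cohort table (CSV or TSV) into a validated :class:`Cohort`.

    Parameters
    ----------
    source
        Path or open text/binary stream with a header row.
    provenance
        Label recorded on the returned cohort.
    sep
        Field delimiter; autodetected from the header when ``None``.

    Raises
    ------
    SchemaError
        A required column is absent or a numeric cell fails to parse.
    ValidationError
        One or more rows violate the cohort invariants; the message lists
        the offending rows.
    CohortError
        The table contains no data rows.
    """
    import csv

    try:
        df = pd.read_csv(source, sep=sep, engine="python", skip_blank_lines=True)
    except (pd.errors.EmptyDataError, csv.Error) as exc:
        raise CohortError("cohort table is empty or undelimited") from exc
    if df.empty:
        raise CohortError("cohort table has a header but no rows")

    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    for col in _NUMERIC_COLUMNS:
        if col not in df.columns:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()].tolist()
        if bad:
            raise SchemaError(f"non-numeric value in column {col!r} at row(s) {bad}")
        df[col] = coerced

    df["participant"] = df["participant"].astype(str)
    _validate(df)
    return Cohort(records=df, provenance=provenance)


def load_reference_cohort() -> Cohort:
    """Load the packaged 38-patient reference cohort."""
    text = resources.files("mfdbp.data").joinpath("table1_cohort.csv").read_text()
    return parse_cohort_table(io.StringIO(text), provenance="fixture")


def compute_exact_age(years: int, months: int) -> float:
    """Decimal age from integer years and months, dividing the year into 12.

    ``compute_exact_age(4, 4)`` is 4.333...; the companion
    :func:`display_age` rounds it to the one-decimal reporting convention
    (4.3).  Full precision is kept internally.
    """
    if years < 0:
        raise ValueError(f"years must be >= 0, got {years}")
    if not 0 <= months <= 11:
        raise ValueError(f"months must be in 0..11, got {months}")
    return years + months / 12.0


def display_age(age: float) -> float:
    """One-decimal reporting convention for ages."""
    return round(age, 1)


def subset_by_age(cohort: Cohort, max_age: float) -> Cohort:
    """Records with ``abx_years`` strictly below ``max_age``, order preserved.

    The primary analysis subset uses ``max_age=11``: a patient at 10.9 years
    is retained, one at 12.8 excluded.  An empty result is legal and logged
    as a warning.
    """
    if max_age <= 0:
        raise ValueError(f"max_age must be > 0, got {max_age}")
    kept = cohort.records[cohort.records["abx_years"] < max_age].reset_index(drop=True)
    logger.info("subset_by_age(%.3g): %d of %d records retained", max_age, len(kept), len(cohort))
    if kept.empty:
        logger.warning("subset_by_age(%.3g) produced an empty cohort", max_age)
    return Cohort(records=kept, provenance=cohort.provenance)


def write_cohort(cohort: Cohort, path: Union[str, Path]) -> None:
    """Write the cohort back to CSV in the canonical column order."""
    cols = [c for c in REQUIRED_COLUMNS + OPTIONAL_COLUMNS if c in cohort.records.columns]
    cohort.records.to_csv(path, columns=cols, index=False)
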