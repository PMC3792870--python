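"""Reading, writing and validation of spot-level array tables and sample sheets.

The on-disk convention is a single flat delimited table (comma- or
tab-separated; the separator is auto-detected from the header line), one row
per quantified spot, mirroring GenePix-style per-spot exports without binding
to a vendor format:

======================  =====================================================
column                  meaning
======================  =====================================================
``slide_id``            physical glass slide the spot was printed on
``subarray_id``         sub-array (incubation chamber) within the slide; one
                        serum sample per sub-array
``sample_id``           sample incubated on the sub-array; empty for buffer
                        blank sub-arrays
``spot_role``           one of ``marker``, ``positive_control``,
                        ``negative_control``, ``blank``
``marker_id``           analyte captured by the spot (empty unless the role
                        is ``marker``)
``replicate_index``     1-based index of the replicate spot
``fg_median``           median foreground fluorescence of the spot (>= 0)
``bg_median``           median local background fluorescence (>= 0)
======================  =====================================================

Marker spots are printed in duplicate, so every ``(subarray_id, marker_id)``
pair must appear exactly twice.  Blank sub-arrays (incubated with blocking
buffer instead of serum) carry an empty ``sample_id`` and ``spot_role=blank``
for every spot.

The sample sheet is a delimited table with columns ``sample_id`` and
``group_label`` (``cancer`` or ``control``); any further numeric column is
treated as an extra single-analyte measurement (for example a CA125 ELISA
concentration in IU/ml) and is carried through to the preprocessed matrix
untouched.
"""
from __future__ import annotations

import logging
import warnings
from pathlib import Path

import pandas as pd

from ._utils import CANCER, CONTROL

log = logging.getLogger(__name__)

SPOT_COLUMNS = [
    "slide_id",
    "subarray_id",
    "sample_id",
    "spot_role",
    "marker_id",
    "replicate_index",
    "fg_median",
    "bg_median",
]
_TEXT_COLUMNS = ["slide_id", "subarray_id", "sample_id", "spot_role", "marker_id"]
SPOT_ROLES = frozenset({"marker", "positive_control", "negative_control", "blank"})
GROUP_LABELS = frozenset({CANCER, CONTROL})


class SchemaError(ValueError):
    """A required column is missing or cannot be typed."""


class ValidationError(ValueError):
    """Table contents violate an invariant of the schema."""


def _detect_sep(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def validate_spot_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate (and type-coerce) a spot table; returns the coerced frame.

    Raises :class:`SchemaError` for missing/mis-typed columns and
    :class:`ValidationError` for content violations (bad roles, negative
    intensities, replicate counts other than 2 per (subarray, marker) pair).
    Row order is preserved.
    """
    missing = [c for c in SPOT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(
            "spot table is missing required column(s): " + ", ".join(missing)
        )
    df = df.copy()
    for c in _TEXT_COLUMNS:
        df[c] = df[c].fillna("").astype(str)
    try:
        df["replicate_index"] = df["replicate_index"].astype(int)
        df["fg_median"] = df["fg_median"].astype(float)
        df["bg_median"] = df["bg_median"].astype(float)
    except (TypeError, ValueError) as exc:
        raise SchemaError(f"could not type spot-table numeric columns: {exc}") from exc

    bad_roles = sorted(set(df["spot_role"]) - SPOT_ROLES)
    if bad_roles:
        raise ValidationError(f"unknown spot_role value(s): {bad_roles}")
    if (df["replicate_index"] < 1).any():
        raise ValidationError("replicate_index must be >= 1")
    n_neg = int(((df["fg_median"] < 0) | (df["bg_median"] < 0)).sum())
    if n_neg:
        raise ValidationError(
            f"{n_neg} row(s) have negative intensities; fg_median and bg_median must be >= 0"
        )

    marker = df[df["spot_role"] == "marker"]
    if (marker["marker_id"] == "").any():
        raise ValidationError("marker spots must carry a marker_id")
    if (marker["sample_id"] == "").any():
        raise ValidationError("marker spots must carry a sample_id")
    counts = marker.groupby(["subarray_id", "marker_id"]).size()
    bad = counts[counts != 2]
    if len(bad):
        pairs = ", ".join(
            f"({sub}, {mk}): {n} spot(s)" for (sub, mk), n in bad.items()
        )
        raise ValidationError(
            "expected exactly 2 replicate spots per (subarray, marker) pair; "
            "offending: " + pairs
        )

    blanks = df[df["spot_role"] == "blank"]
    if (blanks["sample_id"] != "").any():
        raise ValidationError("blank spots must have an empty sample_id")
    return df


def read_spot_table(path, sep: str | None = None) -> pd.DataFrame:
    """Read and validate a spot table from a delimited text file."""
    path = Path(path)
    if sep is None:
        sep = _detect_sep(path)
    df = pd.read_csv(
        path,
        sep=sep,
        dtype={c: str for c in _TEXT_COLUMNS},
        keep_default_na=False,
    )
    return validate_spot_table(df)


def write_spot_table(df: pd.DataFrame, path, sep: str = ",") -> None:
    """Write a spot table; round-trips bit-exactly through :func:`read_spot_table`."""
    cols = SPOT_COLUMNS + [c for c in df.columns if c not in SPOT_COLUMNS]
    df.to_csv(path, sep=sep, index=False, columns=cols)


def read_sample_sheet(path, sep: str | None = None) -> pd.DataFrame:
    """Read a sample sheet (sample_id, group_label, optional analyte columns).

    An empty file yields an empty sheet with a logged warning.  Duplicate
    sample ids or unknown group labels raise :class:`ValidationError`.
    """
    path = Path(path)
    try:
        if sep is None:
            sep = _detect_sep(path)
        df = pd.read_csv(path, sep=sep, dtype={"sample_id": str}, keep_default_na=False)
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=["sample_id", "group_label"])
    if len(df) == 0:
        log.warning("sample sheet %s is empty", path)
        warnings.warn(f"sample sheet {path} is empty", stacklevel=2)
        if "sample_id" not in df.columns:
            df = pd.DataFrame(columns=["sample_id", "group_label"])
        return df
    return validate_sample_sheet(df)


def validate_sample_sheet(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ("sample_id", "group_label") if c not in df.columns]
    if missing:
        raise SchemaError(
            "sample sheet is missing required column(s): " + ", ".join(missing)
        )
    df = df.copy()
    df["sample_id"] = df["sample_id"].astype(str)
    dup = df["sample_id"][df["sample_id"].duplicated()].unique().tolist()
    if dup:
        raise ValidationError(f"duplicate sample_id(s) in sample sheet: {dup}")
    unknown = sorted(set(df["group_label"]) - GROUP_LABELS)
    if unknown:
        raise ValidationError(
            f"unknown group label(s): {unknown}; expected {sorted(GROUP_LABELS)}"
        )
    # any extra column is a per-sample analyte concentration (e.g. CA125, IU/ml)
    for c in df.columns:
        if c not in ("sample_id", "group_label", "age"):
            df[c] = df[c].astype(float)
    return df


def write_sample_sheet(df: pd.DataFrame, path, sep: str = ",") -> None:
    df.to_csv(path, sep=sep, index=False)


def extra_analyte_columns(sheet: pd.DataFrame) -> list[str]:
    """Names of per-sample analyte columns carried by a sample sheet."""
    return [c for c in sheet.columns if c not in ("sample_id", "group_label", "age")]
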