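"""Spot-level preprocessing for antibody arrays.

The pipeline turns per-spot fluorescence medians into a samples x markers
matrix in four fixed steps:

1. **Replicate aggregation** — each analyte is printed in duplicate; the
   value of a (sample, marker) cell is the mean over the two spots of the
   background-subtracted median intensity, with negative differences clamped
   to zero (fluorescence signal cannot be negative).
2. **Positive-control normalization** — each sub-array is rescaled so that
   the mean of its positive-control spots equals a common reference (by
   default the grand mean of all sub-arrays' positive-control means, which
   preserves the overall intensity scale).  This removes slide/sub-array
   scale differences.
3. **Blank-derived detection threshold** — buffer-only blank sub-arrays give
   a limit-of-detection cutoff = mean + k.SD of the blank signals (k = 2 by
   default, sample SD).  Values below the cutoff are non-detections and are
   floored to 1.
4. **Marker filtering** — markers that are non-detections (value 1) in every
   sample carry no information and are dropped.

Extra single-analyte measurements from the sample sheet (e.g. a CA125 ELISA
column, IU/ml) join the matrix after these steps, bypassing array
normalization and flooring — they are not array measurements, and the
downstream split-point scoring is scale-free per marker.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import array_io
from ._utils import as_cancer_mask

log = logging.getLogger(__name__)

FLOOR_VALUE = 1.0


@dataclass(frozen=True)
class BlankModel:
    """Limit-of-detection model from buffer-blank sub-array signals.

    ``cutoff = mean + k * sd`` with the sample (n-1 denominator) SD.
    """

    blank_values: tuple[float, ...]
    k: float
    mean: float
    sd: float
    cutoff: float

    @classmethod
    def from_signals(cls, blank_signals, k: float = 2.0) -> "BlankModel":
        vals = np.asarray(blank_signals, dtype=float)
        if vals.size < 2:
            raise ValueError(
                f"need at least 2 blank signals to compute an SD, got {vals.size}"
            )
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1))
        return cls(
            blank_values=tuple(float(v) for v in vals),
            k=float(k),
            mean=mean,
            sd=sd,
            cutoff=mean + float(k) * sd,
        )


def compute_blank_cutoff(blank_signals, k: float = 2.0) -> BlankModel:
    """Detection threshold from replicate blank sub-array signals.

    Parameters
    ----------
    blank_signals
        One aggregate signal per blank (buffer-only) sub-array; at least 2.
    k
        SD multiplier; the conventional choice is 2.
    """
    return BlankModel.from_signals(blank_signals, k=k)


@dataclass
class MarkerMatrix:
    """Preprocessed samples x markers intensity matrix with group labels.

    ``values`` is indexed by sample_id with one column per marker;
    ``labels`` is a sample-aligned Series of {"cancer", "control"}.
    """

    values: pd.DataFrame
    labels: pd.Series
    floor_value: float = FLOOR_VALUE
    cutoff: float | None = None
    blank_model: BlankModel | None = None
    removed_markers: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.labels = self.labels.reindex(self.values.index)
        if self.labels.isna().any():
            missing = self.values.index[self.labels.isna()].tolist()
            raise ValueError(f"samples without a group label: {missing}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def marker_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def cancer_mask(self) -> np.ndarray:
        return as_cancer_mask(self.labels.to_numpy())

    def subset_markers(self, marker_ids) -> "MarkerMatrix":
        return MarkerMatrix(
            values=self.values[list(marker_ids)].copy(),
            labels=self.labels.copy(),
            floor_value=self.floor_value,
            cutoff=self.cutoff,
            blank_model=self.blank_model,
        )


def write_matrix(matrix: MarkerMatrix, path, sep: str = ",") -> None:
    """Serialize a matrix: columns sample_id, group_label, then markers."""
    out = matrix.values.copy()
    out.insert(0, "group_label", matrix.labels)
    out.index.name = "sample_id"
    out.reset_index().to_csv(path, sep=sep, index=False)


def read_matrix(path, sep: str | None = None) -> MarkerMatrix:
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    df["sample_id"] = df["sample_id"].astype(str)
    df = df.set_index("sample_id")
    labels = df.pop("group_label")
    return MarkerMatrix(values=df.astype(float), labels=labels)


def _clamped_net(spots: pd.DataFrame) -> pd.Series:
    """Background-subtracted intensity, clamped at zero."""
    return (spots["fg_median"] - spots["bg_median"]).clip(lower=0.0)


def aggregate_replicates(spots: pd.DataFrame) -> pd.DataFrame:
    """Average duplicate marker spots into one value per (sample, marker).

    Returns a long frame with columns slide_id, subarray_id, sample_id,
    marker_id, value where value = mean over the two replicate spots of
    max(fg_median - bg_median, 0).  Raises if any (subarray, marker) pair
    does not have exactly 2 replicate spots.
    """
    m = spots[spots["spot_role"] == "marker"].copy()
    counts = m.groupby(["subarray_id", "marker_id"]).size()
    bad = counts[counts != 2]
    if len(bad):
        pairs = ", ".join(f"({sub}, {mk})" for sub, mk in bad.index)
        raise array_io.ValidationError(
            "replicate aggregation needs exactly 2 spots per (subarray, marker); "
            "offending pair(s): " + pairs
        )
    m["net"] = _clamped_net(m)
    agg = (
        m.groupby(["slide_id", "subarray_id", "sample_id", "marker_id"], as_index=False)["net"]
        .mean()
        .rename(columns={"net": "value"})
    )
    return agg


def positive_control_means(spots: pd.DataFrame) -> pd.DataFrame:
    """Per-sub-array mean of background-subtracted positive-control spots."""
    pc = spots[spots["spot_role"] == "positive_control"].copy()
    pc["net"] = _clamped_net(pc)
    return (
        pc.groupby(["slide_id", "subarray_id"], as_index=False)["net"]
        .mean()
        .rename(columns={"net": "pos_mean"})
    )


def normalize_to_positive_controls(
    raw: pd.DataFrame,
    pos_means: pd.Series,
    reference: float | None = None,
) -> tuple[pd.DataFrame, float]:
    """Rescale each array (row) so its positive-control mean equals ``reference``.

    Parameters
    ----------
    raw
        Values with one row per array (sub-array), aligned with ``pos_means``.
    pos_means
        Positive-control mean per array; must be > 0 for every array.
    reference
        Target positive-control level; defaults to the grand mean of
        ``pos_means`` (preserves the overall intensity scale).

    Returns the normalized frame and the reference used.  After this step
    each array's rescaled positive-control mean equals ``reference``.
    """
    pos = pos_means.reindex(raw.index)
    bad = pos.index[pos.isna() | (pos <= 0)].tolist()
    if bad:
        raise ValueError(
            f"array(s) without a positive positive-control mean: {bad}"
        )
    if reference is None:
        reference = float(pos.mean())
    factors = reference / pos
    return raw.mul(factors, axis=0), float(reference)


def apply_floor(values, cutoff: float, floor_value: float = FLOOR_VALUE,
                keep_at_cutoff: bool = True):
    """Replace sub-threshold values by the floor (non-detection) value.

    A value below ``cutoff`` is a non-detection and becomes ``floor_value``
    (1 by convention).  With ``keep_at_cutoff`` (default) a value exactly at
    the cutoff counts as a real signal and is kept; set it False for the
    strict-exceedance convention.  Idempotent as long as
    ``floor_value < cutoff``.
    """
    arr = np.asarray(values, dtype=float)
    below = arr < cutoff if keep_at_cutoff else arr <= cutoff
    out = np.where(below, floor_value, arr)
    if isinstance(values, pd.DataFrame):
        return pd.DataFrame(out, index=values.index, columns=values.columns)
    if isinstance(values, pd.Series):
        return pd.Series(out, index=values.index, name=values.name)
    return out


def filter_markers(matrix: MarkerMatrix) -> MarkerMatrix:
    """Drop markers that are non-detections (floor value) in every sample."""
    all_floor = (matrix.values == matrix.floor_value).all(axis=0)
    removed = list(matrix.values.columns[all_floor])
    if removed:
        log.info("removing %d all-non-detected marker(s): %s", len(removed), removed)
    kept = matrix.values.loc[:, ~all_floor]
    if kept.shape[1] == 0:
        log.warning("all markers were non-detections; matrix is empty")
    return MarkerMatrix(
        values=kept.copy(),
        labels=matrix.labels.copy(),
        floor_value=matrix.floor_value,
        cutoff=matrix.cutoff,
        blank_model=matrix.blank_model,
        removed_markers=removed,
    )


def blank_subarray_signals(spots: pd.DataFrame) -> pd.DataFrame:
    """Raw aggregate signal per blank sub-array (mean clamped net intensity)."""
    bl = spots[spots["spot_role"] == "blank"].copy()
    bl["net"] = _clamped_net(bl)
    return (
        bl.groupby(["slide_id", "subarray_id"], as_index=False)["net"]
        .mean()
        .rename(columns={"net": "blank_signal"})
    )


def build_matrix(
    spots: pd.DataFrame,
    sheet: pd.DataFrame,
    *,
    k: float = 2.0,
    reference: float | None = None,
    floor_value: float = FLOOR_VALUE,
    keep_at_cutoff: bool = True,
    cutoff: float | None = None,
) -> MarkerMatrix:
    """Full preprocessing: aggregate -> normalize -> floor -> filter -> merge.

    ``spots`` is a validated spot table, ``sheet`` a validated sample sheet.
    Blank sub-arrays in ``spots`` provide the detection threshold; they are
    normalized by their slide's mean positive-control level so the cutoff
    lives on the same scale as the normalized marker values.  A precomputed
    ``cutoff`` may be supplied instead (then blanks are not required).

    If a sample was assayed on several sub-arrays its normalized values are
    averaged before flooring.  Extra analyte columns from the sample sheet
    (e.g. CA125) are appended after filtering, un-normalized and un-floored.
    """
    agg = aggregate_replicates(spots)
    wide = agg.pivot(index="subarray_id", columns="marker_id", values="value")
    if wide.isna().any().any():
        missing = [
            (sub, mk)
            for sub in wide.index
            for mk in wide.columns[wide.loc[sub].isna()]
        ]
        raise array_io.ValidationError(
            f"sub-arrays missing marker measurements: {missing[:10]}"
        )

    pc = positive_control_means(spots)
    pos = pc.set_index("subarray_id")["pos_mean"]
    normalized, ref = normalize_to_positive_controls(wide, pos, reference)

    if cutoff is None:
        blanks = blank_subarray_signals(spots)
        if len(blanks) < 2:
            raise ValueError(
                "need >= 2 blank sub-arrays (or an explicit cutoff) to set the "
                f"detection threshold; found {len(blanks)}"
            )
        # blanks have no positive controls of their own: rescale each by its
        # slide's mean positive-control level (sample sub-arrays on that slide)
        slide_pos = pc.groupby("slide_id")["pos_mean"].mean()
        factors = (ref / slide_pos).reindex(blanks["slide_id"]).to_numpy()
        grand = float(ref / pos.mean())
        factors = np.where(np.isnan(factors), grand, factors)
        blank_model = compute_blank_cutoff(
            blanks["blank_signal"].to_numpy() * factors, k=k
        )
        cutoff = blank_model.cutoff
    else:
        blank_model = None

    sub2samp = (
        spots.loc[spots["spot_role"] == "marker", ["subarray_id", "sample_id"]]
        .drop_duplicates()
        .set_index("subarray_id")["sample_id"]
    )
    by_sample = normalized.groupby(sub2samp.reindex(normalized.index)).mean()

    sheet = array_io.validate_sample_sheet(sheet)
    labels = sheet.set_index("sample_id")["group_label"]
    unknown = [s for s in by_sample.index if s not in labels.index]
    if unknown:
        raise array_io.ValidationError(
            f"sample(s) in spot table but not in sample sheet: {unknown}"
        )
    # row order follows the sample sheet, restricted to assayed samples
    order = [s for s in labels.index if s in by_sample.index]
    by_sample = by_sample.loc[order]
    by_sample.columns.name = None
    by_sample.index.name = None

    floored = apply_floor(by_sample, cutoff, floor_value, keep_at_cutoff)
    matrix = MarkerMatrix(
        values=floored,
        labels=labels.loc[order],
        floor_value=floor_value,
        cutoff=float(cutoff),
        blank_model=blank_model,
    )
    matrix = filter_markers(matrix)

    for col in array_io.extra_analyte_columns(sheet):
        matrix.values[col] = sheet.set_index("sample_id")[col].reindex(order).astype(float)
    return matrix
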