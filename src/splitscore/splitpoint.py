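"""Split-point score classification.

For a single marker, a *split point* s divides the intensity axis into a
control interval and a cancer interval; the split is chosen to minimize the
number of misclassified training samples over all candidate positions
(midpoints between adjacent distinct sorted values, plus sentinels below the
minimum and above the maximum) and both orientations (cancer above the split
or cancer below it).  A sample then receives a score of 1 for a marker if its
value falls in that marker's cancer interval and 0 otherwise; its panel score
is the sum over the N panel markers, an integer in [0, N].  A panel threshold
T (fitted, or fixed by the user at an operating point such as T = 3 for a
5-marker panel) calls a sample cancer iff its total score >= T.

Conventions (the data alone do not determine them, so they are fixed here and
configurable where noted):

* a value exactly equal to the split falls in the **control** interval
  (strict inequality toward cancer);
* among equal-misclassification candidate splits the rule with the larger
  margin (gap between the adjacent training values around the split) wins,
  then the smaller split value, then orientation cancer-high;
* at the panel level, score exactly T is called **cancer** (>= T), and when
  several thresholds tie on training misclassification the smallest wins.

Because only the ordering of values matters, every per-marker decision is
invariant under strictly increasing transforms of that marker's intensities.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from ._utils import CANCER, CONTROL, as_cancer_mask
from .preprocess import MarkerMatrix

DIRECTIONS = ("cancer_high", "cancer_low")

PANEL_FORMAT = "splitscore-panel"
PANEL_VERSION = 1


@dataclass(frozen=True)
class SplitPointRule:
    """One marker's fitted split: position, orientation, training error."""

    marker_id: str
    split: float
    direction: str  # "cancer_high" | "cancer_low"
    train_misclassified: int
    margin: float

    def __post_init__(self):
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}")

    def votes_cancer(self, value) -> bool | np.ndarray:
        """Whether a value falls in the cancer interval (boundary -> control)."""
        v = np.asarray(value, dtype=float)
        res = v > self.split if self.direction == "cancer_high" else v < self.split
        return bool(res) if np.isscalar(value) else res


@dataclass
class PanelModel:
    """An ordered set of N split-point rules plus the decision threshold T."""

    rules: list[SplitPointRule]
    threshold: int

    def __post_init__(self):
        ids = [r.marker_id for r in self.rules]
        if len(set(ids)) != len(ids):
            raise ValueError("panel markers must be distinct")
        if not (0 <= self.threshold <= self.n + 1):
            raise ValueError(f"threshold must lie in [0, {self.n + 1}]")

    @property
    def n(self) -> int:
        return len(self.rules)

    @property
    def marker_ids(self) -> list[str]:
        return [r.marker_id for r in self.rules]


@dataclass(frozen=True)
class ScoreResult:
    """Per-sample panel scoring outcome."""

    sample_id: str
    per_marker_scores: tuple[int, ...]
    total_score: int
    predicted: str  # "cancer" | "control"


def _candidates(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Candidate split positions and their margins.

    Midpoints between adjacent distinct sorted values cover every distinct
    classifier behaviour (misclassification is piecewise constant in s) while
    maximizing the separation margin; sentinels one unit below the minimum
    and above the maximum represent the all-one-side rules (margin 0).
    """
    sv = np.unique(values)
    mids = (sv[:-1] + sv[1:]) / 2.0
    gaps = np.diff(sv)
    splits = np.concatenate(([sv[0] - 1.0], mids, [sv[-1] + 1.0]))
    margins = np.concatenate(([0.0], gaps, [0.0]))
    return splits, margins


def fit_split_point(values, labels, marker_id: str = "") -> SplitPointRule:
    """Fit the misclassification-minimizing split for one marker.

    Parameters
    ----------
    values
        Per-sample intensities (no missing values).
    labels
        Per-sample group, {"cancer","control"} strings or a boolean
        cancer mask; both groups must be non-empty.

    Ties are broken deterministically: larger margin, then smaller split,
    then orientation cancer-high.  If all values are identical the rule is
    degenerate (training error min(n_cancer, n_control)) and a warning is
    issued.
    """
    v = np.asarray(values, dtype=float)
    if np.isnan(v).any():
        raise ValueError(f"marker {marker_id!r} has missing values")
    mask = as_cancer_mask(labels)
    if v.shape != mask.shape:
        raise ValueError("values and labels must have the same length")

    c = np.sort(v[mask])
    u = np.sort(v[~mask])
    if np.unique(v).size == 1:
        warnings.warn(
            f"marker {marker_id!r}: all values identical; degenerate split",
            stacklevel=2,
        )

    splits, margins = _candidates(v)
    # cancer_high: a sample votes cancer iff value > s
    mis_high = np.searchsorted(c, splits, side="right") + (
        u.size - np.searchsorted(u, splits, side="right")
    )
    # cancer_low: a sample votes cancer iff value < s
    mis_low = (c.size - np.searchsorted(c, splits, side="left")) + np.searchsorted(
        u, splits, side="left"
    )

    mis = np.concatenate([mis_high, mis_low])
    all_splits = np.concatenate([splits, splits])
    all_margins = np.concatenate([margins, margins])
    dir_pref = np.concatenate([np.zeros_like(splits), np.ones_like(splits)])
    # lexicographic: misclassification, then -margin, then split, then direction
    best = np.lexsort((dir_pref, all_splits, -all_margins, mis))[0]
    return SplitPointRule(
        marker_id=marker_id,
        split=float(all_splits[best]),
        direction=DIRECTIONS[int(dir_pref[best])],
        train_misclassified=int(mis[best]),
        margin=float(all_margins[best]),
    )


def score_sample(sample_values, panel: PanelModel, sample_id: str = "") -> ScoreResult:
    """Score one sample against a panel: 0/1 per marker, summed, thresholded.

    ``sample_values`` maps marker_id -> intensity (dict or Series); every
    panel marker must be present.
    """
    per_marker = []
    for rule in panel.rules:
        try:
            value = sample_values[rule.marker_id]
        except KeyError as exc:
            raise KeyError(
                f"sample {sample_id!r} has no value for panel marker {rule.marker_id!r}"
            ) from exc
        per_marker.append(int(rule.votes_cancer(float(value))))
    total = int(sum(per_marker))
    return ScoreResult(
        sample_id=sample_id,
        per_marker_scores=tuple(per_marker),
        total_score=total,
        predicted=CANCER if total >= panel.threshold else CONTROL,
    )


def score_matrix(values, panel: PanelModel) -> pd.DataFrame:
    """Vectorized panel scoring of a samples x markers frame (or MarkerMatrix).

    Returns a frame indexed by sample with one 0/1 column per panel marker
    plus ``total_score`` and ``predicted``.
    """
    if isinstance(values, MarkerMatrix):
        values = values.values
    missing = [r.marker_id for r in panel.rules if r.marker_id not in values.columns]
    if missing:
        raise KeyError(f"matrix has no value for panel marker(s): {missing}")
    out = pd.DataFrame(index=values.index)
    for rule in panel.rules:
        out[rule.marker_id] = rule.votes_cancer(values[rule.marker_id].to_numpy()).astype(int)
    out["total_score"] = out[[r.marker_id for r in panel.rules]].sum(axis=1)
    out["predicted"] = np.where(out["total_score"] >= panel.threshold, CANCER, CONTROL)
    return out


def fit_threshold(scores, labels, n_markers: int | None = None) -> int:
    """Pick the panel threshold T in [0, N+1] minimizing training error.

    Prediction rule: cancer iff score >= T.  Ties go to the smallest T.
    """
    s = np.asarray(scores)
    mask = as_cancer_mask(labels)
    n = int(n_markers) if n_markers is not None else int(np.max(s))
    best_t, best_mis = 0, None
    for t in range(0, n + 2):
        mis = int(np.count_nonzero((s >= t) != mask))
        if best_mis is None or mis < best_mis:
            best_t, best_mis = t, mis
    return best_t


def rank_markers(matrix: MarkerMatrix) -> pd.DataFrame:
    """Rank all markers by their individual split-point training error.

    Deterministic ordering: ascending misclassification count, ties broken
    by larger margin, then lexical marker id.  This is the panel-selection
    step: the top-N markers form the candidate panel.
    """
    mask = matrix.cancer_mask
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant markers rank last anyway
        for mk in matrix.marker_ids:
            rule = fit_split_point(matrix.values[mk].to_numpy(), mask, marker_id=mk)
            rows.append(
                {
                    "marker_id": mk,
                    "train_misclassified": rule.train_misclassified,
                    "margin": rule.margin,
                    "split": rule.split,
                    "direction": rule.direction,
                }
            )
    df = pd.DataFrame(rows)
    return df.sort_values(
        ["train_misclassified", "margin", "marker_id"],
        ascending=[True, False, True],
        kind="mergesort",
    ).reset_index(drop=True)


def fit_panel(
    matrix: MarkerMatrix,
    marker_ids,
    forced_T: int | None = None,
) -> PanelModel:
    """Fit a panel: one split-point rule per listed marker, then the threshold.

    ``forced_T`` pins the decision threshold to a chosen operating point
    (e.g. T = 3 for a 5-marker panel); otherwise T is fitted by
    :func:`fit_threshold` on the training scores.
    """
    marker_ids = list(marker_ids)
    unknown = [m for m in marker_ids if m not in matrix.values.columns]
    if unknown:
        raise KeyError(f"unknown marker(s): {unknown}")
    mask = matrix.cancer_mask
    rules = [
        fit_split_point(matrix.values[mk].to_numpy(), mask, marker_id=mk)
        for mk in marker_ids
    ]
    panel = PanelModel(rules=rules, threshold=0)
    totals = score_matrix(matrix.values, panel)["total_score"].to_numpy()
    panel.threshold = (
        int(forced_T) if forced_T is not None else fit_threshold(totals, mask, panel.n)
    )
    if not (0 <= panel.threshold <= panel.n + 1):
        raise ValueError(f"threshold must lie in [0, {panel.n + 1}]")
    return panel


def save_panel(panel: PanelModel, path) -> None:
    """Write a panel as a small human-readable YAML document."""
    doc = {
        "format": PANEL_FORMAT,
        "version": PANEL_VERSION,
        "threshold": int(panel.threshold),
        "rules": [
            {
                "marker_id": r.marker_id,
                "split": float(r.split),
                "direction": r.direction,
                "train_misclassified": int(r.train_misclassified),
                "margin": float(r.margin),
            }
            for r in panel.rules
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_panel(path) -> PanelModel:
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or doc.get("format") != PANEL_FORMAT:
        raise ValueError(f"{path} is not a {PANEL_FORMAT} file")
    rules = [SplitPointRule(**r) for r in doc["rules"]]
    return PanelModel(rules=rules, threshold=int(doc["threshold"]))
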