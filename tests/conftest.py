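import numpy as np
import pandas as pd
import pytest

from splitscore import array_io


def spot_row(slide, sub, sample, role, marker, rep, fg, bg):
    return {
        "slide_id": slide,
        "subarray_id": sub,
        "sample_id": sample,
        "spot_role": role,
        "marker_id": marker,
        "replicate_index": rep,
        "fg_median": float(fg),
        "bg_median": float(bg),
    }


@pytest.fixture
def tiny_spots():
    """Two samples x two markers on one slide, plus two blank sub-arrays.

    Hand-traceable through the whole preprocessing pipeline:

    * aggregated values: s1 A=400, B=5; s2 A=200, B=1000
    * positive-control means 200 (X1) and 400 (X2) -> reference 300,
      scale factors 1.5 and 0.75 -> normalized s1 A=600 B=7.5,
      s2 A=150 B=750
    * blank sub-array signals 40 and 60 (slide factor 1.0) -> cutoff
      50 + 2 * sd([40, 60]) = 50 + 2 * sqrt(200) = 78.2842712...
    * flooring: s1 B=7.5 -> 1; everything else kept
    """
    rows = [
        spot_row("L1", "X1", "s1", "marker", "A", 1, 500, 100),
        spot_row("L1", "X1", "s1", "marker", "A", 2, 520, 120),
        spot_row("L1", "X1", "s1", "marker", "B", 1, 90, 100),
        spot_row("L1", "X1", "s1", "marker", "B", 2, 110, 100),
        spot_row("L1", "X1", "s1", "positive_control", "", 1, 300, 100),
        spot_row("L1", "X2", "s2", "marker", "A", 1, 250, 50),
        spot_row("L1", "X2", "s2", "marker", "A", 2, 270, 70),
        spot_row("L1", "X2", "s2", "marker", "B", 1, 1000, 0),
        spot_row("L1", "X2", "s2", "marker", "B", 2, 1000, 0),
        spot_row("L1", "X2", "s2", "positive_control", "", 1, 500, 100),
        spot_row("L1", "XB1", "", "blank", "", 1, 50, 10),
        spot_row("L1", "XB1", "", "blank", "", 2, 60, 20),
        spot_row("L1", "XB2", "", "blank", "", 1, 80, 20),
        spot_row("L1", "XB2", "", "blank", "", 2, 70, 10),
    ]
    return array_io.validate_spot_table(pd.DataFrame(rows))


TINY_CUTOFF = 50.0 + 2.0 * np.sqrt(200.0)


@pytest.fixture
def tiny_sheet():
    return pd.DataFrame(
        {"sample_id": ["s1", "s2"], "group_label": ["cancer", "control"]}
    )


def brute_force_min_misclassification(values, cancer_mask):
    """Independent exhaustive oracle for the optimal single-marker split.

    Enumerates every distinct behaviour of the rules `cancer iff v > s` and
    `cancer iff v < s` by sweeping s over the observed values plus sentinels,
    counting errors by direct iteration.
    """
    v = [float(x) for x in values]
    cancer = [bool(c) for c in cancer_mask]
    candidates = sorted(set(v)) + [min(v) - 1.0, max(v) + 1.0]
    best = None
    for s in candidates:
        mis_h = sum(1 for x, c in zip(v, cancer) if (x > s) != c)
        mis_l = sum(1 for x, c in zip(v, cancer) if (x < s) != c)
        for m in (mis_h, mis_l):
            if best is None or m < best:
                best = m
    return best
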