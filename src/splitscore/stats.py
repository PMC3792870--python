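"""Per-marker differential testing between cancer and control groups.

The screening statistic is a two-sample t-test per marker on log2-transformed
intensities (variance stabilization for multiplicative fluorescence data;
floored non-detections at 1 map to 0), Welch's unequal-variance variant by
default, with Benjamini-Hochberg multiplicity adjustment across all tested
markers.  Both the test variant and the adjustment are configurable.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .preprocess import MarkerMatrix

ADJUST_METHODS = {"bh": "fdr_bh", "bonferroni": "bonferroni", "none": None}
TEST_VARIANTS = ("welch", "student")


def differential_markers(
    matrix: MarkerMatrix,
    alpha: float = 0.05,
    adjust: str = "bh",
    test: str = "welch",
    log2_transform: bool = True,
) -> pd.DataFrame:
    """Test every marker for a group difference; adjust across markers.

    Parameters
    ----------
    matrix
        Preprocessed matrix with labels; each group needs >= 2 samples.
    alpha
        Significance level applied to the adjusted p-values.
    adjust
        "bh" (Benjamini-Hochberg, default), "bonferroni" or "none".
    test
        "welch" (unequal variances, default) or "student".
    log2_transform
        Test on log2 intensities (default) or on the raw scale.

    Returns a frame sorted by adjusted p-value with columns marker_id,
    mean_cancer, mean_control (raw intensity scale), t_stat, p_value,
    p_adjusted, significant.  A marker with zero variance in both groups
    gets p = 1 when the means are equal (no evidence) and p = 0 otherwise
    (deterministic separation), by convention.
    """
    if adjust not in ADJUST_METHODS:
        raise ValueError(f"adjust must be one of {sorted(ADJUST_METHODS)}")
    if test not in TEST_VARIANTS:
        raise ValueError(f"test must be one of {TEST_VARIANTS}")

    mask = matrix.cancer_mask
    if mask.sum() < 2 or (~mask).sum() < 2:
        raise ValueError("each group needs at least 2 samples")

    values = matrix.values.to_numpy(dtype=float)
    tested = np.log2(np.clip(values, 1e-12, None)) if log2_transform else values
    a = tested[mask, :]
    b = tested[~mask, :]

    with np.errstate(invalid="ignore", divide="ignore"):
        t_stat, p_value = scipy.stats.ttest_ind(
            a, b, axis=0, equal_var=(test == "student")
        )
    t_stat = np.asarray(t_stat, dtype=float)
    p_value = np.asarray(p_value, dtype=float)

    # degenerate markers: zero within-group variance in both groups
    zero_var = (a.var(axis=0) == 0) & (b.var(axis=0) == 0)
    equal_means = np.isclose(a.mean(axis=0), b.mean(axis=0))
    p_value = np.where(zero_var & equal_means, 1.0, p_value)
    t_stat = np.where(zero_var & equal_means, 0.0, t_stat)
    sep = zero_var & ~equal_means
    p_value = np.where(sep, 0.0, p_value)
    diff = a.mean(axis=0) - b.mean(axis=0)
    t_stat = np.where(sep, np.where(diff > 0, np.inf, -np.inf), t_stat)

    method = ADJUST_METHODS[adjust]
    if method is None:
        p_adj = p_value.copy()
    else:
        _, p_adj, _, _ = multipletests(p_value, alpha=alpha, method=method)

    out = pd.DataFrame(
        {
            "marker_id": matrix.marker_ids,
            "mean_cancer": matrix.values.to_numpy(dtype=float)[mask, :].mean(axis=0),
            "mean_control": matrix.values.to_numpy(dtype=float)[~mask, :].mean(axis=0),
            "t_stat": t_stat,
            "p_value": p_value,
            "p_adjusted": p_adj,
            "significant": p_adj < alpha,
        }
    )
    out.attrs["alpha"] = alpha
    out.attrs["adjust"] = adjust
    out.attrs["test"] = test
    out.attrs["log2_transform"] = log2_transform
    return out.sort_values(
        ["p_adjusted", "p_value", "marker_id"], kind="mergesort"
    ).reset_index(drop=True)
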