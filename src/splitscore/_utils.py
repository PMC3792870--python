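"""Small shared helpers."""
from __future__ import annotations

import numpy as np

CANCER = "cancer"
CONTROL = "control"


def as_cancer_mask(labels) -> np.ndarray:
    """Coerce group labels to a boolean mask (True = cancer).

    Accepts a boolean array or an array of {"cancer", "control"} strings.
    Raises if any other label appears or if either group is empty.
    """
    arr = np.asarray(labels)
    if arr.dtype == bool:
        mask = arr
    else:
        vals = set(np.unique(arr).tolist())
        unknown = vals - {CANCER, CONTROL}
        if unknown:
            raise ValueError(f"unknown group label(s): {sorted(unknown)}")
        mask = arr == CANCER
    if mask.all() or not mask.any():
        raise ValueError("both groups (cancer and control) must be non-empty")
    return mask
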