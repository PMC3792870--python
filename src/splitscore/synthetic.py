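"""Synthetic spot-level cohorts with the structure the pipeline assumes.

The generator emulates a glass-slide sandwich antibody-array study of serum
samples: a case-control cohort (default 34 cancer / 53 control) assayed for
``n_markers`` analytes (default 174), each printed in duplicate, with
positive-control spots on every sub-array, buffer-only blank sub-arrays
(default 10), a multiplicative per-slide scale effect, and multiplicative
replicate (spot-level) noise at a chosen coefficient of variation (default
10%, typical for this platform).

Intensity model (log scale):

    log V[i, m] = mu_m + delta_m * 1[i is cancer] + eps[i, m]

where ``mu_m`` is a per-marker baseline log-mean drawn uniformly around a
global baseline, ``eps`` is zero-mean Gaussian with the within-group SD
``baseline_log_sd``, and the spiked ("panel") markers carry a group shift of
``shift_sd`` within-group SDs (signed by direction).  For spiked markers the
deviations ``eps`` are drawn from a *truncated* Gaussian with bounded support
(``shift_truncation_sd`` SDs) in both groups, so a 3-SD shift produces
genuinely disjoint class intervals — the structure the split-point model
presupposes.  Non-spiked markers stay ordinary Gaussians, which keeps them a
clean null for t-test calibration.

Each spot's recorded foreground is background + slide_factor * replicate_noise
* signal, so background subtraction recovers the scaled signal exactly and
positive-control normalization removes the slide factor exactly when the
replicate noise is zero.

Every generating parameter is echoed in the returned ``truth`` record.
"""
from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from ._utils import CANCER, CONTROL
from .preprocess import FLOOR_VALUE, MarkerMatrix
from .splitpoint import PanelModel, SplitPointRule


@dataclass(frozen=True)
class PanelMarkerSpec:
    """A marker spiked with a between-group shift.

    shift_sd is in units of the within-group log-scale SD; direction "up"
    means elevated in cancer, "down" means depressed.
    """

    marker_id: str
    shift_sd: float = 3.0
    direction: str = "up"

    def __post_init__(self):
        if self.direction not in ("up", "down"):
            raise ValueError("direction must be 'up' or 'down'")
        if not math.isfinite(self.shift_sd):
            raise ValueError("shift_sd must be finite")


DEFAULT_PANEL: tuple[PanelMarkerSpec, ...] = (
    PanelMarkerSpec("M012", 3.0, "up"),
    PanelMarkerSpec("M047", 3.0, "up"),
    PanelMarkerSpec("M088", 3.0, "down"),
    PanelMarkerSpec("M131", 3.0, "up"),
    PanelMarkerSpec("M166", 3.0, "down"),
)


@dataclass
class SyntheticConfig:
    """Generator settings; the defaults emulate the study conditions.

    Cohort: 34 cancer / 53 control samples, 174 markers in duplicate,
    10 buffer blanks, 8 sub-arrays per slide, ~10% replicate CV.
    Intensities are log-normal around exp(baseline_log_mean) ~ 500
    fluorescence units with per-marker baselines spread uniformly
    +/- ``marker_spread`` on the log scale; blanks sit near 60 units,
    comfortably below marker signal, and positive controls at 3000.
    """

    seed: int
    n_cancer: int = 34
    n_control: int = 53
    n_markers: int = 174
    panel_markers: tuple[PanelMarkerSpec, ...] = DEFAULT_PANEL
    baseline_log_mean: float = math.log(500.0)
    baseline_log_sd: float = 0.35
    marker_spread: float = 0.8
    shift_truncation_sd: float = 1.25
    pos_control_level: float = 3000.0
    n_pos_spots: int = 4
    n_blanks: int = 10
    blank_mean: float = 60.0
    blank_sd: float = 10.0
    bg_level: float = 50.0
    bg_sd: float = 5.0
    slide_scale_sd: float = 0.2
    replicate_cv: float = 0.10
    subarrays_per_slide: int = 8
    include_ca125: bool = False
    ca125_log_mean: float = math.log(15.0)
    ca125_log_sd: float = 0.6
    ca125_shift_sd: float = 1.6
    population_seed: int = 2013

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory for reproducibility")
        if self.n_cancer < 1 or self.n_control < 1:
            raise ValueError("need at least 1 sample per group")
        if self.n_markers < 1:
            raise ValueError("need at least 1 marker")
        self.panel_markers = tuple(self.panel_markers)
        ids = self.marker_ids()
        unknown = [p.marker_id for p in self.panel_markers if p.marker_id not in ids]
        if unknown:
            raise ValueError(
                f"panel marker(s) {unknown} not among the {self.n_markers} "
                "generated markers; supply panel_markers matching marker_ids()"
            )

    def marker_ids(self) -> list[str]:
        width = max(3, len(str(self.n_markers)))
        return [f"M{i:0{width}d}" for i in range(1, self.n_markers + 1)]

    def sample_ids_and_groups(self) -> tuple[list[str], list[str]]:
        wc = max(2, len(str(self.n_cancer)))
        wn = max(2, len(str(self.n_control)))
        ids = [f"case-{i:0{wc}d}" for i in range(1, self.n_cancer + 1)] + [
            f"ctrl-{i:0{wn}d}" for i in range(1, self.n_control + 1)
        ]
        groups = [CANCER] * self.n_cancer + [CONTROL] * self.n_control
        return ids, groups


def _replicate_noise(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Mean-one multiplicative log-normal noise; exactly 1 when cv == 0."""
    if cv <= 0:
        return np.ones(n)
    sigma = math.sqrt(math.log1p(cv**2))
    return np.exp(rng.normal(-sigma**2 / 2.0, sigma, n))


def _true_log_values(rng: np.random.Generator, cfg: SyntheticConfig):
    """Per-(sample, marker) noise-free log intensities plus truth metadata."""
    n_s = cfg.n_cancer + cfg.n_control
    marker_ids = cfg.marker_ids()
    # marker baselines are population biology, shared by every cohort drawn
    # from the same population_seed; only sampling noise uses the cohort seed
    pop_rng = np.random.default_rng(cfg.population_seed)
    mu = cfg.baseline_log_mean + pop_rng.uniform(
        -cfg.marker_spread, cfg.marker_spread, cfg.n_markers
    )
    eps = rng.normal(0.0, cfg.baseline_log_sd, (n_s, cfg.n_markers))

    is_cancer = np.zeros(n_s, dtype=bool)
    is_cancer[: cfg.n_cancer] = True

    panel_truth = []
    idx = {m: j for j, m in enumerate(marker_ids)}
    for spec in cfg.panel_markers:
        j = idx[spec.marker_id]
        if cfg.baseline_log_sd > 0 and math.isfinite(cfg.shift_truncation_sd):
            t = cfg.shift_truncation_sd
            eps[:, j] = scipy.stats.truncnorm.rvs(
                -t, t, loc=0.0, scale=cfg.baseline_log_sd, size=n_s, random_state=rng
            )
        delta = spec.shift_sd * cfg.baseline_log_sd * (1.0 if spec.direction == "up" else -1.0)
        boundary = mu[j] + delta / 2.0
        half = cfg.shift_truncation_sd * cfg.baseline_log_sd
        panel_truth.append(
            {
                "marker_id": spec.marker_id,
                "direction": spec.direction,
                "shift_sd": spec.shift_sd,
                "delta_log": delta,
                "boundary_log": boundary,
                "cancer_support_log": (mu[j] + delta - half, mu[j] + delta + half),
                "control_support_log": (mu[j] - half, mu[j] + half),
            }
        )

    log_v = mu[None, :] + eps
    for spec, info in zip(cfg.panel_markers, panel_truth):
        log_v[is_cancer, idx[spec.marker_id]] += info["delta_log"]
    return marker_ids, is_cancer, mu, log_v, panel_truth


def _assemble_spots(
    rng: np.random.Generator,
    cfg: SyntheticConfig,
    v: np.ndarray,
    sample_ids: list[str],
    marker_ids: list[str],
    slide_prefix: str = "",
) -> tuple[pd.DataFrame, dict]:
    """Lay out sample sub-arrays (duplicate marker spots + positive controls)
    and blank sub-arrays onto slides and draw spot-level intensities.

    Blank sub-arrays are interleaved evenly among the sample sub-arrays, as
    on a real run, so every slide carrying blanks also carries serum
    sub-arrays whose positive controls pin down its scale factor.
    """
    n_s, n_m = v.shape
    n_sub = n_s + cfg.n_blanks
    all_ids = [f"{slide_prefix}sub-{i:03d}" for i in range(1, n_sub + 1)]
    slide_of_sub = [i // cfg.subarrays_per_slide for i in range(n_sub)]
    n_slides = slide_of_sub[-1] + 1
    slide_ids = [f"{slide_prefix}slide-{i:02d}" for i in range(1, n_slides + 1)]
    slide_factors = np.exp(rng.normal(0.0, cfg.slide_scale_sd, n_slides))
    all_slide = np.array([slide_ids[s] for s in slide_of_sub])
    all_factor = slide_factors[np.asarray(slide_of_sub)]

    if cfg.n_blanks:
        spacing = n_sub / cfg.n_blanks
        blank_pos = ((np.arange(cfg.n_blanks) + 0.5) * spacing).astype(int)
        sample_pos = np.setdiff1d(np.arange(n_sub), blank_pos)
    else:
        blank_pos = np.array([], dtype=int)
        sample_pos = np.arange(n_sub)
    sub_ids = [all_ids[p] for p in np.concatenate([sample_pos, blank_pos])]
    sub_slide = all_slide[np.concatenate([sample_pos, blank_pos])]
    sub_factor = all_factor[np.concatenate([sample_pos, blank_pos])]

    frames = []

    # --- marker spots on sample sub-arrays (sample-major, marker, replicate)
    n_ms = n_s * n_m * 2
    sig = np.repeat(v.ravel(), 2)
    sig = sig * np.repeat(sub_factor[:n_s], n_m * 2)
    sig = sig * _replicate_noise(rng, cfg.replicate_cv, n_ms)
    bg = np.clip(rng.normal(cfg.bg_level, cfg.bg_sd, n_ms), 0.0, None)
    frames.append(
        pd.DataFrame(
            {
                "slide_id": np.repeat(sub_slide[:n_s], n_m * 2),
                "subarray_id": np.repeat(sub_ids[:n_s], n_m * 2),
                "sample_id": np.repeat(sample_ids, n_m * 2),
                "spot_role": "marker",
                "marker_id": np.tile(np.repeat(marker_ids, 2), n_s),
                "replicate_index": np.tile([1, 2], n_s * n_m),
                "fg_median": bg + sig,
                "bg_median": bg,
            }
        )
    )

    # --- positive-control spots on sample sub-arrays
    n_ps = n_s * cfg.n_pos_spots
    sig = cfg.pos_control_level * np.repeat(sub_factor[:n_s], cfg.n_pos_spots)
    sig = sig * _replicate_noise(rng, cfg.replicate_cv, n_ps)
    bg = np.clip(rng.normal(cfg.bg_level, cfg.bg_sd, n_ps), 0.0, None)
    frames.append(
        pd.DataFrame(
            {
                "slide_id": np.repeat(sub_slide[:n_s], cfg.n_pos_spots),
                "subarray_id": np.repeat(sub_ids[:n_s], cfg.n_pos_spots),
                "sample_id": np.repeat(sample_ids, cfg.n_pos_spots),
                "spot_role": "positive_control",
                "marker_id": "",
                "replicate_index": np.tile(np.arange(1, cfg.n_pos_spots + 1), n_s),
                "fg_median": bg + sig,
                "bg_median": bg,
            }
        )
    )

    # --- blank sub-arrays: same physical layout, buffer instead of serum
    if cfg.n_blanks > 0:
        n_bspots_each = n_m * 2 + cfg.n_pos_spots
        n_bs = cfg.n_blanks * n_bspots_each
        sig = np.clip(rng.normal(cfg.blank_mean, cfg.blank_sd, n_bs), 0.0, None)
        sig = sig * np.repeat(sub_factor[n_s:], n_bspots_each)
        sig = sig * _replicate_noise(rng, cfg.replicate_cv, n_bs)
        bg = np.clip(rng.normal(cfg.bg_level, cfg.bg_sd, n_bs), 0.0, None)
        frames.append(
            pd.DataFrame(
                {
                    "slide_id": np.repeat(sub_slide[n_s:], n_bspots_each),
                    "subarray_id": np.repeat(sub_ids[n_s:], n_bspots_each),
                    "sample_id": "",
                    "spot_role": "blank",
                    "marker_id": "",
                    "replicate_index": np.tile(
                        np.arange(1, n_bspots_each + 1), cfg.n_blanks
                    ),
                    "fg_median": bg + sig,
                    "bg_median": bg,
                }
            )
        )

    spots = pd.concat(frames, ignore_index=True)
    truth_slides = dict(zip(slide_ids, slide_factors.tolist()))
    return spots, truth_slides


def generate_cohort(cfg: SyntheticConfig):
    """Generate one spot-level cohort.

    Returns ``(spots, sheet, truth)``: a validated spot table, a sample
    sheet (with a CA125 column if ``include_ca125``), and a truth record
    holding every generating parameter, the per-marker baselines, the spiked
    markers' true class boundaries/supports, and the slide scale factors.
    Output is deterministic for a fixed seed.
    """
    rng = np.random.default_rng(cfg.seed)
    sample_ids, groups = cfg.sample_ids_and_groups()
    marker_ids, is_cancer, mu, log_v, panel_truth = _true_log_values(rng, cfg)

    sheet = pd.DataFrame({"sample_id": sample_ids, "group_label": groups})
    if cfg.include_ca125:
        z = rng.normal(0.0, 1.0, len(sample_ids))
        shift = np.where(is_cancer, cfg.ca125_shift_sd, 0.0)
        sheet["CA125"] = np.exp(
            cfg.ca125_log_mean + cfg.ca125_log_sd * (z + shift)
        )

    spots, truth_slides = _assemble_spots(
        rng, cfg, np.exp(log_v), sample_ids, marker_ids
    )
    truth = {
        "config": asdict(cfg),
        "marker_log_means": dict(zip(marker_ids, mu.tolist())),
        "panel": panel_truth,
        "slide_factors": truth_slides,
    }
    return spots, sheet, truth


def generate_replicate_slides(
    cfg: SyntheticConfig, inter_slide_sd: float = 0.0
):
    """Assay the same samples twice, on two independent slide sets.

    Both arms share the per-sample true values; each arm gets its own slide
    factors, replicate noise and backgrounds, plus an extra per-(sample,
    marker) multiplicative log-normal discordance of SD ``inter_slide_sd``
    (log scale).  Concordance (Pearson r of post-normalization values) is
    monotone decreasing in ``inter_slide_sd``; with ``inter_slide_sd = 0``
    and ``replicate_cv = 0`` the two arms agree exactly after normalization.

    Returns ``(spots_a, spots_b, sheet, truth)``.
    """
    rng = np.random.default_rng(cfg.seed)
    sample_ids, groups = cfg.sample_ids_and_groups()
    marker_ids, _, mu, log_v, panel_truth = _true_log_values(rng, cfg)
    sheet = pd.DataFrame({"sample_id": sample_ids, "group_label": groups})

    arms = []
    for arm in (1, 2):
        arm_rng = np.random.default_rng([int(cfg.seed) & 0x7FFFFFFF, arm])
        if inter_slide_sd > 0:
            noise = arm_rng.normal(0.0, inter_slide_sd, log_v.shape)
        else:
            noise = 0.0
        spots, _ = _assemble_spots(
            arm_rng,
            cfg,
            np.exp(log_v + noise),
            sample_ids,
            marker_ids,
            slide_prefix=f"rep{arm}-",
        )
        arms.append(spots)
    truth = {
        "config": asdict(cfg),
        "inter_slide_sd": inter_slide_sd,
        "marker_log_means": dict(zip(marker_ids, mu.tolist())),
        "panel": panel_truth,
    }
    return arms[0], arms[1], sheet, truth


def worked_example_fixture() -> tuple[MarkerMatrix, PanelModel]:
    """Fixed 87-sample, 5-marker worked example at the T = 3 operating point.

    Deterministic construction (no RNG): all 34 cancer samples score 3-5,
    50 of 53 controls score 0-2 and the remaining 3 controls score 3, so at
    threshold 3 the confusion counts are tp=34, fn=0, tn=50, fp=3 —
    sensitivity 100%, specificity 50/53 = 94.3%, overall agreement
    84/87 = 96.6%.
    """
    markers = ["WE1", "WE2", "WE3", "WE4", "WE5"]
    split = 100.0
    cancer_scores = [5] * 20 + [4] * 8 + [3] * 6          # 34 cancers
    control_scores = [0] * 20 + [1] * 18 + [2] * 12 + [3] * 3  # 53 controls

    rows, ids, labels = [], [], []
    for i, score in enumerate(cancer_scores + control_scores):
        cancer = i < len(cancer_scores)
        ids.append(f"case-{i + 1:02d}" if cancer else f"ctrl-{i - 33:02d}")
        labels.append(CANCER if cancer else CONTROL)
        on = 150.0 + 2.0 * i   # in the cancer interval (> split)
        off = 40.0 + (i % 7)   # in the control interval (< split)
        rows.append([on if j < score else off for j in range(5)])

    values = pd.DataFrame(rows, index=ids, columns=markers, dtype=float)
    labels = pd.Series(labels, index=ids)
    matrix = MarkerMatrix(values=values, labels=labels, cutoff=None)

    rules = []
    mask = np.array([lab == CANCER for lab in labels])
    for mk in markers:
        col = values[mk].to_numpy()
        votes = col > split
        mis = int(np.count_nonzero(votes != mask))
        margin = float(col[col > split].min() - col[col < split].max())
        rules.append(
            SplitPointRule(
                marker_id=mk,
                split=split,
                direction="cancer_high",
                train_misclassified=mis,
                margin=margin,
            )
        )
    panel = PanelModel(rules=rules, threshold=3)
    return matrix, panel
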