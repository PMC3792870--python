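import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from splitscore import (
    MarkerMatrix,
    PanelModel,
    SplitPointRule,
    fit_panel,
    fit_split_point,
    fit_threshold,
    load_panel,
    rank_markers,
    save_panel,
    score_matrix,
    score_sample,
)
from conftest import brute_force_min_misclassification


def labels_of(n_cancer, n_control):
    return np.array([True] * n_cancer + [False] * n_control)


# ------------------------------------------------------------ fit_split_point

def test_perfectly_separated_groups():
    values = [5.0, 6.0, 7.0, 1.0, 2.0, 3.0]
    rule = fit_split_point(values, labels_of(3, 3))
    assert rule.direction == "cancer_high"
    assert rule.split == 4.0  # midpoint of 3 and 5 (largest margin)
    assert rule.train_misclassified == 0
    assert rule.margin == 2.0


def test_overlapping_groups_match_brute_force():
    values = [3.0, 5.0, 7.0, 1.0, 2.0, 6.0]  # cancers then controls
    mask = labels_of(3, 3)
    rule = fit_split_point(values, mask)
    assert rule.train_misclassified == brute_force_min_misclassification(values, mask)


def test_label_inversion_flips_direction_keeps_error():
    values = [5.0, 6.0, 7.0, 1.0, 2.0, 3.0]
    mask = labels_of(3, 3)
    a = fit_split_point(values, mask)
    b = fit_split_point(values, ~mask)
    assert a.split == b.split
    assert a.direction != b.direction
    assert a.train_misclassified == b.train_misclassified


def test_all_identical_values_degenerate_rule_warns():
    values = [4.0] * 7
    with pytest.warns(UserWarning, match="identical"):
        rule = fit_split_point(values, labels_of(3, 4))
    assert rule.train_misclassified == 3  # min(n_cancer, n_control)


def test_empty_group_rejected():
    with pytest.raises(ValueError, match="non-empty"):
        fit_split_point([1.0, 2.0], np.array([True, True]))


def test_missing_values_rejected():
    with pytest.raises(ValueError, match="missing"):
        fit_split_point([1.0, np.nan, 2.0], labels_of(1, 2))


def test_oracle_equivalence_on_random_small_instances():
    """Fitted misclassification equals exhaustive enumeration, incl. ties."""
    rng = np.random.default_rng(987)
    for _ in range(400):
        n = int(rng.integers(2, 13))
        n_cancer = int(rng.integers(1, n))
        mask = np.zeros(n, dtype=bool)
        mask[rng.choice(n, n_cancer, replace=False)] = True
        if rng.random() < 0.5:
            values = rng.integers(0, 5, n).astype(float)  # heavy ties
        else:
            values = rng.normal(0, 1, n)
        rule = fit_split_point(values, mask)
        assert rule.train_misclassified == brute_force_min_misclassification(
            values, mask
        )


@settings(derandomize=True, max_examples=100)
@given(st.data())
def test_oracle_equivalence_property(data):
    values = data.draw(
        st.lists(
            st.floats(min_value=-100, max_value=100, allow_nan=False),
            min_size=2,
            max_size=12,
        )
    )
    n = len(values)
    n_cancer = data.draw(st.integers(min_value=1, max_value=n - 1))
    mask = np.array([True] * n_cancer + [False] * (n - n_cancer))
    rule = fit_split_point(values, mask)
    assert rule.train_misclassified == brute_force_min_misclassification(values, mask)


def _optimum_is_unique(values, mask):
    """Whether exactly one (interval, direction) attains minimal error."""
    v = np.asarray(values, float)
    sv = np.unique(v)
    cands = np.concatenate(([sv[0] - 1.0], (sv[:-1] + sv[1:]) / 2, [sv[-1] + 1.0]))
    errs = [
        int((((v > s) if hi else (v < s)) != mask).sum())
        for s in cands
        for hi in (True, False)
    ]
    return errs.count(min(errs)) == 1


@settings(derandomize=True, max_examples=50)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_monotone_transform_preserves_error_and_unique_votes(seed):
    """Only the ordering matters for the training error: x -> exp(x/50)
    changes the split but never the misclassification count.  Per-sample
    votes are also preserved whenever the optimum is unique (with ties the
    margin-based tie-break may pick a different, equally good interval,
    since gap widths are not transform-invariant)."""
    rng = np.random.default_rng(seed)
    n = 14
    values = rng.normal(0, 10, n)
    mask = np.array([True] * 6 + [False] * 8)
    a = fit_split_point(values, mask)
    b = fit_split_point(np.exp(values / 50.0), mask)
    assert a.train_misclassified == b.train_misclassified
    if _optimum_is_unique(values, mask):
        np.testing.assert_array_equal(
            a.votes_cancer(values), b.votes_cancer(np.exp(values / 50.0))
        )


# ------------------------------------------------------------------- scoring

@pytest.fixture
def five_rule_panel():
    rules = [
        SplitPointRule(f"M{i}", split=100.0, direction="cancer_high",
                       train_misclassified=0, margin=10.0)
        for i in range(5)
    ]
    return PanelModel(rules=rules, threshold=3)


def test_score_all_cancer_intervals(five_rule_panel):
    sample = {f"M{i}": 150.0 for i in range(5)}
    res = score_sample(sample, five_rule_panel)
    assert res.total_score == 5
    assert res.predicted == "cancer"


def test_score_two_predicts_control_at_t3(five_rule_panel):
    sample = {"M0": 150.0, "M1": 150.0, "M2": 50.0, "M3": 50.0, "M4": 50.0}
    res = score_sample(sample, five_rule_panel)
    assert res.total_score == 2
    assert res.predicted == "control"


def test_boundary_value_falls_in_control_interval(five_rule_panel):
    sample = {f"M{i}": 100.0 for i in range(5)}  # exactly at every split
    assert score_sample(sample, five_rule_panel).total_score == 0


def test_score_equal_to_threshold_is_cancer(five_rule_panel):
    sample = {"M0": 150.0, "M1": 150.0, "M2": 150.0, "M3": 50.0, "M4": 50.0}
    assert score_sample(sample, five_rule_panel).predicted == "cancer"


def test_missing_marker_named_in_error(five_rule_panel):
    sample = {f"M{i}": 150.0 for i in range(4)}
    with pytest.raises(KeyError, match="M4"):
        score_sample(sample, five_rule_panel, sample_id="s1")


@settings(derandomize=True, max_examples=50)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_score_conservation(seed):
    five_rule_panel = PanelModel(
        rules=[
            SplitPointRule(f"M{i}", 100.0, "cancer_high", 0, 10.0) for i in range(5)
        ],
        threshold=3,
    )
    rng = np.random.default_rng(seed)
    values = pd.DataFrame(
        rng.uniform(0, 200, (10, 5)), columns=[f"M{i}" for i in range(5)]
    )
    scored = score_matrix(values, five_rule_panel)
    totals = scored["total_score"]
    assert ((totals >= 0) & (totals <= 5)).all()
    votes = scored[[f"M{i}" for i in range(5)]]
    assert (votes.sum(axis=1) == totals).all()
    assert votes.isin([0, 1]).all().all()


def test_threshold_monotonicity():
    """Raising T shrinks the predicted-cancer set; sensitivity is
    non-increasing and specificity non-decreasing in T."""
    rng = np.random.default_rng(5)
    scores = rng.integers(0, 6, 60)
    mask = rng.random(60) < 0.4
    prev_set, prev_sens, prev_spec = None, None, None
    for t in range(0, 7):
        pred = scores >= t
        sens = (pred & mask).sum() / mask.sum()
        spec = (~pred & ~mask).sum() / (~mask).sum()
        if prev_set is not None:
            assert set(np.where(pred)[0]) <= prev_set
            assert sens <= prev_sens
            assert spec >= prev_spec
        prev_set, prev_sens, prev_spec = set(np.where(pred)[0]), sens, spec


# -------------------------------------------------------------- fit_threshold

def test_threshold_tie_breaks_to_smallest():
    scores = [5] * 4 + [0] * 6
    assert fit_threshold(scores, labels_of(4, 6), n_markers=5) == 1


def test_threshold_single_marker_panel():
    assert fit_threshold([1, 0], labels_of(1, 1), n_markers=1) == 1


def test_threshold_minimizes_misclassification():
    scores = np.array([5, 4, 4, 3, 2, 1, 1, 0, 0, 0])
    mask = labels_of(4, 6)
    t = fit_threshold(scores, mask, n_markers=5)
    best = min(
        int(((scores >= tt) != mask).sum()) for tt in range(0, 7)
    )
    assert int(((scores >= t) != mask).sum()) == best


# ------------------------------------------------------------------- ranking

def _matrix_from(values: dict, mask):
    df = pd.DataFrame(values, dtype=float)
    labels = pd.Series(
        np.where(mask, "cancer", "control"), index=df.index
    )
    return MarkerMatrix(values=df, labels=labels)


def test_rank_orders_by_misclassification():
    mask = labels_of(3, 3)
    m = _matrix_from(
        {
            "perfect": [10, 11, 12, 1, 2, 3],
            "bad": [5, 1, 4, 6, 2, 3],
            "mid": [10, 11, 1.5, 1, 2, 3],
        },
        mask,
    )
    ranked = rank_markers(m)
    counts = dict(zip(ranked["marker_id"], ranked["train_misclassified"]))
    assert ranked["marker_id"].iloc[0] == "perfect"
    assert list(ranked["train_misclassified"]) == sorted(counts.values())


def test_rank_ties_break_lexically():
    mask = labels_of(2, 2)
    m = _matrix_from({"b": [5.0, 6.0, 1.0, 2.0], "a": [5.0, 6.0, 1.0, 2.0]}, mask)
    ranked = rank_markers(m)
    assert list(ranked["marker_id"]) == ["a", "b"]  # equal counts and margins


# ----------------------------------------------------------------- fit_panel

def test_fit_panel_forced_threshold():
    mask = labels_of(3, 3)
    m = _matrix_from(
        {f"M{i}": [10, 11, 12, 1, 2, 3] for i in range(5)}, mask
    )
    panel = fit_panel(m, [f"M{i}" for i in range(5)], forced_T=3)
    assert panel.n == 5
    assert panel.threshold == 3


def test_fit_panel_unknown_marker():
    m = _matrix_from({"A": [1.0, 2.0, 3.0, 4.0]}, labels_of(2, 2))
    with pytest.raises(KeyError, match="nope"):
        fit_panel(m, ["nope"])


def test_fit_panel_perfect_separation_zero_training_error():
    mask = labels_of(4, 4)
    rng = np.random.default_rng(11)
    vals = {
        f"M{i}": np.concatenate([rng.uniform(10, 12, 4), rng.uniform(1, 3, 4)])
        for i in range(3)
    }
    m = _matrix_from(vals, mask)
    panel = fit_panel(m, list(vals))
    scored = score_matrix(m, panel)
    assert (scored["predicted"].to_numpy() == m.labels.to_numpy()).all()


def test_single_marker_panel_without_forced_threshold():
    m = _matrix_from({"A": [10.0, 12.0, 1.0, 2.0]}, labels_of(2, 2))
    panel = fit_panel(m, ["A"])
    assert panel.n == 1
    assert panel.threshold == 1


# ------------------------------------------------------------- serialization

def test_panel_roundtrip(tmp_path, five_rule_panel):
    path = tmp_path / "panel.yaml"
    save_panel(five_rule_panel, path)
    got = load_panel(path)
    assert got.threshold == five_rule_panel.threshold
    assert got.rules == five_rule_panel.rules


def test_panel_rejects_duplicate_markers():
    rule = SplitPointRule("A", 1.0, "cancer_high", 0, 0.0)
    with pytest.raises(ValueError, match="distinct"):
        PanelModel(rules=[rule, rule], threshold=1)
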