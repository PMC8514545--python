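"""Cross-validation grouping, nulls, ROC/operating-point oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import idarcyto as ic

from conftest import FAST_TRAIN, make_toy_table


def brute_force_auroc(scores, labels):
    """Probability-of-correct-ranking by exhaustive pair enumeration."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


# --- ROC --------------------------------------------------------------------

def test_perfect_and_random_auroc():
    y = np.array([0, 0, 1, 1])
    _, _, auroc, _ = ic.roc(y.astype(float), y, n_boot=50)
    assert auroc == 1.0
    rng = np.random.default_rng(0)
    y2 = rng.integers(0, 2, 2000)
    _, _, a2, _ = ic.roc(rng.random(2000), y2, n_boot=50)
    assert abs(a2 - 0.5) < 0.05


@settings(max_examples=200, derandomize=True, deadline=None)
@given(st.lists(st.tuples(st.integers(0, 5), st.booleans()), min_size=2, max_size=12))
def test_auroc_equals_pairwise_ranking_oracle(pairs):
    scores = np.array([s for s, _ in pairs], dtype=float)
    labels = np.array([int(l) for _, l in pairs])
    if len(np.unique(labels)) < 2:
        return
    _, _, auroc, _ = ic.roc(scores, labels, n_boot=10)
    assert auroc == pytest.approx(brute_force_auroc(scores, labels), abs=1e-12)


def test_single_class_roc_rejected():
    with pytest.raises(ValueError):
        ic.roc(np.array([1.0, 2.0]), np.array([1, 1]))


# --- operating points -------------------------------------------------------

def test_operating_point_matches_hand_enumerated_table():
    # scores > 50: rows 0,1,2,5; labels: tp=2 (0,1), fp=2 (2,5), fn=1 (3), tn=3
    scores = np.array([90, 80, 70, 40, 30, 60, 20, 10], dtype=float)
    labels = np.array([1, 1, 0, 1, 0, 0, 0, 0])
    op = ic.operating_point(scores, labels, 50.0)
    assert op.sensitivity == pytest.approx(100 * 2 / 3)
    assert op.specificity == pytest.approx(100 * 3 / 5)
    assert op.ppv == pytest.approx(100 * 2 / 4)
    assert op.npv == pytest.approx(100 * 3 / 4)


def test_perfect_separation_all_metrics_100():
    scores = np.array([10, 20, 80, 90], dtype=float)
    labels = np.array([0, 0, 1, 1])
    op = ic.operating_point(scores, labels, 50.0)
    assert (op.sensitivity, op.specificity, op.ppv, op.npv) == (100, 100, 100, 100)


def test_strict_cutoff_convention():
    op = ic.operating_point(np.array([54.5, 60.0]), np.array([1, 1]), 54.5)
    assert op.sensitivity == pytest.approx(50.0)  # 54.5 itself is not a call


def test_undefined_metrics_are_nan_not_fabricated():
    op = ic.operating_point(np.array([10.0, 20.0]), np.array([0, 0]), 50.0)
    assert np.isnan(op.sensitivity) and np.isnan(op.ppv)
    assert op.specificity == 100.0


def test_cutoff_sweep_monotonicity():
    rng = np.random.default_rng(3)
    labels = rng.integers(0, 2, 200)
    scores = rng.normal(labels * 2.0, 1.0)
    sweep = ic.cutoff_sweep(scores, labels, np.linspace(-3, 5, 30))
    assert (np.diff(sweep["sensitivity"]) <= 1e-9).all()
    assert (np.diff(sweep["specificity"]) >= -1e-9).all()


# --- cross-validation -------------------------------------------------------

@pytest.fixture(scope="module")
def repeated_toy():
    """Toy cohort with 2 records per subject (subject-effect correlated)."""
    rng = np.random.default_rng(7)
    n_subj = 30
    y_subj = np.repeat([0, 1], n_subj // 2)
    rows = []
    for i, ys in enumerate(y_subj):
        eff = rng.normal(0, 1)
        for _ in range(2):
            rows.append({"subject": f"S{i}", "y": ys,
                         "A": rng.normal(ys * 2 + eff, 0.5),
                         "B": rng.normal(eff, 0.5)})
    df = pd.DataFrame(rows)
    return df[["A", "B"]], df["y"].to_numpy(), df["subject"].to_numpy()


def test_subject_folds_never_split_a_subject(repeated_toy):
    table, y, subjects = repeated_toy
    res = ic.cross_validate(table, y, subjects, None,
                            ic.TrainConfig(**FAST_TRAIN),
                            ic.CVScheme(k=5, grouping="SUBJECT", seed=0))
    df = pd.DataFrame({"subject": subjects, "fold": res.fold_of_record})
    assert (df.groupby("subject")["fold"].nunique() == 1).all()
    # every record scored exactly once
    assert np.isfinite(res.scores).all()
    assert set(res.fold_of_record) == set(range(5))


def test_temporal_scheme_partitions_all_records(repeated_toy):
    table, y, subjects = repeated_toy
    times = np.tile([2.0, 24.0], len(y) // 2)
    res = ic.cross_validate(table, y, subjects, times,
                            ic.TrainConfig(**FAST_TRAIN),
                            ic.CVScheme(k=4, grouping="TEMPORAL", seed=1))
    assert np.isfinite(res.scores).all()


def test_leave_one_subject_out_runs():
    table, y, subjects = make_toy_table(n=12, informative_shift=5.0, seed=9)
    res = ic.cross_validate(table, y, subjects, None,
                            ic.TrainConfig(**FAST_TRAIN),
                            ic.CVScheme(k=12, grouping="SUBJECT", seed=0))
    assert np.isfinite(res.scores).all()


def test_cv_determinism(repeated_toy):
    table, y, subjects = repeated_toy
    kwargs = dict(config=ic.TrainConfig(**FAST_TRAIN),
                  scheme=ic.CVScheme(k=4, seed=5))
    a = ic.cross_validate(table, y, subjects, None, **kwargs)
    b = ic.cross_validate(table, y, subjects, None, **kwargs)
    np.testing.assert_array_equal(a.scores, b.scores)
    assert a.auroc == b.auroc


# --- randomization null -----------------------------------------------------

def test_null_on_noise_features_is_near_half():
    rng = np.random.default_rng(2)
    n = 80
    table = pd.DataFrame({"A": rng.normal(size=n), "B": rng.normal(size=n)})
    y = np.repeat([0, 1], n // 2)
    subjects = np.array([f"S{i}" for i in range(n)])
    aurocs = ic.randomization_null(table, y, subjects,
                                   ic.TrainConfig(**FAST_TRAIN),
                                   ic.CVScheme(k=4, seed=0), n_shuffles=6, seed=3)
    assert 0.35 < aurocs.mean() < 0.65


def test_null_shuffle_determinism(repeated_toy):
    table, y, subjects = repeated_toy
    kwargs = dict(config=ic.TrainConfig(**FAST_TRAIN),
                  scheme=ic.CVScheme(k=4, seed=2), n_shuffles=1, seed=9)
    a = ic.randomization_null(table, y, subjects, **kwargs)
    b = ic.randomization_null(table, y, subjects, **kwargs)
    assert a[0] == b[0]


# --- cohort statistics ------------------------------------------------------

def test_mann_whitney_matches_brute_force_pair_count():
    a = np.array([1.0, 5.0, 7.0, 3.0, 9.0, 11.0])
    b = np.array([2.0, 4.0, 6.0, 8.0, 0.0, 10.0])
    report = ic.cohort_statistics({"g1": a, "g2": b})
    u = report["mann_whitney"][("g1", "g2")]["U"]
    brute = sum((x > y) + 0.5 * (x == y) for x in a for y in b)
    assert u == pytest.approx(brute)


def test_identical_groups_and_self_correlation():
    vals = np.arange(10, dtype=float)
    report = ic.cohort_statistics(
        {"g1": vals, "g2": vals.copy()},
        paired={"self": (vals, vals), "mono": (vals, np.exp(vals))},
    )
    assert report["mann_whitney"][("g1", "g2")]["p"] > 0.9
    assert report["spearman"]["self"]["rho"] == pytest.approx(1.0)
    assert report["spearman"]["mono"]["rho"] == pytest.approx(1.0)


def test_empty_group_skipped_with_warning():
    report = ic.cohort_statistics({"g1": np.arange(5.0), "g2": np.array([])})
    assert report["warnings"]
    assert not report["mann_whitney"]
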