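"""Split construction, metrics, ROC, and the evaluation experiment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

from pnespipe import (
    ClassifierSpec,
    EpochClassificationExperiment,
    SplitPlan,
    confusion_metrics,
    default_classifier_specs,
    make_loo_splits,
    make_random_split,
    roc_auc,
    standardize_features,
    train_and_score,
)
from pnespipe.spectral import METADATA_COLUMNS


def gaussian_table(n_subjects=6, n_epochs=20, n_features=8, sep=10.0, seed=0):
    """Toy feature table: two well-separated Gaussian classes."""
    rng = np.random.default_rng(seed)
    rows = []
    for c, label in enumerate(("CNT", "PNES")):
        for s in range(n_subjects // 2):
            X = rng.standard_normal((n_epochs, n_features)) + c * sep
            for i in range(n_epochs):
                rows.append((f"{label}{s}", label, i, *X[i]))
    cols = list(METADATA_COLUMNS) + [f"f{i}" for i in range(n_features)]
    return pd.DataFrame(rows, columns=cols)


# -- splits -----------------------------------------------------------------

def subjects_10_10():
    return {"CNT": [f"CNT{i}" for i in range(10)],
            "PNES": [f"PNES{i}" for i in range(10)]}


def test_random_split_sizes_and_determinism():
    plan = make_random_split(subjects_10_10(), train_per_class=7, seed=3)
    assert len(plan.train_subjects) == 14 and len(plan.test_subjects) == 6
    assert plan == make_random_split(subjects_10_10(), train_per_class=7, seed=3)
    other = make_random_split(subjects_10_10(), train_per_class=7, seed=4)
    assert set(other.train_subjects) != set(plan.train_subjects)


def test_random_split_requires_spare_subjects():
    with pytest.raises(ValueError):
        make_random_split({"CNT": ["a"], "PNES": ["b", "c"]}, train_per_class=1)


def test_loo_splits_partition_subjects():
    ids = [f"s{i}" for i in range(20)]
    plans = make_loo_splits(ids)
    assert len(plans) == 20
    held = [p.test_subjects[0] for p in plans]
    assert sorted(held) == sorted(ids)
    for p in plans:
        assert set(p.train_subjects) | set(p.test_subjects) == set(ids)
        assert not set(p.train_subjects) & set(p.test_subjects)
    with pytest.raises(ValueError):
        make_loo_splits(["only"])


def test_split_plan_rejects_overlap():
    with pytest.raises(ValueError):
        SplitPlan("loo", ("a", "b"), ("b",))


# -- standardization --------------------------------------------------------

def test_standardize_definition_and_degenerate_column():
    train = np.array([[3.0, 1.0], [7.0, 1.0]])  # col0: mean 5, SD 2
    test = np.array([[7.0, 9.0]])
    tr, te, _ = standardize_features(train, test)
    assert te[0, 0] == pytest.approx(1.0)
    assert np.all(tr[:, 1] == 0.0) and te[0, 1] == 0.0


def test_standardize_idempotent(rng):
    X = rng.standard_normal((50, 4))
    tr1, te1, _ = standardize_features(X, X)
    tr2, _, _ = standardize_features(tr1, te1)
    np.testing.assert_allclose(tr2, tr1, atol=1e-12)


# -- classifiers ------------------------------------------------------------

@pytest.mark.parametrize("spec", default_classifier_specs(),
                         ids=lambda s: s.kind)
def test_separable_classes_are_perfectly_classified(spec, rng):
    Xtr = np.vstack([rng.standard_normal((40, 5)),
                     rng.standard_normal((40, 5)) + 10.0])
    ytr = np.array(["CNT"] * 40 + ["PNES"] * 40)
    Xte = np.vstack([rng.standard_normal((10, 5)),
                     rng.standard_normal((10, 5)) + 10.0])
    yte = np.array(["CNT"] * 10 + ["PNES"] * 10)
    Xtr_s, Xte_s, _ = standardize_features(Xtr, Xte)
    pred, scores = train_and_score(Xtr_s, ytr, Xte_s, spec)
    _, metrics = confusion_metrics(yte, pred)
    assert metrics["accuracy"] == 1.0
    assert scores.shape == (20,)
    # scores oriented PNES-positive
    assert scores[yte == "PNES"].mean() > scores[yte == "CNT"].mean()


def test_single_class_training_rejected(rng):
    X = rng.standard_normal((10, 3))
    with pytest.raises(ValueError):
        train_and_score(X, np.array(["CNT"] * 10), X, ClassifierSpec("LDA"))


@pytest.mark.parametrize("kind", ["LDA", "NB"])
def test_duplicating_training_rows_is_inert(kind, rng):
    """LDA and naive Bayes depend on per-class sufficient statistics, so
    duplicating every training row must not change predictions."""
    Xtr = rng.standard_normal((60, 4))
    ytr = np.array(["CNT", "PNES"] * 30)
    Xte = rng.standard_normal((30, 4))
    spec = ClassifierSpec(kind)
    p1, _ = train_and_score(Xtr, ytr, Xte, spec)
    p2, _ = train_and_score(np.vstack([Xtr, Xtr]), np.tile(ytr, 2), Xte, spec)
    np.testing.assert_array_equal(p1, p2)


# -- metrics ----------------------------------------------------------------

def test_confusion_metric_examples():
    y = np.array(["PNES"] * 10 + ["CNT"] * 10)
    pred = np.concatenate([["PNES"] * 9, ["CNT"], ["CNT"] * 9, ["PNES"]])
    counts, m = confusion_metrics(y, pred)
    assert (counts.TP, counts.TN, counts.FP, counts.FN) == (9, 9, 1, 1)
    assert m["accuracy"] == pytest.approx(0.9)
    _, perfect = confusion_metrics(y, y)
    for key in ("accuracy", "precision", "recall", "f1"):
        assert perfect[key] == 1.0


def test_f1_from_precision_recall_pair():
    # confusion table realizing precision 0.78 and recall 0.90 exactly
    tp, fp, fn, tn = 702, 198, 78, 500
    y = np.array(["PNES"] * (tp + fn) + ["CNT"] * (fp + tn))
    pred = np.concatenate([["PNES"] * tp, ["CNT"] * fn,
                           ["PNES"] * fp, ["CNT"] * tn])
    _, m = confusion_metrics(y, pred)
    assert m["precision"] == pytest.approx(0.78)
    assert m["recall"] == pytest.approx(0.90)
    assert m["f1"] == pytest.approx(2 * 0.78 * 0.90 / 1.68)
    assert abs(m["f1"] - 0.83) <= 0.01  # printed-precision agreement


def test_confusion_rejects_empty_or_mismatched():
    with pytest.raises(ValueError):
        confusion_metrics([], [])
    with pytest.raises(ValueError):
        confusion_metrics(["CNT"], ["CNT", "PNES"])


def test_auc_perfect_and_null(rng):
    y = np.array(["CNT", "CNT", "PNES", "PNES"])
    _, auc = roc_auc([0.0, 0.0, 1.0, 1.0], y)
    assert auc == 1.0
    yb = np.array(["CNT", "PNES"] * 1000)
    _, auc0 = roc_auc(rng.standard_normal(2000), yb)
    assert abs(auc0 - 0.5) < 0.05
    with pytest.raises(ValueError):
        roc_auc([0.1], np.array(["CNT"]))


def mann_whitney_auc(scores, y):
    """Rank-statistic oracle: AUC = U / (n_pos * n_neg), ties averaged."""
    scores = np.asarray(scores, dtype=float)
    pos = scores[y == "PNES"]
    neg = scores[y != "PNES"]
    ranks = sstats.rankdata(scores)
    u = ranks[y == "PNES"].sum() - len(pos) * (len(pos) + 1) / 2
    return u / (len(pos) * len(neg))


def test_auc_equals_rank_statistic_with_ties(rng):
    for _ in range(20):
        n = rng.integers(10, 60)
        scores = rng.integers(0, 5, size=n).astype(float)  # heavy ties
        y = np.where(rng.random(n) < 0.5, "PNES", "CNT")
        if len(set(y)) < 2:
            continue
        _, auc = roc_auc(scores, y)
        assert auc == pytest.approx(mann_whitney_auc(scores, y), abs=1e-12)


# -- experiment -------------------------------------------------------------

def test_experiment_grid_shape_and_summaries():
    table = gaussian_table()
    res = EpochClassificationExperiment(table, seed=0, train_per_class=2).fit()
    # 3 classifiers x (1 RS + 6 LOO)
    assert len(res.records) == 3 * (1 + 6)
    assert set(res.records["scheme"]) == {"random_split", "loo"}
    # summaries recomputable from the per-split records
    ms = res.mean_sd()
    sub = res.records[(res.records.classifier == "SVM")
                      & (res.records.scheme == "loo")]["accuracy"]
    assert ms.loc[("SVM", "loo"), ("accuracy", "mean")] == pytest.approx(
        sub.mean(), abs=1e-12)
    assert ms.loc[("SVM", "loo"), ("accuracy", "std")] == pytest.approx(
        sub.std(ddof=1), abs=1e-12)
    assert "accuracy" in res.summary()


def test_experiment_loo_invariant_to_epoch_order():
    """Shuffling epoch order within the table must not change LOO means
    (splits operate on subjects, not row positions)."""
    table = gaussian_table(seed=5)
    res1 = EpochClassificationExperiment(table, schemes=("loo",),
                                         train_per_class=2).fit()
    res2 = EpochClassificationExperiment(
        table.sample(frac=1, random_state=2).reset_index(drop=True),
        schemes=("loo",), train_per_class=2).fit()
    m1 = res1.records.groupby("classifier")["accuracy"].mean()
    m2 = res2.records.groupby("classifier")["accuracy"].mean()
    pd.testing.assert_series_equal(m1, m2)


def test_experiment_detects_leakage():
    table = gaussian_table()
    exp = EpochClassificationExperiment(table, train_per_class=2)
    plan = make_loo_splits(sorted(set(table.subject_id)))[0]
    plan.train_subjects = plan.train_subjects + plan.test_subjects  # corrupt
    with pytest.raises(RuntimeError):
        exp._split_masks(plan)


def test_experiment_single_class_table_rejected():
    table = gaussian_table()
    with pytest.raises(ValueError):
        EpochClassificationExperiment(table[table.class_label == "CNT"])


def test_epoch_level_split_runs_and_is_flagged():
    table = gaussian_table()
    res = EpochClassificationExperiment(
        table, schemes=("random_split",), epoch_level=True, seed=1).fit()
    assert (res.records["test_subjects"] == "").all()
    assert res.records["accuracy"].min() >= 0.99  # separable either way
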