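"""Classifier training and validation: subject-level random split and
leave-one-subject-out evaluation of SVM / LDA / Gaussian naive Bayes.

The central objects follow the model/results pattern:
``EpochClassificationExperiment`` is built from a feature table and
``fit()`` returns an ``EvaluationResults`` carrying per-split confusion
counts, metrics, ROC curves and mean +/- SD summaries with a ``summary()``
table.

Validation operates on whole subjects: an epoch's subject is either
entirely in the training set or entirely in the test set, and every split
is checked for subject-level leakage at run time. PNES is the positive
class throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import roc_curve
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC

from .spectral import METADATA_COLUMNS, feature_matrix

POSITIVE_CLASS = "PNES"
NEGATIVE_CLASS = "CNT"


@dataclass
class ClassifierSpec:
    """One classifier configuration.

    kind is one of SVM, LDA, NB. The SVM is an RBF-kernel C-SVC with
    gamma = 0.01 and C = 1 by default; degree and coef0 are inert for the
    RBF kernel and kept only for provenance, as is the epsilon that belongs
    to the regression variant. LDA and NB run with library defaults; "NB"
    is Gaussian naive Bayes.
    """

    kind: str
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in ("SVM", "LDA", "NB"):
            raise ValueError(f"unknown classifier kind {self.kind!r}")
        if self.kind == "SVM":
            gamma = self.params.get("gamma", 0.01)
            C = self.params.get("C", 1.0)
            if not (gamma > 0 and C > 0):
                raise ValueError("SVM needs gamma > 0 and C > 0")

    def build(self):
        if self.kind == "SVM":
            return SVC(
                kernel="rbf",
                gamma=self.params.get("gamma", 0.01),
                C=self.params.get("C", 1.0),
                coef0=self.params.get("coef0", 0.0),
                degree=self.params.get("degree", 3),
            )
        if self.kind == "LDA":
            return LinearDiscriminantAnalysis(**self.params)
        return GaussianNB(**self.params)


def default_classifier_specs():
    return (ClassifierSpec("SVM"), ClassifierSpec("LDA"), ClassifierSpec("NB"))


@dataclass
class SplitPlan:
    """A subject-level train/test partition."""

    scheme: str  # "random_split" or "loo"
    train_subjects: tuple
    test_subjects: tuple
    seed: int | None = None

    def __post_init__(self):
        train, test = set(self.train_subjects), set(self.test_subjects)
        if train & test:
            raise ValueError(f"train/test subjects overlap: {sorted(train & test)}")
        if not train or not test:
            raise ValueError("both train and test must be non-empty")


@dataclass
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self):
        return self.TP + self.TN + self.FP + self.FN


def make_random_split(subject_ids_by_class, train_per_class=7, seed=0):
    """Uniform subject-level 70/30-style split: ``train_per_class`` training
    subjects drawn per class without replacement, remainder to test."""
    rng = np.random.default_rng(seed)
    train, test = [], []
    for label in sorted(subject_ids_by_class):
        ids = sorted(subject_ids_by_class[label])
        if len(ids) <= train_per_class:
            raise ValueError(
                f"class {label} has {len(ids)} subjects, "
                f"need more than train_per_class={train_per_class}"
            )
        chosen = rng.choice(len(ids), size=train_per_class, replace=False)
        chosen = {ids[i] for i in chosen}
        train.extend(sorted(chosen))
        test.extend(s for s in ids if s not in chosen)
    return SplitPlan("random_split", tuple(train), tuple(test), seed=seed)


def make_loo_splits(subject_ids):
    """Leave-one-subject-out: one plan per subject, that subject as test."""
    ids = sorted(set(subject_ids))
    if len(ids) < 2:
        raise ValueError("leave-one-out needs at least 2 subjects")
    return [
        SplitPlan("loo", tuple(s for s in ids if s != held_out), (held_out,))
        for held_out in ids
    ]


def standardize_features(train, test):
    """Per-column z-scoring fitted on the training matrix only.

    Columns with zero training SD are mapped to 0 in both partitions.
    Returns (train', test', (mean, sd)).
    """
    mean = train.mean(axis=0)
    sd = train.std(axis=0)
    zero = sd == 0.0
    safe = np.where(zero, 1.0, sd)
    train_z = (train - mean) / safe
    test_z = (test - mean) / safe
    train_z[:, zero] = 0.0
    test_z[:, zero] = 0.0
    return train_z, test_z, (mean, sd)


def train_and_score(train_X, train_y, test_X, spec):
    """Fit one classifier and score the test epochs.

    Returns (predicted labels, continuous scores) where the score is the
    decision value (SVM, LDA) or the positive-class probability (NB),
    oriented so larger means more PNES-like.
    """
    classes = np.unique(train_y)
    if classes.size < 2:
        raise ValueError("training set must contain both classes")
    clf = spec.build()
    clf.fit(train_X, train_y)
    pred = clf.predict(test_X)
    if hasattr(clf, "decision_function"):
        scores = clf.decision_function(test_X)
        if list(clf.classes_)[-1] != POSITIVE_CLASS:
            scores = -scores
    else:
        pos = list(clf.classes_).index(POSITIVE_CLASS)
        scores = clf.predict_proba(test_X)[:, pos]
    return pred, scores


def confusion_metrics(true_labels, predicted_labels, positive=POSITIVE_CLASS):
    """Confusion counts and the standard metrics, PNES as positive.

    Returns (ConfusionCounts, metrics dict). Per-class precision/recall/F1
    are computed with each class in turn as the positive one; accuracy is
    (TP + TN) / total.
    """
    true_labels = np.asarray(true_labels)
    predicted_labels = np.asarray(predicted_labels)
    if true_labels.size == 0 or true_labels.shape != predicted_labels.shape:
        raise ValueError("label vectors must be equal-length and non-empty")
    tp = int(np.sum((true_labels == positive) & (predicted_labels == positive)))
    tn = int(np.sum((true_labels != positive) & (predicted_labels != positive)))
    fp = int(np.sum((true_labels != positive) & (predicted_labels == positive)))
    fn = int(np.sum((true_labels == positive) & (predicted_labels != positive)))
    counts = ConfusionCounts(TP=tp, TN=tn, FP=fp, FN=fn)

    def _prf(tp_, fp_, fn_):
        p = tp_ / (tp_ + fp_) if tp_ + fp_ else 0.0
        r = tp_ / (tp_ + fn_) if tp_ + fn_ else 0.0
        f1 = 2.0 * p * r / (p + r) if p + r else 0.0
        return p, r, f1

    p_pos, r_pos, f_pos = _prf(tp, fp, fn)
    p_neg, r_neg, f_neg = _prf(tn, fn, fp)
    metrics = {
        "accuracy": (tp + tn) / counts.total,
        "precision": p_pos, "recall": r_pos, "f1": f_pos,
        "precision_cnt": p_neg, "recall_cnt": r_neg, "f1_cnt": f_neg,
        "precision_macro": (p_pos + p_neg) / 2.0,
        "recall_macro": (r_pos + r_neg) / 2.0,
        "f1_macro": (f_pos + f_neg) / 2.0,
    }
    return counts, metrics


def roc_auc(scores, true_labels, positive=POSITIVE_CLASS):
    """ROC points (threshold sweep, ties grouped) and trapezoidal AUC."""
    true_labels = np.asarray(true_labels)
    y = true_labels == positive
    if y.all() or not y.any():
        raise ValueError("ROC needs both classes in the test set")
    fpr, tpr, _ = roc_curve(y, np.asarray(scores, dtype=float))
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


class EpochClassificationExperiment:
    """Grid evaluation of epoch classifiers on a feature table.

    Parameters
    ----------
    table : DataFrame
        Feature table with subject_id / class_label / epoch_index metadata
        columns followed by feature columns.
    classifiers : sequence of ClassifierSpec
    schemes : sequence of {"random_split", "loo"}
    train_per_class : int
        Training subjects per class for the random split (7 by default: with
        10+10 subjects and 120 epochs each this yields 1,680 training epochs).
    n_random_splits : int
        Number of independent random-split repetitions.
    standardize : bool
        Train-fitted z-scoring of the features (on by default; the RBF SVM
        at gamma = 0.01 is numerically degenerate on raw PSD moments).
    epoch_level : bool
        If True, the random split partitions epochs instead of subjects.
        Leakage-prone: epochs of one subject land on both sides. Off by
        default and only present to quantify that optimism.
    seed : int
        Drives the random-split subject draw.
    """

    def __init__(self, table, classifiers=None, schemes=("random_split", "loo"),
                 train_per_class=7, n_random_splits=1, standardize=True,
                 epoch_level=False, seed=0):
        self.table = table
        self.classifiers = tuple(classifiers or default_classifier_specs())
        self.schemes = tuple(schemes)
        self.train_per_class = train_per_class
        self.n_random_splits = n_random_splits
        self.standardize = standardize
        self.epoch_level = epoch_level
        self.seed = seed

        self.X, self.feature_cols = feature_matrix(table)
        self.y = table["class_label"].to_numpy()
        self.subjects = table["subject_id"].to_numpy()
        classes = set(self.y)
        if len(classes) < 2:
            raise ValueError(f"feature table holds a single class: {classes}")

    # -- split plans --------------------------------------------------------

    def subject_ids_by_class(self):
        out = {}
        for sid, lab in zip(self.subjects, self.y):
            out.setdefault(lab, set()).add(sid)
        return {lab: sorted(ids) for lab, ids in out.items()}

    def split_plans(self, scheme):
        if scheme == "random_split":
            return [
                make_random_split(self.subject_ids_by_class(),
                                  self.train_per_class, seed=self.seed + r)
                for r in range(self.n_random_splits)
            ]
        if scheme == "loo":
            return make_loo_splits(self.subjects)
        raise ValueError(f"unknown scheme {scheme!r}")

    def _split_masks(self, plan):
        train_mask = np.isin(self.subjects, plan.train_subjects)
        test_mask = np.isin(self.subjects, plan.test_subjects)
        # leakage guard: no subject may appear on both sides
        both = set(self.subjects[train_mask]) & set(self.subjects[test_mask])
        if both:
            raise RuntimeError(f"subject leakage across split: {sorted(both)}")
        return train_mask, test_mask

    def _epoch_level_masks(self, rng):
        n = len(self.y)
        idx = rng.permutation(n)
        n_train = int(round(0.7 * n))
        train_mask = np.zeros(n, dtype=bool)
        train_mask[idx[:n_train]] = True
        return train_mask, ~train_mask

    # -- fitting ------------------------------------------------------------

    def fit(self):
        """Run the full classifier x scheme x split grid."""
        records, rocs, pooled = [], {}, {}
        for scheme in self.schemes:
            if scheme == "random_split" and self.epoch_level:
                rng = np.random.default_rng(self.seed)
                masks = [
                    self._epoch_level_masks(rng)
                    for _ in range(self.n_random_splits)
                ]
                plans = [None] * len(masks)
            else:
                plans = self.split_plans(scheme)
                masks = [self._split_masks(p) for p in plans]
            for split_id, (plan, (tr, te)) in enumerate(zip(plans, masks)):
                Xtr, Xte = self.X[tr], self.X[te]
                ytr, yte = self.y[tr], self.y[te]
                if self.standardize:
                    Xtr, Xte, _ = standardize_features(Xtr, Xte)
                for spec in self.classifiers:
                    pred, scores = train_and_score(Xtr, ytr, Xte, spec)
                    counts, metrics = confusion_metrics(yte, pred)
                    rec = {
                        "classifier": spec.kind, "scheme": scheme,
                        "split_id": split_id,
                        "test_subjects": ",".join(plan.test_subjects) if plan else "",
                        "n_test_epochs": counts.total,
                        "TP": counts.TP, "TN": counts.TN,
                        "FP": counts.FP, "FN": counts.FN,
                        **metrics,
                    }
                    if len(set(yte)) == 2:
                        points, auc = roc_auc(scores, yte)
                        rec["auc"] = auc
                        rocs[(spec.kind, scheme, split_id)] = points
                    else:
                        rec["auc"] = np.nan
                    records.append(rec)
                    key = (spec.kind, scheme)
                    acc = pooled.setdefault(key, {"y": [], "pred": [], "score": []})
                    acc["y"].append(yte)
                    acc["pred"].append(pred)
                    acc["score"].append(scores)
        pooled = {
            k: {name: np.concatenate(v[name]) for name in v}
            for k, v in pooled.items()
        }
        return EvaluationResults(
            self, pd.DataFrame.from_records(records), rocs, pooled)


class EvaluationResults:
    """Per-split evaluation records plus mean +/- SD summaries.

    ``records`` is a DataFrame with one row per classifier x scheme x split
    (confusion counts, metrics, AUC); ``roc_points`` maps (classifier,
    scheme, split_id) to an (n, 2) array of (FPR, TPR) points.
    """

    SUMMARY_METRICS = ("accuracy", "precision", "recall", "f1", "auc")

    def __init__(self, experiment, records, roc_points, pooled=None):
        self.experiment = experiment
        self.records = records
        self.roc_points = roc_points
        self.pooled = pooled or {}

    def pooled_metrics(self, classifier, scheme):
        """Metrics over all test epochs of a scheme pooled into one
        confusion table.

        The per-split view is degenerate for leave-one-subject-out (each
        test set holds one class, so precision and AUC are undefined per
        split); pooling the held-out predictions restores them.
        """
        acc = self.pooled[(classifier, scheme)]
        counts, metrics = confusion_metrics(acc["y"], acc["pred"])
        _, metrics["auc"] = roc_auc(acc["score"], acc["y"])
        return counts, metrics

    def pooled_per_class_table(self, classifier, scheme):
        _, m = self.pooled_metrics(classifier, scheme)
        return pd.DataFrame(
            {
                "precision": [m["precision_cnt"], m["precision"]],
                "recall": [m["recall_cnt"], m["recall"]],
                "f1": [m["f1_cnt"], m["f1"]],
            },
            index=[NEGATIVE_CLASS, POSITIVE_CLASS],
        )

    def mean_sd(self):
        """Mean and SD of the headline metrics across splits."""
        grouped = self.records.groupby(["classifier", "scheme"])
        out = grouped[list(self.SUMMARY_METRICS)].agg(["mean", "std"])
        return out.fillna(0.0)

    def metric(self, classifier, scheme, name="accuracy"):
        mask = (self.records["classifier"] == classifier) & \
               (self.records["scheme"] == scheme)
        vals = self.records.loc[mask, name]
        return float(vals.mean()), float(vals.std(ddof=1)) if len(vals) > 1 else 0.0

    def mean_roc(self, classifier, scheme, grid_size=101):
        """Vertical average of per-split ROC curves on a common FPR grid."""
        grid = np.linspace(0.0, 1.0, grid_size)
        curves = [
            np.interp(grid, pts[:, 0], pts[:, 1])
            for (clf, sch, _), pts in sorted(self.roc_points.items())
            if clf == classifier and sch == scheme
        ]
        if not curves:
            raise ValueError(f"no ROC curves for {classifier}/{scheme}")
        return grid, np.mean(curves, axis=0)

    def per_class_table(self, classifier, scheme):
        """Mean per-class precision/recall/F1 (CNT and PNES rows)."""
        mask = (self.records["classifier"] == classifier) & \
               (self.records["scheme"] == scheme)
        sub = self.records.loc[mask]
        return pd.DataFrame(
            {
                "precision": [sub["precision_cnt"].mean(), sub["precision"].mean()],
                "recall": [sub["recall_cnt"].mean(), sub["recall"].mean()],
                "f1": [sub["f1_cnt"].mean(), sub["f1"].mean()],
            },
            index=[NEGATIVE_CLASS, POSITIVE_CLASS],
        )

    def summary(self):
        """Human-readable report: per-class scores then mean +/- SD blocks."""
        lines = []
        for spec in self.experiment.classifiers:
            for scheme in self.experiment.schemes:
                sub = self.records[
                    (self.records["classifier"] == spec.kind)
                    & (self.records["scheme"] == scheme)
                ]
                if sub.empty:
                    continue
                lines.append(f"== {spec.kind} ({scheme}) ==")
                if (spec.kind, scheme) in self.pooled:
                    tab = self.pooled_per_class_table(spec.kind, scheme)
                else:
                    tab = self.per_class_table(spec.kind, scheme)
                lines.append(tab.round(3).to_string())
                lines.append(
                    f"{'accuracy':>10}: {sub['accuracy'].mean():.3f} +/- "
                    f"{(sub['accuracy'].std(ddof=1) if len(sub) > 1 else 0.0):.3f}"
                    "  (mean over splits)")
                if (spec.kind, scheme) in self.pooled:
                    _, pm = self.pooled_metrics(spec.kind, scheme)
                    lines.append(
                        f"{'pooled':>10}: acc {pm['accuracy']:.3f}, "
                        f"auc {pm['auc']:.3f}")
                lines.append("")
        return "\n".join(lines)

    def to_json(self, path):
        doc = {
            "records": self.records.to_dict(orient="records"),
            "roc": {
                f"{clf}|{sch}|{sid}": pts.tolist()
                for (clf, sch, sid), pts in self.roc_points.items()
            },
        }
        import json
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1, default=float)
        return path

    def to_csv(self, path):
        self.records.to_csv(path, index=False)
        return path


def evaluate(table, classifiers=None, schemes=("random_split", "loo"),
             seed=0, **kwargs):
    """One-call wrapper: build the experiment and fit it."""
    exp = EpochClassificationExperiment(
        table, classifiers=classifiers, schemes=schemes, seed=seed, **kwargs
    )
    return exp.fit()
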