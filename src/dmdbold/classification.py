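"""Linear-SVM benchmarking of feature sets.

Feature sets are compared on a common footing: the same stratified
rounds x folds cross-validation splits (shared split seed) are applied to
each variant, a linear support-vector machine is trained per fold with
train-split standardization, and five confusion-matrix metrics are recorded
per fold with the patient group as the positive class.  Variants:

* ``plain``         — all features ("DMDp");
* ``per_fold_lasso``— a single LASSO selection on the training split only,
                      then classification on the selected columns
                      ("DMDp-LASSO"; leakage-free);
* ``fixed_subset``  — restrict to a caller-supplied feature subset, e.g.
                      the repeated-LASSO intersection
                      ("DMDp-LASSO-intersect"; note the subset is typically
                      computed on all data, so this variant carries an
                      optimistic selection bias that the report names);
* ``chance``        — training labels permuted before fitting
                      ("DMDp-chance"; empirical noise floor near 0.5).

Metric distributions of two variants are compared with an unpaired pooled
permutation test of the difference in means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .features import FeatureTable
from .selection import LassoConfig, lasso_fit, _standardize

__all__ = [
    "MetricSet",
    "ComparisonResult",
    "METRIC_NAMES",
    "classification_metrics",
    "cross_validated_svm",
    "compare_feature_sets_permutation",
]

METRIC_NAMES = ("accuracy", "precision", "recall", "f1", "specificity")

VARIANTS = ("plain", "per_fold_lasso", "fixed_subset", "chance")


def classification_metrics(tp: int, fp: int, fn: int, tn: int) -> dict[str, float]:
    """Five confusion-matrix metrics with patient = positive class.

    Ratios with a zero denominator are reported as 0.0 and flagged in the
    ``degenerate`` entry rather than raising: they occur legitimately when
    a fold predicts a single class.
    """
    counts = (tp, fp, fn, tn)
    if any(c < 0 for c in counts):
        raise ValueError("negative confusion-matrix counts")
    total = sum(counts)
    if total < 1:
        raise ValueError("empty confusion matrix")
    degenerate = []

    def ratio(num, den, name):
        if den == 0:
            degenerate.append(name)
            return 0.0
        return num / den

    precision = ratio(tp, tp + fp, "precision")
    recall = ratio(tp, tp + fn, "recall")
    out = {
        "accuracy": (tp + tn) / total,
        "precision": precision,
        "recall": recall,
        "f1": ratio(2 * precision * recall, precision + recall, "f1"),
        "specificity": ratio(tn, tn + fp, "specificity"),
    }
    out["degenerate"] = degenerate
    return out


@dataclass
class MetricSet:
    """rounds x folds rows of the five metrics for one feature-set variant."""

    rows: np.ndarray  # (n_rows, 5)
    feature_set_name: str

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=float)
        if self.rows.ndim != 2 or self.rows.shape[1] != len(METRIC_NAMES):
            raise ValueError(f"rows must be (n, {len(METRIC_NAMES)})")
        if np.any(self.rows < 0) or np.any(self.rows > 1):
            raise ValueError("metrics must lie in [0, 1]")

    def mean(self) -> dict[str, float]:
        return dict(zip(METRIC_NAMES, self.rows.mean(axis=0)))

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.rows, columns=list(METRIC_NAMES))
        frame.insert(0, "feature_set", self.feature_set_name)
        return frame


def cross_validated_svm(
    table: FeatureTable,
    rounds: int = 3,
    folds: int = 10,
    variant: str = "plain",
    subset: np.ndarray | None = None,
    seed: int = 0,
    C: float = 1.0,
    lasso_config: LassoConfig | None = None,
    name: str | None = None,
) -> MetricSet:
    """Repeated stratified k-fold linear-SVM evaluation of one variant.

    Returns rounds*folds metric rows.  The fold structure depends only on
    ``seed``, ``rounds`` and ``folds``, so different variants evaluated with
    the same seed see identical train/test divisions.
    """
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}")
    if variant == "fixed_subset":
        if subset is None or len(subset) == 0:
            raise ValueError("fixed_subset variant needs a non-empty subset")
        subset = np.asarray(subset, dtype=int)
    if table.n_subjects < folds:
        raise ValueError("fewer subjects than folds")

    y = table.labels
    rows = []
    chance_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(11,))
    )
    for rnd in range(rounds):
        splitter = StratifiedKFold(n_splits=folds, shuffle=True,
                                   random_state=seed + 1000 * rnd)
        for train_idx, test_idx in splitter.split(table.values, y):
            X_train, X_test = table.values[train_idx], table.values[test_idx]
            y_train, y_test = y[train_idx], y[test_idx]
            if len(np.unique(y_test)) < 2 or len(np.unique(y_train)) < 2:
                raise ValueError("a fold contains a single class")

            if variant == "fixed_subset":
                X_train, X_test = X_train[:, subset], X_test[:, subset]
            elif variant == "per_fold_lasso":
                cfg = lasso_config or LassoConfig(seed=seed)
                train_table = FeatureTable(
                    values=X_train, feature_names=list(table.feature_names),
                    labels=y_train,
                )
                beta = lasso_fit(train_table, cfg)
                picked = np.flatnonzero(beta != 0.0)
                if picked.size:  # empty selection falls back to all features
                    X_train, X_test = X_train[:, picked], X_test[:, picked]
            elif variant == "chance":
                y_train = chance_rng.permutation(y_train)

            mu = X_train.mean(axis=0)
            sd = X_train.std(axis=0)
            sd[sd == 0] = 1.0
            X_train = (X_train - mu) / sd
            X_test = (X_test - mu) / sd

            clf = SVC(kernel="linear", C=C)
            clf.fit(X_train, y_train)
            pred = clf.predict(X_test)
            tp = int(np.sum((pred == 1) & (y_test == 1)))
            fp = int(np.sum((pred == 1) & (y_test == 0)))
            fn = int(np.sum((pred == 0) & (y_test == 1)))
            tn = int(np.sum((pred == 0) & (y_test == 0)))
            m = classification_metrics(tp, fp, fn, tn)
            rows.append([m[k] for k in METRIC_NAMES])
    return MetricSet(rows=np.asarray(rows), feature_set_name=name or variant)


@dataclass
class ComparisonResult:
    """Per-metric permutation p-values for one pair of metric sets."""

    pair: tuple[str, str]
    p_values: dict[str, float]
    mean_difference: dict[str, float]
    B: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "metric": list(self.p_values),
                "mean_difference": [self.mean_difference[m] for m in self.p_values],
                "p_value": [self.p_values[m] for m in self.p_values],
            }
        )


def compare_feature_sets_permutation(
    a: MetricSet, b: MetricSet, B: int = 1000, seed: int = 0
) -> ComparisonResult:
    """Unpaired pooled permutation test per metric.

    Statistic: |mean(a) - mean(b)|; the null pools the two sets' fold rows
    and reassigns them at random into groups of the original sizes.
    """
    if a.rows.shape[0] != b.rows.shape[0]:
        raise ValueError("metric sets must have equal row counts")
    rng = np.random.default_rng(seed)
    n = a.rows.shape[0]
    pooled = np.vstack([a.rows, b.rows])  # (2n, 5)
    observed = np.abs(a.rows.mean(axis=0) - b.rows.mean(axis=0))
    count = np.zeros(len(METRIC_NAMES), dtype=int)
    for _ in range(B):
        perm = rng.permutation(2 * n)
        stat = np.abs(
            pooled[perm[:n]].mean(axis=0) - pooled[perm[n:]].mean(axis=0)
        )
        count += stat >= observed
    pvals = (count + 1) / (B + 1)
    return ComparisonResult(
        pair=(a.feature_set_name, b.feature_set_name),
        p_values=dict(zip(METRIC_NAMES, pvals)),
        mean_difference=dict(
            zip(METRIC_NAMES, a.rows.mean(axis=0) - b.rows.mean(axis=0))
        ),
        B=B,
    )
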