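"""Stability-style feature selection via repeated LASSO plus permutation tests.

A single L1-penalized regression of the binary group label on the feature
table picks a sparse discriminative subset, but which features enter the
support depends on the data subsample the fit sees.  The procedure here
exploits that instability instead of fighting it: the LASSO is refit many
times, each on the training portion of a freshly shuffled k-fold split (a
random ~(k-1)/k subsample), and only features selected in *every* run are
kept.  The intersection is then vetted feature-by-feature with label
permutation tests of the group mean difference; survivors at level alpha
are called abnormal regions, and the mean coefficient over runs reports
each one's direction (positive = patient group higher, with patients coded
1 and controls 0) and strength.

The LASSO objective is

    min_beta  ( ||y - X beta||^2 + gamma * ||beta||_1 ) / (2N),

i.e. the penalty shares the 1/(2N) normalisation with the residual, so the
effective scikit-learn ``alpha`` is ``gamma / (2N)`` and, for a single
standardized feature, the solution is the soft threshold of the
feature-label covariance at gamma/(2N).  Under this normalisation
``gamma = 0.2`` is a light penalty: each run keeps a few dozen of several
hundred features and the *intersection* across subsample-randomized runs,
not the penalty alone, does the pruning.  Features are standardized to
zero mean and unit variance before fitting (the penalty is
scale-sensitive); labels stay 0/1.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso

from .features import FeatureTable

__all__ = [
    "LassoConfig",
    "SelectionResults",
    "RepeatedLasso",
    "lasso_fit",
    "repeated_lasso_selection",
    "mean_coefficients",
    "group_difference_permutation_test",
    "call_abnormal_regions",
]

logger = logging.getLogger(__name__)

#: coefficients below this magnitude are treated as zero (solver float dust)
COEF_FLOOR = 1e-10


@dataclass
class LassoConfig:
    """Settings for one family of repeated LASSO selections.

    gamma : L1 penalty strength (default 0.2, appropriate for standardized
        features against 0/1 labels).
    n_folds : folds in the shuffled split each run draws its training
        subsample from (default 10, i.e. fits on ~90% of subjects).
    n_repeats : number of independent runs intersected (default 1000).
    standardize : z-score features before fitting (default True).
    seed : base seed; run r uses an independent child stream.
    """

    gamma: float = 0.2
    n_folds: int = 10
    n_repeats: int = 1000
    standardize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.gamma) and self.gamma > 0):
            raise ValueError("gamma must be positive")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Z-score columns; constant columns are zeroed with a warning and
    reported in the returned mask (they can never be selected)."""
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    constant = sd == 0
    if np.any(constant):
        warnings.warn(
            f"{int(constant.sum())} constant feature column(s) dropped from "
            "standardization", stacklevel=3,
        )
    sd_safe = np.where(constant, 1.0, sd)
    Z = (X - mu) / sd_safe
    Z[:, constant] = 0.0
    return Z, constant


def lasso_fit(
    table: FeatureTable,
    config: LassoConfig,
    row_subset: np.ndarray | None = None,
) -> np.ndarray:
    """One LASSO fit; returns the length-p coefficient vector.

    ``row_subset`` restricts the fit to a subject subsample (used by the
    repeated-selection driver); coefficients are always reported for the
    full feature set.
    """
    X = table.values if row_subset is None else table.values[row_subset]
    y = table.labels.astype(float) if row_subset is None else table.labels[row_subset].astype(float)
    if config.standardize:
        X, _ = _standardize(X)
    # gamma/(2N): the L1 term shares the 1/(2N) normalisation (N = samples
    # actually entering this fit)
    model = Lasso(alpha=config.gamma / (2 * X.shape[0]), fit_intercept=True,
                  max_iter=10000)
    model.fit(X, y)
    coefs = model.coef_.copy()
    coefs[np.abs(coefs) < COEF_FLOOR] = 0.0
    return coefs


@dataclass
class SelectionResults:
    """Output of the repeated-selection procedure.

    ``per_run_selected`` holds each run's support; ``intersection`` the
    features present in every support; ``mean_coefficients`` the average
    coefficient over runs for each intersected feature; ``perm_pvalues``
    and ``abnormal`` are filled by :func:`call_abnormal_regions`.
    """

    per_run_selected: list[np.ndarray]
    intersection: np.ndarray
    coef_matrix: np.ndarray  # (n_repeats, p)
    feature_names: list[str]
    config: LassoConfig
    mean_coefficients: np.ndarray | None = None
    perm_pvalues: np.ndarray | None = None
    abnormal: np.ndarray | None = None
    alpha: float = 0.05
    network_map: dict = field(default_factory=dict)

    @property
    def selection_frequency(self) -> np.ndarray:
        """Fraction of runs selecting each feature (length p)."""
        p = self.coef_matrix.shape[1]
        freq = np.zeros(p)
        for sel in self.per_run_selected:
            freq[sel] += 1.0
        return freq / len(self.per_run_selected)

    def summary(self) -> pd.DataFrame:
        """Intersected features with mean coefficient, direction and
        (when computed) permutation p-value and abnormal call."""
        idx = self.intersection
        data = {
            "feature": [self.feature_names[i] for i in idx],
            "mean_coefficient": self.mean_coefficients
            if self.mean_coefficients is not None
            else self.coef_matrix[:, idx].mean(axis=0),
        }
        data["direction"] = np.where(
            np.asarray(data["mean_coefficient"]) > 0, "patient_higher", "patient_lower"
        )
        if self.perm_pvalues is not None:
            data["p_value"] = self.perm_pvalues
            data["abnormal"] = [i in set(self.abnormal.tolist()) for i in idx]
        if self.network_map:
            data["network"] = [
                self.network_map.get(self._region_of(name), "")
                for name in data["feature"]
            ]
        frame = pd.DataFrame(data)
        return frame.sort_values("mean_coefficient", ascending=False).reset_index(drop=True)

    @staticmethod
    def _region_of(feature_name: str) -> str:
        return feature_name.split(":", 1)[-1]

    def to_json(self) -> str:
        payload = {
            "config": {
                "gamma": self.config.gamma,
                "n_folds": self.config.n_folds,
                "n_repeats": self.config.n_repeats,
                "standardize": self.config.standardize,
                "seed": self.config.seed,
            },
            "alpha": self.alpha,
            "selection_frequency": {
                self.feature_names[i]: f
                for i, f in enumerate(self.selection_frequency)
                if f > 0
            },
            "intersection": [self.feature_names[i] for i in self.intersection],
            "mean_coefficients": None
            if self.mean_coefficients is None
            else dict(zip([self.feature_names[i] for i in self.intersection],
                          self.mean_coefficients.tolist())),
            "perm_pvalues": None
            if self.perm_pvalues is None
            else dict(zip([self.feature_names[i] for i in self.intersection],
                          self.perm_pvalues.tolist())),
            "abnormal": None
            if self.abnormal is None
            else [self.feature_names[i] for i in self.abnormal],
        }
        return json.dumps(payload, indent=1, sort_keys=True)


class RepeatedLasso:
    """Repeated-LASSO selection model over a feature table.

    ``fit()`` runs ``config.n_repeats`` LASSO regressions, each on the
    training portion (all folds but one) of a freshly shuffled
    ``config.n_folds``-fold split of the subjects, and intersects the
    supports.  Call :func:`call_abnormal_regions` (or ``fit`` with
    ``permutation_B``) to complete the abnormal-region calls.
    """

    def __init__(self, table: FeatureTable, config: LassoConfig | None = None):
        self.table = table
        self.config = config or LassoConfig()
        if table.n_subjects < self.config.n_folds:
            raise ValueError("fewer subjects than folds")

    def fit(self, permutation_B: int | None = None, alpha: float = 0.05,
            network_map: dict | None = None) -> SelectionResults:
        cfg = self.config
        n = self.table.n_subjects
        fold_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=cfg.seed, spawn_key=(0,))
        )
        supports: list[np.ndarray] = []
        coefs = np.empty((cfg.n_repeats, self.table.n_features))
        for r in range(cfg.n_repeats):
            order = fold_rng.permutation(n)
            held_out = order[: n // cfg.n_folds]  # one fold held out
            train = np.setdiff1d(order, held_out)
            beta = lasso_fit(self.table, cfg, row_subset=train)
            coefs[r] = beta
            supports.append(np.flatnonzero(beta != 0.0))
        inter = supports[0]
        for sel in supports[1:]:
            inter = np.intersect1d(inter, sel)
        if inter.size == 0:
            warnings.warn("repeated LASSO intersection is empty", stacklevel=2)
        result = SelectionResults(
            per_run_selected=supports,
            intersection=inter,
            coef_matrix=coefs,
            feature_names=list(self.table.feature_names),
            config=cfg,
            network_map=network_map or {},
        )
        result.mean_coefficients = mean_coefficients(coefs, inter)
        if permutation_B is not None:
            call_abnormal_regions(result, self.table, alpha=alpha, B=permutation_B)
        return result


def repeated_lasso_selection(table: FeatureTable,
                             config: LassoConfig) -> SelectionResults:
    """Functional wrapper around :class:`RepeatedLasso` (selection only)."""
    return RepeatedLasso(table, config).fit()


def mean_coefficients(per_run_coefs: np.ndarray, intersection: np.ndarray) -> np.ndarray:
    """Average coefficient over runs for each intersected feature."""
    per_run_coefs = np.asarray(per_run_coefs)
    intersection = np.asarray(intersection, dtype=int)
    return per_run_coefs[:, intersection].mean(axis=0)


def group_difference_permutation_test(
    feature_values: np.ndarray,
    labels: np.ndarray,
    B: int = 1000,
    seed: int = 0,
) -> float:
    """Two-sided label-permutation test of the group mean difference.

    Statistic: |mean(patient) - mean(control)|.  The p-value uses the
    add-one estimator (observed + 1 over B + 1), so it is bounded below by
    1/(B+1) and can never be exactly zero.
    """
    x = np.asarray(feature_values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if B < 1:
        raise ValueError("B must be >= 1")
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("both groups must be non-empty")
    observed = abs(x[labels == 1].mean() - x[labels == 0].mean())
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(B):
        perm = rng.permutation(labels)
        stat = abs(x[perm == 1].mean() - x[perm == 0].mean())
        if stat >= observed:
            count += 1
    return (count + 1) / (B + 1)


def call_abnormal_regions(
    result: SelectionResults,
    table: FeatureTable,
    alpha: float = 0.05,
    B: int = 1000,
    seed: int | None = None,
) -> SelectionResults:
    """Permutation-test every intersected feature; p < alpha => abnormal.

    Completes ``result`` in place (p-values, abnormal set, alpha) and
    returns it.  Per-feature test seeds derive from the selection seed so
    the whole procedure is reproducible.
    """
    base_seed = result.config.seed if seed is None else seed
    idx = result.intersection
    streams = np.random.SeedSequence(entropy=base_seed, spawn_key=(7,)).spawn(
        max(1, idx.size)
    )
    pvals = np.array([
        group_difference_permutation_test(
            table.values[:, j], table.labels, B=B,
            seed=streams[i].generate_state(1)[0] % (2**31),
        )
        for i, j in enumerate(idx)
    ]) if idx.size else np.empty(0)
    result.perm_pvalues = pvals
    result.alpha = alpha
    result.abnormal = idx[pvals < alpha] if idx.size else idx.copy()
    logger.info(
        "%d intersected feature(s), %d abnormal at alpha=%g",
        idx.size, result.abnormal.size, alpha,
    )
    return result
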