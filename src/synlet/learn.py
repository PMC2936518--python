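"""Ensemble learning for imbalanced gene-pair classification.

The training pipeline mirrors the rare-class treatment standard in
genetic-interaction prediction: the negative (majority) class is
randomly under-sampled to ``ratio`` times the positive class for
*training only*; test sets always keep the true class skew so that
evaluation remains unbiased.  Several base classifiers are fitted on the
identical balanced, mean-imputed table, and their per-example SL
probabilities are combined by a noisy-AND score

    Score(x) = prod_i p_i(x) - prod_i (1 - p_i(x)),

the difference between the products of the classifiers' SL and non-SL
probabilities; higher means more likely synthetic lethal.  The score
lies in [-1, 1], is non-decreasing in every p_i and antisymmetric under
p -> 1 - p.

A stratified cross-validation harness scores every labelled example
exactly once with a model that never saw it, and — when SL-dependent
overlay features are requested — rebuilds the known-SL network from the
training fold's positives only, so no test label leaks into a feature.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .features import (
    FeatureSpec,
    SL_NETWORK_NAME,
    assemble_feature_matrix,
    build_sl_dependent_catalog,
)
from .networks import GenePair, WeightedNetwork, network_from_pairs

logger = logging.getLogger(__name__)

PROB_EPS = 1e-6  # hard 0/1 probabilities are clipped so products stay informative

__all__ = [
    "undersample",
    "impute_missing",
    "noisy_and_score",
    "EnsembleModel",
    "train_ensemble",
    "cross_validate",
    "least_connected_split",
    "make_classifier",
    "DEFAULT_CLASSIFIERS",
    "FAST_CLASSIFIERS",
]


# ---------------------------------------------------------------------------
# seeding: all randomness flows from one seed via named sub-streams
# ---------------------------------------------------------------------------

def _substream(seed: int, name: str) -> int:
    """Deterministic 31-bit child seed for a named random sub-stream."""
    h = np.random.SeedSequence([seed & 0x7FFFFFFF, abs(hash_name(name))])
    return int(h.generate_state(1)[0] & 0x7FFFFFFF)


def hash_name(name: str) -> int:
    # stable across processes (unlike builtin hash of str)
    h = 2166136261
    for ch in name.encode():
        h = ((h ^ ch) * 16777619) & 0xFFFFFFFF
    return h


# ---------------------------------------------------------------------------
# under-sampling and imputation
# ---------------------------------------------------------------------------

def undersample(
    matrix: pd.DataFrame,
    labels: pd.Series,
    ratio: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Keep all positives and floor(ratio * n_pos) random negatives.

    Sampling is uniform without replacement and deterministic under a
    fixed seed.  ``ratio`` below 1 or demanding more negatives than
    exist is an error (the message names the maximum feasible ratio).
    """
    y = labels.astype(int)
    pos_idx = np.flatnonzero(y.to_numpy() == 1)
    neg_idx = np.flatnonzero(y.to_numpy() == 0)
    if ratio < 1:
        raise ValueError("ratio must be >= 1")
    if pos_idx.size == 0:
        raise ValueError("no positive examples to anchor under-sampling")
    n_neg_keep = int(np.floor(ratio * pos_idx.size))
    if n_neg_keep > neg_idx.size:
        raise ValueError(
            f"ratio {ratio} needs {n_neg_keep} negatives but only "
            f"{neg_idx.size} exist (max feasible ratio "
            f"{neg_idx.size / pos_idx.size:.2f})"
        )
    rng = np.random.default_rng(_substream(seed, "undersample"))
    chosen_neg = np.sort(rng.choice(neg_idx, size=n_neg_keep, replace=False))
    keep = np.sort(np.concatenate([pos_idx, chosen_neg]))
    return matrix.iloc[keep], y.iloc[keep]


def fit_imputer(train: pd.DataFrame) -> pd.Series:
    """Per-column training means; all-missing columns fall back to 0."""
    means = train.mean(axis=0, skipna=True)
    n_bad = int(means.isna().sum())
    if n_bad:
        logger.warning("imputer: %d all-missing column(s) fall back to 0", n_bad)
    return means.fillna(0.0)


def impute_missing(train: pd.DataFrame, apply_to: pd.DataFrame) -> pd.DataFrame:
    """Substitute training-column means into the missing cells of
    ``apply_to`` (statistics never come from the applied-to data)."""
    means = fit_imputer(train)
    return apply_to.fillna(means)


# ---------------------------------------------------------------------------
# noisy-AND combination
# ---------------------------------------------------------------------------

def noisy_and_score(probs: Sequence[float]) -> float:
    """Difference of products of SL and non-SL probabilities.

    Score = prod_i p_i - prod_i (1 - p_i), in [-1, 1].
    """
    p = np.asarray(probs, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one probability")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("probabilities must lie in [0, 1]")
    return float(np.prod(p) - np.prod(1.0 - p))


def _combine(prob_matrix: np.ndarray, combiner: str) -> np.ndarray:
    """Row-wise combination of an (n_examples, n_classifiers) array."""
    if combiner == "difference":
        return np.prod(prob_matrix, axis=1) - np.prod(1.0 - prob_matrix, axis=1)
    if combiner == "product":  # canonical noisy-AND, for sensitivity analysis
        return np.prod(prob_matrix, axis=1)
    raise ValueError(f"unknown combiner {combiner!r}")


# ---------------------------------------------------------------------------
# base classifiers
# ---------------------------------------------------------------------------

DEFAULT_CLASSIFIERS = ("svm", "neural_net", "rules", "forest", "knn", "tree")
# compact deterministic set for quick experiments and tests
FAST_CLASSIFIERS = ("logistic", "forest", "knn", "tree")


def make_classifier(name: str, seed: int = 0):
    """Instantiate a base classifier by family name.

    Families follow the usual ensemble make-up for this problem: an
    SVM, a feed-forward neural network, a rule-style learner (a shallow
    depth-capped decision tree standing in for a sequential-covering
    rule inducer), a random forest, k-nearest neighbours and an
    unconstrained decision tree.  A deterministic logistic-regression
    family is included for fast, reproducible runs.
    """
    if name == "svm":
        return make_pipeline(
            StandardScaler(), SVC(probability=True, random_state=seed)
        )
    if name == "neural_net":
        return make_pipeline(
            StandardScaler(),
            MLPClassifier(hidden_layer_sizes=(16,), max_iter=1000, random_state=seed),
        )
    if name == "rules":
        return DecisionTreeClassifier(
            max_depth=4, min_samples_leaf=5, random_state=seed
        )
    if name == "forest":
        return RandomForestClassifier(n_estimators=100, random_state=seed, n_jobs=1)
    if name == "knn":
        return KNeighborsClassifier(n_neighbors=5)
    if name == "tree":
        return DecisionTreeClassifier(random_state=seed)
    if name == "logistic":
        return make_pipeline(
            StandardScaler(), LogisticRegression(max_iter=1000)
        )
    raise ValueError(f"unknown classifier family {name!r}")


def _positive_proba(clf, X: np.ndarray) -> np.ndarray:
    prob = clf.predict_proba(X)
    classes = list(clf.classes_)
    p = prob[:, classes.index(1)]
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("classifier produced probabilities outside [0, 1]")
    return np.clip(p, PROB_EPS, 1.0 - PROB_EPS)


# ---------------------------------------------------------------------------
# ensemble training and prediction
# ---------------------------------------------------------------------------

@dataclass
class EnsembleModel:
    """Trained base classifiers plus the imputation state and feature
    order they were fitted with."""

    classifiers: list[tuple[str, object]]
    impute_means: pd.Series
    feature_names: list[str]
    combiner: str = "difference"

    def __post_init__(self) -> None:
        if len(self.classifiers) < 2:
            raise ValueError("an ensemble needs at least 2 base classifiers")
        missing = set(self.feature_names) - set(self.impute_means.index)
        if missing:
            raise ValueError(f"imputation state lacks columns: {sorted(missing)}")

    def predict_scores(self, matrix: pd.DataFrame) -> pd.Series:
        """Noisy-AND score per row of ``matrix``.

        Missing cells are filled with the model's *training* means; the
        matrix must carry exactly the model's feature columns.
        """
        extra = set(matrix.columns) - set(self.feature_names)
        absent = set(self.feature_names) - set(matrix.columns)
        if extra or absent:
            raise ValueError(
                f"feature columns mismatch: missing={sorted(absent)}, extra={sorted(extra)}"
            )
        if matrix.shape[0] == 0:
            return pd.Series(dtype=float, index=matrix.index)
        X = (
            matrix[self.feature_names]
            .fillna(self.impute_means)
            .to_numpy(dtype=float)
        )
        probs = np.column_stack([_positive_proba(c, X) for _, c in self.classifiers])
        return pd.Series(_combine(probs, self.combiner), index=matrix.index)

    # -- persistence --------------------------------------------------
    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        manifest = {
            "classifiers": [name for name, _ in self.classifiers],
            "feature_names": self.feature_names,
            "combiner": self.combiner,
        }
        (d / "manifest.json").write_text(json.dumps(manifest, indent=2))
        self.impute_means.rename("mean").to_csv(d / "imputation.tsv", sep="\t")
        for i, (name, clf) in enumerate(self.classifiers):
            joblib.dump(clf, d / f"classifier_{i}_{name}.joblib")

    @classmethod
    def load(cls, directory: str | Path) -> "EnsembleModel":
        d = Path(directory)
        manifest = json.loads((d / "manifest.json").read_text())
        means = pd.read_csv(d / "imputation.tsv", sep="\t", index_col=0)["mean"]
        classifiers = [
            (name, joblib.load(d / f"classifier_{i}_{name}.joblib"))
            for i, name in enumerate(manifest["classifiers"])
        ]
        return cls(
            classifiers=classifiers,
            impute_means=means,
            feature_names=manifest["feature_names"],
            combiner=manifest["combiner"],
        )


def train_ensemble(
    matrix: pd.DataFrame,
    labels: pd.Series,
    classifiers: Sequence[str] = DEFAULT_CLASSIFIERS,
    ratio: float = 1.0,
    seed: int = 0,
    combiner: str = "difference",
) -> EnsembleModel:
    """Under-sample, fit imputation on the sampled set, fit every base
    classifier on the identical imputed table."""
    y = labels.astype(int)
    if y.nunique() < 2:
        raise ValueError("training set must contain both classes")
    Xs, ys = undersample(matrix, y, ratio=ratio, seed=seed)
    means = fit_imputer(Xs)
    X = Xs.fillna(means).to_numpy(dtype=float)
    fitted = []
    for name in classifiers:
        clf = make_classifier(name, seed=_substream(seed, f"clf:{name}"))
        clf.fit(X, ys.to_numpy())
        fitted.append((name, clf))
    return EnsembleModel(
        classifiers=fitted,
        impute_means=means,
        feature_names=list(matrix.columns),
        combiner=combiner,
    )


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclass
class SLDependentConfig:
    """How to rebuild SL-dependent overlay features inside each fold.

    ``input_networks`` maps name -> WeightedNetwork; the SL network is
    constructed per fold from the training positives alone (weight 1
    edges) and overlaid with each input network plus itself.
    """

    input_networks: dict[str, WeightedNetwork]


@dataclass
class CVResult:
    scores: pd.Series            # one score per example, original order
    fold: np.ndarray             # test-fold index per example
    fold_sl_networks: list[WeightedNetwork] = field(default_factory=list)


def _pairs_from_index(index: pd.MultiIndex) -> list[GenePair]:
    return [GenePair(a, b) for a, b in index]


def cross_validate(
    matrix: pd.DataFrame,
    labels: pd.Series,
    n_folds: int = 10,
    classifiers: Sequence[str] = DEFAULT_CLASSIFIERS,
    ratio: float = 1.0,
    seed: int = 0,
    combiner: str = "difference",
    sl_dependent: Optional[SLDependentConfig] = None,
) -> CVResult:
    """Stratified n-fold cross-validation with training-only under-sampling.

    Every example is scored exactly once by a model whose training folds
    exclude it; test folds keep the original class skew.  With
    ``sl_dependent`` given, the SL-dependent overlay columns are
    recomputed inside each fold from the training positives only and
    appended to the feature table for that fold.
    """
    y = labels.astype(int)
    n_pos = int((y == 1).sum())
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if n_pos < n_folds:
        raise ValueError(f"{n_pos} positives cannot stratify {n_folds} folds")
    skf = StratifiedKFold(
        n_splits=n_folds, shuffle=True, random_state=_substream(seed, "folds")
    )
    scores = np.full(len(y), np.nan)
    fold_of = np.full(len(y), -1, dtype=int)
    fold_nets: list[WeightedNetwork] = []
    pairs = _pairs_from_index(matrix.index) if sl_dependent is not None else None

    for k, (train_idx, test_idx) in enumerate(skf.split(np.zeros(len(y)), y.to_numpy())):
        X_train, y_train = matrix.iloc[train_idx], y.iloc[train_idx]
        X_test = matrix.iloc[test_idx]
        if sl_dependent is not None:
            train_pos_pairs = [pairs[i] for i in train_idx if y.iloc[i] == 1]
            sl_net = network_from_pairs(train_pos_pairs, name=SL_NETWORK_NAME)
            fold_nets.append(sl_net)
            catalog = build_sl_dependent_catalog(sorted(sl_dependent.input_networks))
            sources: dict[str, object] = dict(sl_dependent.input_networks)
            sources[SL_NETWORK_NAME] = sl_net
            extra_train = assemble_feature_matrix(
                catalog, sources, [pairs[i] for i in train_idx]
            ).set_axis(X_train.index, axis=0)
            extra_test = assemble_feature_matrix(
                catalog, sources, [pairs[i] for i in test_idx]
            ).set_axis(X_test.index, axis=0)
            X_train = pd.concat([X_train, extra_train], axis=1)
            X_test = pd.concat([X_test, extra_test], axis=1)
        model = train_ensemble(
            X_train,
            y_train,
            classifiers=classifiers,
            ratio=ratio,
            seed=_substream(seed, f"fold:{k}"),
            combiner=combiner,
        )
        scores[test_idx] = model.predict_scores(X_test).to_numpy()
        fold_of[test_idx] = k

    return CVResult(
        scores=pd.Series(scores, index=matrix.index),
        fold=fold_of,
        fold_sl_networks=fold_nets,
    )


# ---------------------------------------------------------------------------
# least-connected train/test split
# ---------------------------------------------------------------------------

@dataclass
class Split:
    train_index: np.ndarray
    test_index: np.ndarray


def least_connected_split(
    matrix: pd.DataFrame,
    labels: pd.Series,
    sl_net: WeightedNetwork,
    k: int,
) -> Split:
    """Hold out the k least-connected positive pairs for testing.

    Pair connectivity is min(degree) in the known-SL network; ties break
    by canonical pair order.  The negative test set is the negatives
    whose both genes occur among the test-positive genes; training drops
    any positive sharing a gene with a test positive.
    """
    y = labels.astype(int).to_numpy()
    pairs = _pairs_from_index(matrix.index)
    pos_idx = np.flatnonzero(y == 1)
    if k > pos_idx.size:
        raise ValueError(f"k={k} exceeds {pos_idx.size} positives")
    ranked = sorted(
        pos_idx,
        key=lambda i: (
            min(sl_net.degree(pairs[i].a), sl_net.degree(pairs[i].b)),
            (pairs[i].a, pairs[i].b),
        ),
    )
    test_pos = ranked[:k]
    test_genes = {g for i in test_pos for g in pairs[i]}
    test_neg = [
        i
        for i in np.flatnonzero(y == 0)
        if pairs[i].a in test_genes and pairs[i].b in test_genes
    ]
    test = set(test_pos) | set(test_neg)
    train = [
        i
        for i in range(len(y))
        if i not in test
        and not (y[i] == 1 and (pairs[i].a in test_genes or pairs[i].b in test_genes))
    ]
    return Split(
        train_index=np.asarray(train, dtype=int),
        test_index=np.asarray(sorted(test), dtype=int),
    )
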