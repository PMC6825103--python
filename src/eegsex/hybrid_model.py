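"""Random-forest leaf embedding + logistic regression hybrid classifier.

The hybrid fits a random forest on the training features, re-expresses
every sample as the one-hot indicator of the leaf it reaches in each
tree (a sparse, high-dimensional partition encoding), concatenates those
indicators with the original feature vector, and fits an L1-regularised
logistic regression on the combined design.  The per-tree linear
coefficients on each tree's leaf block play the role of per-tree
weights; no separate scalar tree weighting is applied.

Leaf columns are laid out tree-major with a stable depth-first
(left-child-first) leaf enumeration inside each tree, so the encoding is
reproducible across runs given the forest seed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import joblib
import numpy as np
from scipy import sparse
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from .exceptions import ValidationError

log = logging.getLogger(__name__)

_PERSIST_VERSION = 1


@dataclass
class ForestParams:
    """Random-forest hyperparameters (nt trees of depth <= md)."""

    nt: int = 200
    md: int = 5
    split_criterion: str = "gini"
    min_samples_split: int = 2
    min_samples_leaf: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nt < 1:
            raise ValidationError("number of trees nt must be >= 1")
        if self.md < 1:
            raise ValidationError("max depth md must be >= 1")
        if self.min_samples_split < 2 or self.min_samples_leaf < 1:
            raise ValidationError("invalid min_samples_split / min_samples_leaf")

    def to_sklearn(self) -> RandomForestClassifier:
        return RandomForestClassifier(
            n_estimators=self.nt,
            max_depth=self.md,
            criterion=self.split_criterion,
            min_samples_split=self.min_samples_split,
            min_samples_leaf=self.min_samples_leaf,
            random_state=self.seed,
            n_jobs=1,
        )


@dataclass
class LinearParams:
    """Logistic-regression hyperparameters (penalty, inverse strength C)."""

    penalty: str = "l1"
    C: float = 1.0
    tol: float = 1e-4
    max_iter: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.penalty not in ("l1", "l2"):
            raise ValidationError("penalty must be 'l1' or 'l2'")
        if not self.C > 0:
            raise ValidationError("C must be positive")

    def to_sklearn(self) -> LogisticRegression:
        # liblinear: supports both penalties, deterministic, good on sparse
        # designs; l1_ratio 1 -> lasso penalty, 0 -> ridge penalty
        return LogisticRegression(
            l1_ratio=1.0 if self.penalty == "l1" else 0.0,
            C=self.C,
            tol=self.tol,
            max_iter=self.max_iter,
            solver="liblinear",
            random_state=self.seed,
        )


def _validate_xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2:
        raise ValidationError("X must be 2-D")
    if len(y) != X.shape[0]:
        raise ValidationError("X row count != y length")
    if len(np.unique(y)) != 2:
        raise ValidationError("y must contain exactly two classes")
    if not np.all(np.isfinite(X)):
        raise ValidationError("X contains non-finite values")
    return X, y


def fit_forest(X: np.ndarray, y: np.ndarray, params: ForestParams) -> RandomForestClassifier:
    """Fit the tree ensemble (bootstrap resamples, random feature subsets)."""
    X, y = _validate_xy(X, y)
    forest = params.to_sklearn()
    forest.fit(X, y)
    return forest


def build_leaf_map(forest: RandomForestClassifier) -> list[np.ndarray]:
    """Per-tree lookup from node id to global leaf-column index.

    sklearn stores tree nodes in depth-first pre-order with the left
    child first, so ascending leaf node ids give the stable depth-first
    left-first enumeration; columns are assigned tree-major.
    """
    maps: list[np.ndarray] = []
    offset = 0
    for est in forest.estimators_:
        tree = est.tree_
        leaf_ids = np.flatnonzero(tree.children_left == -1)
        lut = np.full(tree.node_count, -1, dtype=np.int64)
        lut[leaf_ids] = offset + np.arange(leaf_ids.size)
        offset += leaf_ids.size
        maps.append(lut)
    return maps


def n_encoded_columns(leaf_map: list[np.ndarray]) -> int:
    return int(sum((lut >= 0).sum() for lut in leaf_map))


def leaf_encode(
    forest: RandomForestClassifier,
    X: np.ndarray,
    leaf_map: list[np.ndarray] | None = None,
) -> sparse.csr_matrix:
    """One-hot leaf-membership encoding, shape (n_samples, total leaf count).

    Row i carries a single 1 per tree, in the column of the leaf sample i
    reaches; every row therefore sums to the number of trees.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != forest.n_features_in_:
        raise ValidationError(
            f"X has {X.shape[1] if X.ndim == 2 else '?'} features, "
            f"forest expects {forest.n_features_in_}"
        )
    if leaf_map is None:
        leaf_map = build_leaf_map(forest)
    leaves = forest.apply(X)  # (n_samples, nt) node ids
    cols = np.column_stack(
        [leaf_map[t][leaves[:, t]] for t in range(leaves.shape[1])]
    ).ravel()
    n, nt = leaves.shape
    rows = np.repeat(np.arange(n), nt)
    data = np.ones(n * nt, dtype=np.float64)
    return sparse.csr_matrix(
        (data, (rows, cols)), shape=(n, n_encoded_columns(leaf_map))
    )


@dataclass
class HybridModel:
    """Fitted forest + leaf map + logistic model over [leaf one-hot || X]."""

    forest: RandomForestClassifier
    leaf_map: list[np.ndarray]
    linear: LogisticRegression
    n_original: int
    n_encoded: int
    forest_params: ForestParams = field(default_factory=ForestParams)
    linear_params: LinearParams = field(default_factory=LinearParams)


def _design(model_forest, leaf_map, X: np.ndarray) -> sparse.csr_matrix:
    return sparse.hstack(
        [leaf_encode(model_forest, X, leaf_map), sparse.csr_matrix(X)], format="csr"
    )


def fit_hybrid(
    X: np.ndarray,
    y: np.ndarray,
    fp: ForestParams | None = None,
    lp: LinearParams | None = None,
) -> HybridModel:
    """Fit the full hybrid: forest, leaf encoding, then logistic regression."""
    fp = fp or ForestParams()
    lp = lp or LinearParams()
    X, y = _validate_xy(X, y)
    forest = fit_forest(X, y, fp)
    leaf_map = build_leaf_map(forest)
    design = _design(forest, leaf_map, X)
    linear = lp.to_sklearn()
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        linear.fit(design, y)
    if any(issubclass(w.category, ConvergenceWarning) for w in caught):
        log.warning("logistic solver hit the %d-iteration cap", lp.max_iter)
    return HybridModel(
        forest=forest,
        leaf_map=leaf_map,
        linear=linear,
        n_original=X.shape[1],
        n_encoded=n_encoded_columns(leaf_map),
        forest_params=fp,
        linear_params=lp,
    )


def predict_scores(model: HybridModel, X: np.ndarray) -> np.ndarray:
    """Probability of the positive (larger) class for each sample."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_original:
        raise ValidationError(
            f"X must have {model.n_original} features, got "
            f"{X.shape[1] if X.ndim == 2 else '?'}"
        )
    design = _design(model.forest, model.leaf_map, X)
    return model.linear.predict_proba(design)[:, -1]


def predict_labels(
    model: HybridModel, X: np.ndarray, threshold: float = 0.5
) -> np.ndarray:
    """Positive class iff score >= threshold (boundary inclusive)."""
    if not 0 < threshold < 1:
        raise ValidationError("threshold must lie strictly inside (0, 1)")
    scores = predict_scores(model, X)
    pos, neg = model.linear.classes_[-1], model.linear.classes_[0]
    return np.where(scores >= threshold, pos, neg)


def save_model(model: HybridModel, path) -> None:
    """Persist the fitted hybrid to a single version-stamped archive."""
    joblib.dump({"version": _PERSIST_VERSION, "model": model}, path)


def load_model(path) -> HybridModel:
    payload = joblib.load(path)
    if payload.get("version") != _PERSIST_VERSION:
        raise ValidationError(
            f"unsupported model archive version {payload.get('version')!r}"
        )
    return payload["model"]
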