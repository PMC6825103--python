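"""Nested cross-validation, metrics, group comparison, robustness sweeps.

The evaluation protocol is a nested 10-fold cross-validation: an outer
stratified 10-fold loop estimates generalisation; inside each outer
training set an inner 10-fold grid search picks hyperparameters, so the
outer test fold never influences tuning.  Reported metrics are accuracy
and the area under the ROC curve, averaged over outer folds.

Fold splitting is at the epoch level by default (epochs of one subject
may land in both train and test — the protocol's known leakage caveat);
pass ``groups=subject_ids`` for the subject-grouped alternative.

The positive class throughout is ``"female"``; scores are P(female).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import (
    StratifiedGroupKFold,
    StratifiedKFold,
    StratifiedShuffleSplit,
)

from .entropy_features import FeatureMatrix
from .exceptions import ValidationError
from .hybrid_model import (
    ForestParams,
    LinearParams,
    fit_hybrid,
    predict_scores,
)

log = logging.getLogger(__name__)

POSITIVE_LABEL = "female"
CLASSIFIER_KINDS = ("LR", "RF", "hybrid")

#: The 27 male:female subject-count cases of the sex-ratio robustness sweep.
SEX_RATIO_CASES: list[tuple[int, int]] = (
    [(13, f) for f in range(1, 16)] + [(m, 15) for m in range(12, 0, -1)]
)

#: Default hyperparameter sweep values (single-run defaults stay nt=200,
#: md=5, penalty=l1, C=1.0).
DEFAULT_NT_GRID = [1, 10, 20, 50, 100, 200, 500, 1000, 2000]
DEFAULT_MD_GRID = list(range(1, 11)) + [20]
DEFAULT_C_GRID = [0.001, 0.01, 0.1, 1.0, 10.0]


def encode_labels(labels: np.ndarray) -> np.ndarray:
    """Map sex labels to {0, 1} with female as the positive class."""
    labels = np.asarray(labels)
    return (labels == POSITIVE_LABEL).astype(int)


# ---------------------------------------------------------------------------
# Classifier wrappers

class _SkClassifier:
    """fit/scores facade over a plain sklearn estimator."""

    def __init__(self, estimator):
        self.estimator = estimator

    def fit(self, X, y):
        self.estimator.fit(X, y)
        return self

    def scores(self, X):
        return self.estimator.predict_proba(X)[:, -1]


class _HybridClassifier:
    def __init__(self, fp: ForestParams, lp: LinearParams):
        self.fp, self.lp = fp, lp
        self.model = None

    def fit(self, X, y):
        self.model = fit_hybrid(X, y, self.fp, self.lp)
        return self

    def scores(self, X):
        return predict_scores(self.model, X)


def make_classifier(kind: str, params: dict | None = None, seed: int = 0):
    """Build an unfitted classifier of the given kind.

    ``params`` may carry any of nt, md, penalty, C; unspecified values
    fall back to the defaults (nt=200, md=5, penalty=l1, C=1.0).
    """
    p = dict(params or {})
    fp = ForestParams(nt=int(p.get("nt", 200)), md=int(p.get("md", 5)), seed=seed)
    lp = LinearParams(
        penalty=str(p.get("penalty", "l1")), C=float(p.get("C", 1.0)), seed=seed
    )
    if kind == "LR":
        return _SkClassifier(lp.to_sklearn())
    if kind == "RF":
        return _SkClassifier(fp.to_sklearn())
    if kind == "hybrid":
        return _HybridClassifier(fp, lp)
    raise ValidationError(f"unknown classifier kind {kind!r}")


# ---------------------------------------------------------------------------
# Folds and metrics

def stratified_folds(
    labels: np.ndarray,
    k: int,
    seed: int = 0,
    groups: np.ndarray | None = None,
) -> np.ndarray:
    """Per-sample fold index for (group-)stratified k-fold splitting."""
    labels = np.asarray(labels)
    if k < 2:
        raise ValidationError("number of folds k must be >= 2")
    _, counts = np.unique(labels, return_counts=True)
    if groups is None and counts.min() < k:
        raise ValidationError(
            f"smallest class has {counts.min()} samples, fewer than k = {k}"
        )
    X_dummy = np.zeros((len(labels), 1))
    if groups is None:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(X_dummy, labels)
    else:
        splitter = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(X_dummy, labels, groups=np.asarray(groups))
    fold = np.full(len(labels), -1, dtype=int)
    for f, (_, test_idx) in enumerate(splits):
        fold[test_idx] = f
    return fold


@dataclass
class ROCCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def roc_curve_auc(scores: np.ndarray, labels: np.ndarray) -> ROCCurve:
    """ROC over all distinct score thresholds and trapezoidal AUC.

    Equals the normalised Mann-Whitney U statistic (probability a random
    positive outscores a random negative, ties counted half).
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if len(np.unique(y)) != 2:
        raise ValidationError("ROC requires both classes present")
    uniq = set(np.unique(y).tolist())
    pos = POSITIVE_LABEL if POSITIVE_LABEL in uniq else y.max()
    fpr, tpr, thr = _sk_roc_curve(y, scores, pos_label=pos)
    return ROCCurve(fpr=fpr, tpr=tpr, thresholds=thr,
                    auc=float(np.trapezoid(tpr, fpr)))


def accuracy_at_threshold(
    scores: np.ndarray, y: np.ndarray, threshold: float = 0.5
) -> float:
    """Fraction correct when predicting positive iff score >= threshold."""
    y = np.asarray(y)
    pred = (np.asarray(scores) >= threshold).astype(y.dtype)
    return float((pred == y).mean())


# ---------------------------------------------------------------------------
# Grid search

@dataclass
class ParamGrid:
    """Hyperparameter search space over (nt, md, penalty, C)."""

    forest_nt: list[int] = field(default_factory=lambda: [200])
    forest_md: list[int] = field(default_factory=lambda: [5])
    linear_penalty: list[str] = field(default_factory=lambda: ["l1"])
    linear_C: list[float] = field(default_factory=lambda: [1.0])

    def __post_init__(self) -> None:
        for name in ("forest_nt", "forest_md", "linear_penalty", "linear_C"):
            if not getattr(self, name):
                raise ValidationError(f"grid list {name} must be non-empty")

    def cells(self) -> list[dict]:
        return [
            {"nt": nt, "md": md, "penalty": pen, "C": C}
            for nt, md, pen, C in itertools.product(
                self.forest_nt, self.forest_md, self.linear_penalty, self.linear_C
            )
        ]


def _cell_sort_key(cell: dict, score: float):
    # ties: smaller nt, smaller md, l2 before l1, larger C
    return (-score, cell["nt"], cell["md"],
            0 if cell["penalty"] == "l2" else 1, -cell["C"])


def grid_search(
    X: np.ndarray,
    y: np.ndarray,
    grid: ParamGrid,
    kind: str = "hybrid",
    k: int = 10,
    seed: int = 0,
) -> tuple[dict, pd.DataFrame]:
    """Exhaustive grid evaluation by stratified k-fold CV accuracy.

    Every grid cell is scored with the same fold assignment; the winner
    is the cell with the highest mean accuracy, ties broken by smaller
    nt, smaller md, l2 before l1, then larger C.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    fold = stratified_folds(y, k, seed)
    rows = []
    for cell in grid.cells():
        accs = []
        for f in range(k):
            test = fold == f
            clf = make_classifier(kind, cell, seed=seed).fit(X[~test], y[~test])
            accs.append(accuracy_at_threshold(clf.scores(X[test]), y[test]))
        rows.append({**cell, "mean_accuracy": float(np.mean(accs))})
    table = pd.DataFrame(rows)
    best_row = min(rows, key=lambda r: _cell_sort_key(r, r["mean_accuracy"]))
    best = {key: best_row[key] for key in ("nt", "md", "penalty", "C")}
    return best, table


# ---------------------------------------------------------------------------
# Nested cross-validation

@dataclass
class FoldResult:
    fold: int
    test_idx: np.ndarray
    inner_pool_idx: np.ndarray
    params: dict
    accuracy: float
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray


@dataclass
class CVReport:
    """Per-outer-fold metrics plus their averages for one classifier kind."""

    classifier_kind: str
    seed: int
    folds: list[FoldResult]

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean([f.accuracy for f in self.folds]))

    @property
    def mean_auc(self) -> float:
        return float(np.mean([f.auc for f in self.folds]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"fold": f.fold, "accuracy": f.accuracy, "auc": f.auc, **f.params}
                for f in self.folds
            ]
        )

    def mean_roc(self, n_points: int = 101) -> pd.DataFrame:
        """Vertically averaged ROC over a fixed false-positive-rate grid."""
        grid = np.linspace(0.0, 1.0, n_points)
        tprs = [np.interp(grid, f.fpr, f.tpr) for f in self.folds]
        return pd.DataFrame({"fpr": grid, "tpr": np.mean(tprs, axis=0)})


def nested_cv(
    X: np.ndarray,
    y: np.ndarray,
    classifier_kind: str = "hybrid",
    grid: ParamGrid | None = None,
    outer_k: int = 10,
    inner_k: int = 10,
    seed: int = 0,
    groups: np.ndarray | None = None,
    classifier_factory=None,
) -> CVReport:
    """Nested k-fold cross-validation with inner grid search.

    When ``grid`` is None (or has a single cell) the inner search is a
    no-op and the default parameters are used everywhere.  The inner
    loop only ever sees the outer training portion; each fold result
    records the index pool the inner loop drew from, so the no-leakage
    property is auditable.  ``classifier_factory(params, seed)`` may
    replace the built-in kinds (used to inject stubs in testing).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    fold = stratified_folds(y, outer_k, seed, groups=groups)
    factory = classifier_factory or (
        lambda params, s: make_classifier(classifier_kind, params, seed=s)
    )
    results = []
    for f in range(outer_k):
        test = fold == f
        train_idx = np.flatnonzero(~test)
        test_idx = np.flatnonzero(test)
        if grid is not None and len(grid.cells()) > 1:
            best, _ = grid_search(
                X[train_idx], y[train_idx], grid, kind=classifier_kind,
                k=inner_k, seed=seed + 1 + f,
            )
        else:
            best = (grid.cells()[0] if grid is not None
                    else {"nt": 200, "md": 5, "penalty": "l1", "C": 1.0})
        clf = factory(best, seed).fit(X[train_idx], y[train_idx])
        scores = clf.scores(X[test_idx])
        roc = roc_curve_auc(scores, y[test_idx])
        results.append(FoldResult(
            fold=f,
            test_idx=test_idx,
            inner_pool_idx=train_idx,
            params=best,
            accuracy=accuracy_at_threshold(scores, y[test_idx]),
            auc=roc.auc,
            fpr=roc.fpr,
            tpr=roc.tpr,
        ))
    report = CVReport(classifier_kind=classifier_kind, seed=seed, folds=results)
    log.info(
        "nested CV (%s, %d folds): mean accuracy %.4f, mean AUC %.4f",
        classifier_kind, outer_k, report.mean_accuracy, report.mean_auc,
    )
    return report


# ---------------------------------------------------------------------------
# Group comparison

def compare_groups(fm: FeatureMatrix, alpha: float = 0.01) -> pd.DataFrame:
    """Welch two-sample t test of every feature between female and male epochs.

    Returns per-feature group means +/- SD, the t statistic (female minus
    male orientation), the two-sided p value and a significance flag at
    ``alpha``.  Undefined (flagged) cells are omitted pairwise.
    """
    vals = fm.values.copy()
    vals[fm.nan_mask] = np.nan
    female = vals[fm.labels == "female"]
    male = vals[fm.labels == "male"]
    if len(female) < 2 or len(male) < 2:
        raise ValidationError("each sex needs at least 2 epochs for a group test")
    rows = []
    for j, name in enumerate(fm.feature_names):
        fv = female[:, j][np.isfinite(female[:, j])]
        mv = male[:, j][np.isfinite(male[:, j])]
        if len(fv) < 2 or len(mv) < 2:
            raise ValidationError(f"feature {name}: a group has < 2 defined epochs")
        if fv.std(ddof=1) == 0 and mv.std(ddof=1) == 0:
            # degenerate: no within-group variation
            t, p = (0.0, 1.0) if fv.mean() == mv.mean() else (np.inf, 0.0)
        else:
            t, p = sstats.ttest_ind(fv, mv, equal_var=False)
        rows.append({
            "feature": name,
            "female_mean": fv.mean(), "female_sd": fv.std(ddof=1),
            "male_mean": mv.mean(), "male_sd": mv.std(ddof=1),
            "t": float(t), "p": float(p),
            "significant": bool(p < alpha),
        })
    return pd.DataFrame(rows).set_index("feature")


# ---------------------------------------------------------------------------
# Robustness sweeps

def _clean_xy(fm: FeatureMatrix) -> tuple[np.ndarray, np.ndarray, FeatureMatrix]:
    clean = fm.drop_undefined()
    return clean.values, encode_labels(clean.labels), clean


def _holdout_eval(
    X: np.ndarray,
    y: np.ndarray,
    kinds: tuple[str, ...],
    test_fraction: float,
    repeats: int,
    seed: int,
) -> dict[str, tuple[float, float]]:
    """Mean (accuracy, AUC) per kind over stratified random splits."""
    accs = {k: [] for k in kinds}
    aucs = {k: [] for k in kinds}
    sss = StratifiedShuffleSplit(
        n_splits=repeats, test_size=test_fraction, random_state=seed
    )
    for rep, (tr, te) in enumerate(sss.split(X, y)):
        for kind in kinds:
            clf = make_classifier(kind, seed=seed + rep).fit(X[tr], y[tr])
            s = clf.scores(X[te])
            accs[kind].append(accuracy_at_threshold(s, y[te]))
            aucs[kind].append(roc_curve_auc(s, y[te]).auc)
    return {k: (float(np.mean(accs[k])), float(np.mean(aucs[k]))) for k in kinds}


def channel_subset_sweep(
    fm: FeatureMatrix,
    m_values: list[int] | None = None,
    kinds: tuple[str, ...] = CLASSIFIER_KINDS,
    repeats: int = 10,
    test_fraction: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Accuracy/AUC versus electrode count.

    For each m, ``repeats`` uniformly random m-channel subsets are drawn,
    the evaluation is run on each subset's feature columns and the
    results averaged (one output row per m per classifier kind).
    """
    channels = fm.channels
    m_values = list(m_values) if m_values is not None else list(range(1, len(channels) + 1))
    for m in m_values:
        if not 1 <= m <= len(channels):
            raise ValidationError(f"channel count m = {m} outside 1..{len(channels)}")
    rng = np.random.default_rng(seed)
    rows = []
    for m in m_values:
        accs = {k: [] for k in kinds}
        aucs = {k: [] for k in kinds}
        for rep in range(repeats):
            subset = list(rng.choice(channels, size=m, replace=False))
            X, y, _ = _clean_xy(fm.select_channels(subset))
            res = _holdout_eval(X, y, kinds, test_fraction, 1, seed + rep)
            for k in kinds:
                accs[k].append(res[k][0])
                aucs[k].append(res[k][1])
        for k in kinds:
            rows.append({
                "m": m, "classifier": k,
                "accuracy": float(np.mean(accs[k])),
                "auc": float(np.mean(aucs[k])),
            })
    return pd.DataFrame(rows)


def test_fraction_sweep(
    fm: FeatureMatrix,
    fractions: list[float],
    kinds: tuple[str, ...] = CLASSIFIER_KINDS,
    repeats: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Accuracy/AUC versus the held-out test proportion.

    Each fraction uses ``repeats`` stratified random splits; fractions
    leaving fewer than 2 samples of either class on either side are
    skipped with a warning.
    """
    X, y, _ = _clean_xy(fm)
    _, counts = np.unique(y, return_counts=True)
    rows = []
    for frac in fractions:
        if not 0 < frac < 1:
            raise ValidationError(f"test fraction {frac} outside (0, 1)")
        feasible = all(
            int(np.floor(c * frac)) >= 2 and c - int(np.ceil(c * frac)) >= 2
            for c in counts
        )
        if not feasible:
            log.warning("skipping infeasible test fraction %.3g", frac)
            continue
        res = _holdout_eval(X, y, kinds, frac, repeats, seed)
        for k in kinds:
            rows.append({
                "test_fraction": frac, "classifier": k,
                "accuracy": res[k][0], "auc": res[k][1],
            })
    return pd.DataFrame(rows)


def class_ratio_sweep(
    fm: FeatureMatrix,
    ratios: list[tuple[int, int]] | None = None,
    kinds: tuple[str, ...] = CLASSIFIER_KINDS,
    repeats: int = 10,
    test_fraction: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Accuracy/AUC versus the male:female subject-count ratio.

    For each (n_male, n_female) case, that many subjects of each sex are
    sampled without replacement (all their epochs kept) and the holdout
    evaluation run; results are averaged over ``repeats`` draws.  The
    default case list is the 27-ratio design {13:1 .. 13:15 .. 1:15}.
    """
    ratios = list(ratios) if ratios is not None else list(SEX_RATIO_CASES)
    subj = pd.DataFrame({"subject_id": fm.subject_ids, "label": fm.labels})
    subj = subj.drop_duplicates()
    males = subj.loc[subj.label == "male", "subject_id"].to_numpy()
    females = subj.loc[subj.label == "female", "subject_id"].to_numpy()
    rng = np.random.default_rng(seed)
    rows = []
    for n_m, n_f in ratios:
        if n_m > len(males) or n_f > len(females):
            raise ValidationError(
                f"ratio {n_m}:{n_f} needs more subjects than available "
                f"({len(males)} male, {len(females)} female)"
            )
        accs = {k: [] for k in kinds}
        aucs = {k: [] for k in kinds}
        for rep in range(repeats):
            chosen = set(rng.choice(males, n_m, replace=False)) | set(
                rng.choice(females, n_f, replace=False)
            )
            sub = fm.select_rows(np.isin(fm.subject_ids, list(chosen)))
            X, y, _ = _clean_xy(sub)
            res = _holdout_eval(X, y, kinds, test_fraction, 1, seed + rep)
            for k in kinds:
                accs[k].append(res[k][0])
                aucs[k].append(res[k][1])
        for k in kinds:
            rows.append({
                "n_male": n_m, "n_female": n_f, "ratio": f"{n_m}:{n_f}",
                "classifier": k,
                "accuracy": float(np.mean(accs[k])),
                "auc": float(np.mean(aucs[k])),
            })
    return pd.DataFrame(rows)
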