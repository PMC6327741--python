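"""Classification and evaluation: MCC threshold sweep, ROC/AUC, CV, grids.

The evaluation stack mirrors how redox-site predictors are benchmarked:
a classifier produces a per-site confidence score in [0, 1]; the ROC
curve and its AUC summarise ranking quality; the Matthews correlation
coefficient (MCC) is reported at the confidence threshold that maximises
it, found by sweeping every threshold that changes the confusion matrix.
Stratified 10-fold cross-validation pools out-of-fold scores into a
single report per dataset; a cross-dataset train/test mode and an
(n_seq, n_mod) grid search over the adjacency-matrix depth complete the
stack, together with a feature-label correlation profile compared
against random features via a two-sample Kolmogorov-Smirnov test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LinearRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .features import FeatureTable, assemble, normalize_columns_train_test
from .ram import TargetSite

__all__ = [
    "PredictionScores",
    "EvalReport",
    "mcc",
    "optimal_mcc_threshold",
    "roc_auc",
    "evaluate_scores",
    "Classifier",
    "make_classifier",
    "crossval_10fold",
    "train_test",
    "sweep_n",
    "SweepResult",
    "feature_label_correlation_profile",
    "CorrelationProfile",
]

ClassifierName = Literal["rf", "svm", "knn", "ols"]


@dataclass(frozen=True)
class PredictionScores:
    """Per-site confidence scores in [0, 1] paired with true labels."""

    scores: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        if self.scores.shape != self.labels.shape:
            raise ValueError("scores and labels differ in length")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary")


@dataclass(frozen=True)
class EvalReport:
    """Headline metrics at the MCC-optimal confidence threshold."""

    mcc: float
    auc: float
    acc: float
    sn: float
    sp: float
    optimal_threshold: float
    confusion: tuple[int, int, int, int]  # (TP, FP, TN, FN)
    fold_auc_mean: float | None = None
    fold_auc_sd: float | None = None

    def to_dict(self) -> dict:
        d = {
            "MCC": self.mcc,
            "AUC": self.auc,
            "ACC": self.acc,
            "SN": self.sn,
            "SP": self.sp,
            "optimal_threshold": self.optimal_threshold,
            "confusion": {
                k: v for k, v in zip(("TP", "FP", "TN", "FN"), self.confusion)
            },
        }
        if self.fold_auc_mean is not None:
            d["fold_AUC_mean"] = self.fold_auc_mean
            d["fold_AUC_sd"] = self.fold_auc_sd
        return d


def mcc(tp: int, fp: int, tn: int, fn: int) -> float:
    """Matthews correlation coefficient from confusion counts.

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)); any zero
    factor in the denominator yields 0 by the standard convention.
    """
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def _confusion(scores: np.ndarray, labels: np.ndarray, threshold: float):
    pred = scores > threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    tn = int(np.sum(~pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    return tp, fp, tn, fn


def optimal_mcc_threshold(scores: PredictionScores) -> tuple[float, float]:
    """Threshold maximising MCC, found by exhaustive sweep.

    Candidate thresholds are the midpoints between consecutive distinct
    sorted scores plus sentinels below the minimum and above the maximum
    (all-positive / all-negative calls); between candidates the
    confusion matrix — hence MCC — cannot change.  A site is called
    positive when its score strictly exceeds the threshold.  Ties in MCC
    resolve to the lowest threshold.
    """
    labels = scores.labels
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes required to optimise a threshold")
    distinct = np.unique(scores.scores)
    candidates = [float(distinct[0]) - 1.0]
    candidates.extend(((distinct[:-1] + distinct[1:]) / 2).tolist())
    candidates.append(float(distinct[-1]) + 1.0)
    best_t, best_m = candidates[0], -2.0
    for t in candidates:
        m = mcc(*_confusion(scores.scores, labels, t))
        if m > best_m + 1e-15:
            best_t, best_m = t, m
    return best_t, best_m


def roc_auc(scores: PredictionScores) -> float:
    """Tie-aware area under the ROC curve of confidences vs labels."""
    if len(np.unique(scores.labels)) < 2:
        raise ValueError("both classes required for AUC")
    return float(roc_auc_score(scores.labels, scores.scores))


def evaluate_scores(
    scores: PredictionScores,
    fold_aucs: Sequence[float] | None = None,
) -> EvalReport:
    """Full report: AUC plus MCC/ACC/SN/SP at the MCC-optimal threshold."""
    threshold, best_mcc = optimal_mcc_threshold(scores)
    tp, fp, tn, fn = _confusion(scores.scores, scores.labels, threshold)
    total = tp + fp + tn + fn
    return EvalReport(
        mcc=best_mcc,
        auc=roc_auc(scores),
        acc=(tp + tn) / total,
        sn=tp / (tp + fn) if tp + fn else 0.0,
        sp=tn / (tn + fp) if tn + fp else 0.0,
        optimal_threshold=threshold,
        confusion=(tp, fp, tn, fn),
        fold_auc_mean=float(np.mean(fold_aucs)) if fold_aucs else None,
        fold_auc_sd=float(np.std(fold_aucs)) if fold_aucs else None,
    )


# ---------------------------------------------------------------------------
# Classifiers

class Classifier:
    """Uniform wrapper: fit on a matrix, emit confidences in [0, 1]."""

    #: margin classifiers need per-column train/test normalization
    needs_column_norm = False

    def __init__(self, name: str, estimator, proba: bool):
        self.name = name
        self._est = estimator
        self._proba = proba

    def fit(self, X: np.ndarray, y: np.ndarray) -> "Classifier":
        self._est.fit(X, y)
        return self

    def confidence(self, X: np.ndarray) -> np.ndarray:
        if self._proba:
            return self._est.predict_proba(X)[:, 1]
        raw = self._est.predict(X)
        return np.clip(raw, 0.0, 1.0)


def make_classifier(
    name: ClassifierName = "rf", seed: int = 0, **params
) -> Classifier:
    """Build one of the supported classifier backends.

    ``rf`` — random forest, 500 trees, unlimited depth (the default and
    the strongest performer for this task; tree votes average into the
    confidence score).  ``svm`` — RBF support-vector machine with Platt
    scaling; requires per-column normalization.  ``knn`` — k-nearest
    neighbours vote fraction.  ``ols`` — linear least-squares baseline,
    predictions clipped to [0, 1].
    """
    if name == "rf":
        est = RandomForestClassifier(
            n_estimators=params.pop("n_estimators", 500),
            max_depth=params.pop("max_depth", None),
            random_state=seed,
            n_jobs=params.pop("n_jobs", 1),
            **params,
        )
        return Classifier("rf", est, proba=True)
    if name == "svm":
        est = SVC(probability=True, random_state=seed, **params)
        clf = Classifier("svm", est, proba=True)
        clf.needs_column_norm = True
        return clf
    if name == "knn":
        est = KNeighborsClassifier(n_neighbors=params.pop("n_neighbors", 5), **params)
        return Classifier("knn", est, proba=True)
    if name == "ols":
        return Classifier("ols", LinearRegression(**params), proba=False)
    raise ValueError(f"unknown classifier {name!r}")


def feature_importances(
    clf: Classifier, table: FeatureTable
) -> dict[str, float]:
    """Impurity importances of a fitted forest, aggregated per block."""
    imp = getattr(clf._est, "feature_importances_", None)
    if imp is None:
        raise ValueError("classifier does not expose feature importances")
    return {
        name: float(imp[sl].sum()) for name, sl in table.blocks.items()
    }


# ---------------------------------------------------------------------------
# Cross-validation and train/test

def crossval_10fold(
    table: FeatureTable,
    classifier: ClassifierName = "rf",
    seed: int = 0,
    n_folds: int = 10,
    **clf_params,
) -> tuple[PredictionScores, EvalReport]:
    """Stratified k-fold CV with pooled out-of-fold confidence scores.

    Folds come from a seeded stratified shuffle; each site is scored
    exactly once, by the model that never saw it.  The report is
    computed over the pooled scores (one number per dataset), with
    per-fold AUC mean/sd attached for transparency.
    """
    y = table.labels()
    counts = np.bincount(y, minlength=2)
    if counts.min() < n_folds:
        raise ValueError(
            f"need >= {n_folds} sites per class for {n_folds}-fold CV, "
            f"have {counts.tolist()}"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    pooled = np.empty(len(y), dtype=float)
    fold_aucs: list[float] = []
    for train_idx, test_idx in skf.split(table.matrix, y):
        X_train, X_test = table.matrix[train_idx], table.matrix[test_idx]
        clf = make_classifier(classifier, seed=seed, **clf_params)
        if clf.needs_column_norm:
            mean = X_train.mean(axis=0)
            sd = X_train.std(axis=0)
            safe = np.where(sd > 0, sd, 1.0)
            X_train = np.where(sd > 0, (X_train - mean) / safe, 0.0)
            X_test = np.where(sd > 0, (X_test - mean) / safe, 0.0)
        clf.fit(X_train, y[train_idx])
        fold_scores = clf.confidence(X_test)
        pooled[test_idx] = fold_scores
        if len(np.unique(y[test_idx])) == 2:
            fold_aucs.append(
                float(roc_auc_score(y[test_idx], fold_scores))
            )
    scores = PredictionScores(scores=pooled, labels=y)
    return scores, evaluate_scores(scores, fold_aucs)


def train_test(
    train_table: FeatureTable,
    test_table: FeatureTable,
    classifier: ClassifierName = "rf",
    seed: int = 0,
    **clf_params,
) -> tuple[PredictionScores, EvalReport]:
    """Fit on one dataset, score another (cross-dataset evaluation)."""
    if train_table.column_names != test_table.column_names:
        raise ValueError("train and test tables have different columns")
    clf = make_classifier(classifier, seed=seed, **clf_params)
    tr, te = train_table, test_table
    if clf.needs_column_norm:
        tr, te = normalize_columns_train_test(train_table, test_table)
    clf.fit(tr.matrix, tr.labels())
    scores = PredictionScores(scores=clf.confidence(te.matrix), labels=te.labels())
    return scores, evaluate_scores(scores)


# ---------------------------------------------------------------------------
# n grid search

@dataclass(frozen=True)
class SweepResult:
    """CV AUC over an (n_seq, n_mod) grid, with the argmax pair."""

    n_seq_values: tuple[int, ...]
    n_mod_values: tuple[int, ...]
    auc_grid: np.ndarray  # shape (len(n_seq_values), len(n_mod_values))
    best: tuple[int, int]

    def to_dict(self) -> dict:
        return {
            "n_seq_values": list(self.n_seq_values),
            "n_mod_values": list(self.n_mod_values),
            "auc_grid": self.auc_grid.tolist(),
            "best_n_seq": self.best[0],
            "best_n_mod": self.best[1],
        }


def sweep_n(
    sites: Sequence[TargetSite],
    n_seq_values: Sequence[int],
    n_mod_values: Sequence[int],
    classifier: ClassifierName = "rf",
    seed: int = 0,
    n_folds: int = 10,
    **assemble_kwargs,
) -> SweepResult:
    """Grid-search the adjacency-matrix depth n by cross-validated AUC.

    The feature table is reassembled for every (n_seq, n_mod) pair —
    changing n changes the RAM blocks themselves — and scored with
    :func:`crossval_10fold` under a fixed seed.  When no structures are
    supplied the RAMmod block is absent and the n_mod axis is inert.
    """
    if not n_seq_values or not n_mod_values:
        raise ValueError("n ranges must be non-empty")
    grid = np.empty((len(n_seq_values), len(n_mod_values)), dtype=float)
    for i, ns in enumerate(n_seq_values):
        for j, nm in enumerate(n_mod_values):
            table = assemble(sites, n_seq=ns, n_mod=nm, **assemble_kwargs)
            _, report = crossval_10fold(
                table, classifier=classifier, seed=seed, n_folds=n_folds
            )
            grid[i, j] = report.auc
    best_flat = int(np.argmax(grid))
    bi, bj = divmod(best_flat, grid.shape[1])
    return SweepResult(
        n_seq_values=tuple(n_seq_values),
        n_mod_values=tuple(n_mod_values),
        auc_grid=grid,
        best=(n_seq_values[bi], n_mod_values[bj]),
    )


# ---------------------------------------------------------------------------
# Feature-label correlation profile

@dataclass(frozen=True)
class CorrelationProfile:
    """Per-feature label correlations vs a matched random baseline.

    ``ks_statistic``/``ks_pvalue`` come from the two-sample
    Kolmogorov-Smirnov test between the observed correlation sample and
    the correlations of seeded random feature columns; ``density``
    holds kernel-density summaries for plotting.
    """

    correlations: np.ndarray
    random_correlations: np.ndarray
    ks_statistic: float
    ks_pvalue: float
    density: dict[str, np.ndarray] = field(default_factory=dict)


def _pearson_vs_label(matrix: np.ndarray, y: np.ndarray) -> np.ndarray:
    yc = y - y.mean()
    xc = matrix - matrix.mean(axis=0)
    num = xc.T @ yc
    denom = np.sqrt((xc**2).sum(axis=0) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
    return r


def feature_label_correlation_profile(
    table: FeatureTable, seed: int = 0, grid_points: int = 256
) -> CorrelationProfile:
    """Pearson correlation of every feature with the label, vs random.

    A matched matrix of seeded standard-normal columns provides the
    null sample; if the real features carry signal the two correlation
    distributions separate, which the KS test quantifies.  Constant
    features get correlation 0.
    """
    y = table.labels().astype(float)
    corr = _pearson_vs_label(table.matrix, y)
    rng = np.random.default_rng(seed)
    random_matrix = rng.standard_normal(table.matrix.shape)
    random_corr = _pearson_vs_label(random_matrix, y)
    ks = stats.ks_2samp(corr, random_corr)
    grid = np.linspace(
        min(corr.min(), random_corr.min()) - 0.05,
        max(corr.max(), random_corr.max()) + 0.05,
        grid_points,
    )
    density: dict[str, np.ndarray] = {"grid": grid}
    for key, sample in (("features", corr), ("random", random_corr)):
        if np.std(sample) > 0:
            density[key] = stats.gaussian_kde(sample)(grid)
        else:
            density[key] = np.zeros_like(grid)
    return CorrelationProfile(
        correlations=corr,
        random_correlations=random_corr,
        ks_statistic=float(ks.statistic),
        ks_pvalue=float(ks.pvalue),
        density=density,
    )
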