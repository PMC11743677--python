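"""Leakage-safe subject-level cross-validated classification.

The discriminant protocol: subjects (not epochs) are partitioned into k
stratified folds; within each fold the training rows alone determine

1. univariate feature selection — a feature is retained when its Welch
   two-sample t-test or Wilcoxon rank-sum p-value (either-test rule by
   default) falls below ``alpha``;
2. median imputation of missing values, z-standardization, and PCA
   keeping the smallest number of components reaching 95% cumulative
   explained variance;

and the fitted transform is applied unchanged to the held-out rows.
Eight standard classifiers (SVM, decision tree, naive Bayes, LDA,
AdaBoost, KNN, random forest, logistic regression) run with library
defaults.  Performance is summarised per fold and as mean +/- SD across
folds: accuracy, sensitivity, specificity, positive predictive value,
F1 (from the confusion counts, PMCI positive) and the rank-based AUC
(Mann-Whitney form with average ranks for ties).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .features import FeatureMatrix

__all__ = [
    "CLASSIFIER_NAMES",
    "FoldPlan",
    "TransformModel",
    "MetricsReport",
    "CVResult",
    "subject_kfold",
    "select_features",
    "fit_transform",
    "apply_transform",
    "make_classifier",
    "train_and_predict",
    "confusion_metrics",
    "auc_rank",
    "run_cv",
]

CLASSIFIER_NAMES = ("SVM", "DT", "NB", "LDA", "ADA", "KNN", "RF", "LogReg")

METRIC_COLUMNS = ("ACC", "AUC", "SEN", "SPE", "PPV", "F1")


# ---------------------------------------------------------------------------
# fold construction


@dataclass(frozen=True)
class FoldPlan:
    """A stratified partition of subject IDs into k disjoint folds."""

    folds: Tuple[Tuple[Tuple[str, ...], Tuple[str, ...]], ...]  # (train, test)
    k: int
    seed: int

    def test_subjects(self) -> List[Tuple[str, ...]]:
        return [test for _, test in self.folds]


def subject_kfold(matrix: FeatureMatrix, k: int = 10, seed: int = 0) -> FoldPlan:
    """Stratified k-fold partition of the subject set.

    Folds partition subjects (never rows), so no subject's epochs can
    appear on both sides of a split.  Deterministic given ``seed``.
    """
    subject_label = (
        pd.Series(matrix.labels.to_numpy(), index=matrix.subject_ids)
        .groupby(level=0).first()
    )
    subjects = np.array(sorted(subject_label.index))
    labels = subject_label.loc[subjects].to_numpy()
    for cls, count in zip(*np.unique(labels, return_counts=True)):
        if count < k:
            raise ValueError(
                f"class {cls!r} has {count} subjects; needs at least k={k}"
            )
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = tuple(
        (tuple(subjects[tr]), tuple(subjects[te]))
        for tr, te in splitter.split(subjects, labels)
    )
    return FoldPlan(folds=folds, k=k, seed=seed)


# ---------------------------------------------------------------------------
# feature selection and transform


def select_features(
    values: pd.DataFrame,
    y: np.ndarray,
    alpha: float = 0.05,
    rule: str = "either",
) -> pd.Series:
    """Univariate two-group screening on training rows only.

    For each feature, a Welch two-sample t-test and a Wilcoxon rank-sum
    test compare the two groups; under the default ``either`` rule a
    feature is retained when ``min(p_t, p_w) < alpha`` (the ``both``
    rule requires both).  Constant and all-missing features are dropped.
    Returns a boolean Series indexed by feature name.
    """
    if rule not in ("either", "both"):
        raise ValueError("rule must be 'either' or 'both'")
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training rows must contain both classes")
    a = values[y == 1].to_numpy(dtype=float)
    b = values[y == 0].to_numpy(dtype=float)
    with np.errstate(all="ignore"):
        t_res = stats.ttest_ind(a, b, axis=0, equal_var=False, nan_policy="omit")
        w_res = stats.ranksums(a, b, axis=0, nan_policy="omit")
    p_t = np.asarray(t_res.pvalue, dtype=float)
    p_w = np.asarray(w_res.pvalue, dtype=float)
    p_t = np.where(np.isfinite(p_t), p_t, 1.0)
    p_w = np.where(np.isfinite(p_w), p_w, 1.0)
    if rule == "either":
        keep = np.minimum(p_t, p_w) < alpha
    else:
        keep = np.maximum(p_t, p_w) < alpha
    # constants cannot discriminate; drop them regardless of p-values
    col = values.to_numpy(dtype=float)
    with np.errstate(all="ignore"):
        sd = np.nanstd(col, axis=0)
    keep &= np.nan_to_num(sd, nan=0.0) > 0
    return pd.Series(keep, index=values.columns)


@dataclass
class TransformModel:
    """Training-fold-fitted selection mask, scaler and PCA basis."""

    feature_names: Tuple[str, ...]
    medians: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    pca_mean: np.ndarray
    components: np.ndarray  # (k95, n_selected)
    explained_variance_ratio: np.ndarray
    k95: int = field(init=False)

    def __post_init__(self) -> None:
        self.k95 = self.components.shape[0]


def _standardize(values: pd.DataFrame, model: TransformModel) -> np.ndarray:
    x = values.loc[:, list(model.feature_names)].to_numpy(dtype=float)
    nan_rows, nan_cols = np.nonzero(np.isnan(x))
    if nan_rows.size:
        x[nan_rows, nan_cols] = model.medians[nan_cols]
    return (x - model.means) / model.sds


def fit_transform(
    train_values: pd.DataFrame,
    mask: pd.Series,
    variance: float = 0.95,
) -> Tuple[TransformModel, np.ndarray]:
    """Fit imputation + z-scoring + PCA on training rows; return both the
    model and the reduced training block.

    ``k95`` is the smallest component count whose cumulative explained
    variance reaches ``variance``.  Component signs follow the
    convention that each component's largest-magnitude loading is
    positive, making the basis deterministic.
    """
    names = tuple(mask.index[mask])
    if not names:
        raise ValueError(
            "feature selection retained nothing; relax alpha or use the "
            "'either' rule"
        )
    x = train_values.loc[:, list(names)].to_numpy(dtype=float)
    medians = np.nanmedian(x, axis=0)
    nan_rows, nan_cols = np.nonzero(np.isnan(x))
    if nan_rows.size:
        x[nan_rows, nan_cols] = medians[nan_cols]
    means = x.mean(axis=0)
    sds = x.std(axis=0)
    sds[sds == 0] = 1.0
    z = (x - means) / sds

    n_comp = variance if 0 < variance < 1 else int(variance)
    pca = PCA(n_components=n_comp, svd_solver="full")
    pca.fit(z)
    components = pca.components_.copy()
    for row in components:
        if row[np.argmax(np.abs(row))] < 0:
            row *= -1.0
    model = TransformModel(
        feature_names=names,
        medians=medians,
        means=means,
        sds=sds,
        pca_mean=pca.mean_,
        components=components,
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
    )
    return model, (z - model.pca_mean) @ model.components.T


def apply_transform(model: TransformModel, values: pd.DataFrame) -> np.ndarray:
    """Project rows using only stored training-fold parameters."""
    z = _standardize(values, model)
    return (z - model.pca_mean) @ model.components.T


# ---------------------------------------------------------------------------
# classifiers


def make_classifier(name: str, seed: int = 0):
    """Instantiate one of the eight classifiers with library defaults.

    Stochastic learners receive ``seed`` as their random state so runs
    are reproducible.
    """
    factories = {
        "SVM": lambda: SVC(random_state=seed),
        "DT": lambda: DecisionTreeClassifier(random_state=seed),
        "NB": lambda: GaussianNB(),
        "LDA": lambda: LinearDiscriminantAnalysis(),
        "ADA": lambda: AdaBoostClassifier(random_state=seed),
        "KNN": lambda: KNeighborsClassifier(),
        "RF": lambda: RandomForestClassifier(random_state=seed),
        "LogReg": lambda: LogisticRegression(max_iter=1000),
    }
    if name not in factories:
        raise ValueError(
            f"unknown classifier {name!r}; valid names: {list(CLASSIFIER_NAMES)}"
        )
    return factories[name]()


def train_and_predict(
    classifier_name: str,
    train_reduced: np.ndarray,
    train_y: np.ndarray,
    test_reduced: np.ndarray,
    seed: int = 0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Fit one classifier and return (continuous scores, hard labels).

    Scores are class-1 probabilities where available, otherwise decision
    function values; higher means more PMCI-like.
    """
    if len(np.unique(train_y)) < 2:
        raise ValueError("training rows must contain both classes")
    clf = make_classifier(classifier_name, seed)
    clf.fit(train_reduced, train_y)
    if hasattr(clf, "predict_proba"):
        scores = clf.predict_proba(test_reduced)[:, 1]
    else:
        scores = clf.decision_function(test_reduced)
    return np.asarray(scores, dtype=float), clf.predict(test_reduced)


# ---------------------------------------------------------------------------
# metrics


def confusion_metrics(predicted: np.ndarray, truth: np.ndarray) -> Dict[str, float]:
    """Confusion counts and the five derived proportions (PMCI = 1).

    Ratios with zero denominators are reported as NaN (missing), never
    raised.
    """
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise ValueError("predicted and true label arrays must align")
    tp = int(np.sum((predicted == 1) & (truth == 1)))
    fn = int(np.sum((predicted == 0) & (truth == 1)))
    fp = int(np.sum((predicted == 1) & (truth == 0)))
    tn = int(np.sum((predicted == 0) & (truth == 0)))

    def ratio(num: float, den: float) -> float:
        return num / den if den > 0 else float("nan")

    return {
        "TP": tp, "FN": fn, "FP": fp, "TN": tn,
        "ACC": ratio(tp + tn, tp + fn + fp + tn),
        "SEN": ratio(tp, tp + fn),
        "SPE": ratio(tn, fp + tn),
        "PPV": ratio(tp, tp + fp),
        "F1": ratio(2 * tp, 2 * tp + fp + fn),
    }


def auc_rank(scores: np.ndarray, truth: np.ndarray) -> float:
    """Rank-sum AUC: ``(sum of positive ranks - M(M+1)/2) / (M N)``.

    Pooled scores are ranked ascending with average ranks for ties,
    which makes the statistic the Mann-Whitney concordance probability
    ``P(s+ > s-) + P(s+ = s-)/2``.  NaN when a class is absent.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth)
    m = int((truth == 1).sum())
    n = int((truth == 0).sum())
    if m == 0 or n == 0:
        return float("nan")
    ranks = stats.rankdata(scores)
    return float((ranks[truth == 1].sum() - m * (m + 1) / 2) / (m * n))


@dataclass
class MetricsReport:
    """Per-fold metrics plus mean +/- SD summary for one classifier."""

    per_fold: pd.DataFrame  # rows = folds; columns = counts + metrics

    @property
    def mean(self) -> pd.Series:
        return self.per_fold[list(METRIC_COLUMNS)].mean()

    @property
    def std(self) -> pd.Series:
        return self.per_fold[list(METRIC_COLUMNS)].std()

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({"mean": self.mean, "sd": self.std})

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        parts = ", ".join(
            f"{k}={100 * self.mean[k]:.2f}±{100 * self.std[k]:.2f}%"
            for k in METRIC_COLUMNS
        )
        return f"MetricsReport({parts})"


@dataclass
class CVResult:
    """Cross-validation output: one report per classifier plus a run log."""

    reports: Dict[str, MetricsReport]
    fold_logs: List[Dict[str, object]]
    seed: int

    def report(self, name: str) -> MetricsReport:
        return self.reports[name]


# ---------------------------------------------------------------------------
# the cross-validated protocol


def run_cv(
    matrix: FeatureMatrix,
    plan: Optional[FoldPlan] = None,
    classifiers: Sequence[str] | str = CLASSIFIER_NAMES,
    alpha: float = 0.05,
    rule: str = "either",
    variance: float = 0.95,
    k: int = 10,
    seed: int = 0,
) -> CVResult:
    """Run the full leakage-safe protocol.

    For every fold: feature selection, imputation, standardization and
    PCA are fitted on training-subject rows only, then applied to the
    held-out rows; each requested classifier is trained and evaluated on
    the reduced data.  The per-fold transform is shared across
    classifiers (it does not depend on the classifier).  Folds whose
    test rows contain a single class get NaN for the class-conditional
    metrics; the run continues.
    """
    if isinstance(classifiers, str):
        classifiers = (classifiers,)
    for name in classifiers:
        if name not in CLASSIFIER_NAMES:
            raise ValueError(
                f"unknown classifier {name!r}; valid names: {list(CLASSIFIER_NAMES)}"
            )
    if plan is None:
        plan = subject_kfold(matrix, k=k, seed=seed)

    y_all = matrix.y
    fold_rows: Dict[str, List[Dict[str, float]]] = {c: [] for c in classifiers}
    fold_logs: List[Dict[str, object]] = []
    for fold_index, (train_subjects, test_subjects) in enumerate(plan.folds):
        train_mask = matrix.rows_for(train_subjects)
        test_mask = matrix.rows_for(test_subjects)
        train_values = matrix.values[train_mask]
        test_values = matrix.values[test_mask]
        y_train, y_test = y_all[train_mask], y_all[test_mask]

        mask = select_features(train_values, y_train, alpha=alpha, rule=rule)
        model, train_reduced = fit_transform(train_values, mask, variance=variance)
        test_reduced = apply_transform(model, test_values)
        fold_logs.append({
            "fold": fold_index,
            "n_train_rows": int(train_mask.sum()),
            "n_test_rows": int(test_mask.sum()),
            "n_selected": int(mask.sum()),
            "k95": model.k95,
            "test_subjects": list(test_subjects),
        })

        for name in classifiers:
            scores, hard = train_and_predict(
                name, train_reduced, y_train, test_reduced, seed=seed
            )
            row = confusion_metrics(hard, y_test)
            row["AUC"] = auc_rank(scores, y_test)
            fold_rows[name].append(row)

    reports = {
        name: MetricsReport(per_fold=pd.DataFrame(rows))
        for name, rows in fold_rows.items()
    }
    return CVResult(reports=reports, fold_logs=fold_logs, seed=seed)
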