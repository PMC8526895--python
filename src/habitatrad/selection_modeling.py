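"""Feature selection cascade, model grid, and cross-validated evaluation.

The cascade mirrors common radiomics practice: (1) a Spearman redundancy
filter (|rho| > 0.99 drops the later column), (2) a univariate
association filter that routes each feature to a two-sample t-test or a
Mann-Whitney U test depending on Shapiro-Wilk normality and Levene
variance-homogeneity gates, keeping p < .05, and (3) one of three
model-based selectors (SVM-RFE, random-forest importance, LASSO).

Models are evaluated by stratified five-fold cross-validation grouped by
lesion: rows are habitat-level samples, all habitats of a lesion stay in
one fold, the whole cascade is re-fit inside each training fold, and
predictions are averaged over a lesion's habitats before scoring.  The
decision threshold is chosen per fold by maximizing F1 on the training
lesions over a 0.01-step grid.  The full selector x classifier grid has
3 x 6 = 18 pipelines; habitat-generation methods are compared by paired
t-tests over their 18 pipeline-mean AUCs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import (
    AdaBoostClassifier,
    BaggingClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.feature_selection import RFECV
from sklearn.linear_model import LassoCV, LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

SELECTORS = ("svm_rfe", "random_forest", "lasso")
CLASSIFIERS = ("svm", "random_forest", "gbdt", "logistic_regression", "adaboost", "bagging")

POSITIVE_LABEL = "NSCLC"


@dataclass
class SelectionReport:
    """Audit trail of the selection cascade."""

    dropped_by_redundancy: list[dict] = field(default_factory=list)
    univariate: list[dict] = field(default_factory=list)
    model_based: dict = field(default_factory=dict)


@dataclass(frozen=True)
class PipelineSpec:
    selector: str
    classifier: str
    seed: int = 0

    def __post_init__(self):
        if self.selector not in SELECTORS:
            raise ValueError(f"unknown selector {self.selector!r}")
        if self.classifier not in CLASSIFIERS:
            raise ValueError(f"unknown classifier {self.classifier!r}")

    @property
    def name(self) -> str:
        return f"{self.selector}+{self.classifier}"


def pipeline_grid(seed: int = 0) -> list[PipelineSpec]:
    """The full selector x classifier grid: exactly 18 pipelines."""
    return [PipelineSpec(s, c, seed) for s, c in product(SELECTORS, CLASSIFIERS)]


@dataclass
class CvReport:
    """Per-fold and summary metrics of one pipeline on one feature table."""

    pipeline: PipelineSpec
    fold_metrics: pd.DataFrame  # rows: folds; columns: auc, accuracy, sensitivity, specificity, threshold, n_features
    mean: dict = field(default_factory=dict)
    sd: dict = field(default_factory=dict)

    def __post_init__(self):
        for col in ("auc", "accuracy", "sensitivity", "specificity"):
            self.mean[col] = float(self.fold_metrics[col].mean())
            self.sd[col] = float(self.fold_metrics[col].std(ddof=1))


# ---------------------------------------------------------------------------
# filters


def redundancy_filter(
    table: pd.DataFrame, rho_threshold: float = 0.99
) -> tuple[pd.DataFrame, SelectionReport]:
    """Drop near-duplicate features by Spearman correlation.

    A greedy scan in fixed column order keeps the first of any pair with
    |rho| > threshold and drops the later; constant columns (undefined
    rho) are dropped with reason "constant".
    """
    if len(table) < 2:
        raise ValueError("need at least 2 samples")
    report = SelectionReport()
    cols = list(table.columns)
    constant = [c for c in cols if table[c].nunique(dropna=True) <= 1]
    for c in constant:
        report.dropped_by_redundancy.append({"feature": c, "partner": None, "rho": np.nan, "reason": "constant"})
    cols = [c for c in cols if c not in set(constant)]
    if not cols:
        return table[[]], report
    rho = table[cols].rank().corr().to_numpy()  # Pearson of ranks == Spearman
    keep: list[int] = []
    for j in range(len(cols)):
        partner = next((i for i in keep if abs(rho[i, j]) > rho_threshold), None)
        if partner is None:
            keep.append(j)
        else:
            report.dropped_by_redundancy.append(
                {"feature": cols[j], "partner": cols[partner], "rho": float(rho[partner, j]), "reason": "redundant"}
            )
    return table[[cols[j] for j in keep]], report


def univariate_filter(
    table: pd.DataFrame,
    labels: pd.Series,
    alpha: float = 0.05,
    gate: str = "conventional",
    report: SelectionReport | None = None,
) -> pd.DataFrame:
    """Keep features significantly associated with the class (p < alpha).

    Each feature is routed to a two-sample t-test when the parametric
    gates pass, otherwise to a Mann-Whitney U test.  With
    ``gate="conventional"`` the t-test is used when Shapiro-Wilk (per
    class) and Levene do NOT reject (all p >= .05); ``gate="literal"``
    inverts the routing (t-test when all gate p < .05).  Classes with
    fewer than 3 samples skip the normality gate and use Mann-Whitney.
    """
    if gate not in ("conventional", "literal"):
        raise ValueError(f"unknown gate {gate!r}")
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("both classes must be present")
    a_mask, b_mask = labels == classes[0], labels == classes[1]
    if report is None:
        report = SelectionReport()
    kept = []
    for col in table.columns:
        x = table[col].to_numpy(dtype=float)
        xa, xb = x[a_mask], x[b_mask]
        if min(xa.size, xb.size) < 3:
            test = "mannwhitney"
            logger.info("%s: class with < 3 samples, normality gate skipped", col)
        elif np.ptp(xa) == 0 or np.ptp(xb) == 0:
            test = "mannwhitney"  # Shapiro undefined on constant samples
        else:
            sw_a = stats.shapiro(xa).pvalue
            sw_b = stats.shapiro(xb).pvalue
            lev = stats.levene(xa, xb).pvalue
            if gate == "conventional":
                parametric = sw_a >= alpha and sw_b >= alpha and lev >= alpha
            else:
                parametric = sw_a < alpha and sw_b < alpha and lev < alpha
            test = "ttest" if parametric else "mannwhitney"
        if test == "ttest":
            p = stats.ttest_ind(xa, xb).pvalue
        else:
            try:
                p = stats.mannwhitneyu(xa, xb, alternative="two-sided").pvalue
            except ValueError:  # all values identical across both classes
                p = 1.0
        keep = bool(p < alpha)
        report.univariate.append({"feature": col, "test": test, "p": float(p), "kept": keep})
        if keep:
            kept.append(col)
    return table[kept]


# ---------------------------------------------------------------------------
# model-based selection


def model_based_select(
    table: pd.DataFrame, labels: pd.Series, selector: str, seed: int = 0
) -> list[str]:
    """Final selection stage; returns the kept feature names.

    * ``svm_rfe`` — recursive feature elimination with a linear SVM,
      feature count chosen by internal 3-fold CV;
    * ``random_forest`` — keep features with importance above the mean
      importance;
    * ``lasso`` — keep nonzero coefficients at the CV-chosen penalty.

    If a selector returns an empty set, the top-1 ranked feature is kept
    as a fallback.
    """
    if selector not in SELECTORS:
        raise ValueError(f"unknown selector {selector!r}")
    cols = list(table.columns)
    if len(cols) <= 1:
        return cols
    X = StandardScaler().fit_transform(table.to_numpy(dtype=float))
    y = (np.asarray(labels) == POSITIVE_LABEL).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("model-based selection needs both classes")

    if selector == "svm_rfe":
        cv = min(3, int(np.bincount(y).min()))
        rfe = RFECV(
            SVC(kernel="linear", C=1.0),
            step=max(1, len(cols) // 10),
            cv=StratifiedKFold(max(cv, 2), shuffle=True, random_state=seed),
            min_features_to_select=1,
        )
        rfe.fit(X, y)
        kept = [c for c, s in zip(cols, rfe.support_) if s]
        ranking = dict(zip(cols, rfe.ranking_.tolist()))
        top1 = min(ranking, key=ranking.get)
    elif selector == "random_forest":
        rf = RandomForestClassifier(n_estimators=200, random_state=seed)
        rf.fit(X, y)
        imp = rf.feature_importances_
        kept = [c for c, v in zip(cols, imp) if v > imp.mean()]
        top1 = cols[int(np.argmax(imp))]
    else:  # lasso
        lasso = LassoCV(cv=3, random_state=seed, max_iter=5000)
        lasso.fit(X, y.astype(float))
        kept = [c for c, v in zip(cols, lasso.coef_) if v != 0.0]
        top1 = cols[int(np.argmax(np.abs(lasso.coef_)))] if np.any(lasso.coef_) else cols[0]
    if not kept:
        logger.info("%s selected no features; falling back to top-1 (%s)", selector, top1)
        kept = [top1]
    return kept


def _make_classifier(name: str, seed: int):
    if name == "svm":
        return SVC(kernel="rbf", C=1.0, gamma="scale", probability=True, random_state=seed)
    if name == "random_forest":
        return RandomForestClassifier(n_estimators=200, random_state=seed)
    if name == "gbdt":
        return GradientBoostingClassifier(n_estimators=100, random_state=seed)
    if name == "logistic_regression":
        return LogisticRegression(max_iter=2000, random_state=seed)
    if name == "adaboost":
        return AdaBoostClassifier(n_estimators=50, random_state=seed)
    if name == "bagging":
        return BaggingClassifier(n_estimators=10, random_state=seed)
    raise ValueError(f"unknown classifier {name!r}")


# ---------------------------------------------------------------------------
# cross-validation


def f1_optimal_threshold(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Threshold maximizing F1 over the 0.00..1.00 grid (step 0.01).

    Ties are broken toward 0.5.
    """
    grid = np.round(np.arange(0.0, 1.0001, 0.01), 2)
    best_f1, best_t = -1.0, 0.5
    for t in grid:
        pred = scores >= t
        tp = np.sum(pred & (y_true == 1))
        fp = np.sum(pred & (y_true == 0))
        fn = np.sum(~pred & (y_true == 1))
        f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else 0.0
        if f1 > best_f1 + 1e-12 or (abs(f1 - best_f1) <= 1e-12 and abs(t - 0.5) < abs(best_t - 0.5)):
            best_f1, best_t = f1, t
    return float(best_t)


def aggregate_lesion_prediction(habitat_scores) -> float:
    """Lesion-level score: arithmetic mean of its habitats' scores."""
    scores = np.asarray(list(habitat_scores), dtype=float)
    if scores.size == 0:
        raise ValueError("need at least one habitat score")
    return float(scores.mean())


def make_lesion_folds(
    lesion_ids: pd.Series, labels: pd.Series, n_folds: int = 5, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified folds at the lesion level, mapped back to row indices.

    All habitat rows of a lesion share its fold, so no lesion straddles
    the train/test boundary.
    """
    lesion_ids = pd.Series(np.asarray(lesion_ids))
    labels = pd.Series(np.asarray(labels))
    lesion_label = labels.groupby(lesion_ids.values).first()
    counts = lesion_label.value_counts()
    if counts.min() < n_folds:
        raise ValueError(
            f"need at least {n_folds} lesions per class, got {counts.to_dict()}"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    lesions = lesion_label.index.to_numpy()
    folds = []
    for train_l, test_l in skf.split(lesions, lesion_label.to_numpy()):
        train_set = set(lesions[train_l])
        test_set = set(lesions[test_l])
        train_rows = np.flatnonzero(lesion_ids.isin(train_set))
        test_rows = np.flatnonzero(lesion_ids.isin(test_set))
        folds.append((train_rows, test_rows))
    return folds


def _fit_cascade(
    X_train: pd.DataFrame, y_train: pd.Series, selector: str, seed: int, gate: str
):
    """Fit the full selection cascade on a training fold.

    Returns (kept columns, per-column medians for imputation).
    """
    medians = X_train.median()
    Xt = X_train.fillna(medians)
    Xt, _ = redundancy_filter(Xt)
    Xu = univariate_filter(Xt, y_train, gate=gate)
    if Xu.shape[1] == 0:
        # nothing passes the association filter: keep the single smallest-p
        # feature so a model can still be fit (logged, matches the top-1
        # fallback convention of the model-based stage)
        best = min(
            Xt.columns,
            key=lambda c: stats.mannwhitneyu(
                Xt[c][np.asarray(y_train) == np.unique(y_train)[0]],
                Xt[c][np.asarray(y_train) == np.unique(y_train)[1]],
                alternative="two-sided",
            ).pvalue
            if Xt[c].nunique() > 1
            else 1.0,
        )
        logger.info("univariate filter kept nothing; falling back to %s", best)
        Xu = Xt[[best]]
    kept = model_based_select(Xu, y_train, selector, seed=seed)
    return kept, medians


def evaluate_pipeline(
    table: pd.DataFrame,
    labels: pd.Series,
    lesion_ids: pd.Series,
    spec: PipelineSpec,
    folds: list[tuple[np.ndarray, np.ndarray]],
    gate: str = "conventional",
    check_no_leakage: bool = True,
) -> CvReport:
    """Cross-validate one pipeline; metrics are lesion-level.

    Within each fold: median imputation, redundancy + univariate filters,
    model-based selection and classifier fit all use the training rows
    only; habitat scores are averaged per lesion before the AUC and the
    F1-optimized threshold metrics are computed.
    """
    labels = pd.Series(np.asarray(labels))
    lesion_ids = pd.Series(np.asarray(lesion_ids))
    y_all = (labels == POSITIVE_LABEL).astype(int)
    rows = []
    for fold_idx, (train_rows, test_rows) in enumerate(folds):
        if check_no_leakage:
            assert not set(lesion_ids.iloc[train_rows]) & set(lesion_ids.iloc[test_rows]), (
                "lesion straddles the train/test boundary"
            )
        X_train = table.iloc[train_rows].reset_index(drop=True)
        y_train = labels.iloc[train_rows].reset_index(drop=True)
        if y_train.nunique() < 2 or labels.iloc[test_rows].nunique() < 2:
            raise ValueError(f"fold {fold_idx} contains a single class")
        kept, medians = _fit_cascade(X_train, y_train, spec.selector, spec.seed, gate)

        scaler = StandardScaler().fit(X_train[kept].fillna(medians[kept]))
        clf = _make_classifier(spec.classifier, spec.seed)
        clf.fit(scaler.transform(X_train[kept].fillna(medians[kept])), y_all.iloc[train_rows])

        def lesion_scores(row_idx):
            X = table.iloc[row_idx][kept].fillna(medians[kept])
            s = clf.predict_proba(scaler.transform(X))[:, 1]
            df = pd.DataFrame({"lesion": lesion_ids.iloc[row_idx].values, "score": s,
                               "y": y_all.iloc[row_idx].values})
            agg = df.groupby("lesion").agg(score=("score", aggregate_lesion_prediction),
                                           y=("y", "first"))
            return agg["y"].to_numpy(), agg["score"].to_numpy()

        y_tr, s_tr = lesion_scores(train_rows)
        y_te, s_te = lesion_scores(test_rows)
        threshold = f1_optimal_threshold(y_tr, s_tr)
        pred = s_te >= threshold
        tp = np.sum(pred & (y_te == 1)); tn = np.sum(~pred & (y_te == 0))
        fp = np.sum(pred & (y_te == 0)); fn = np.sum(~pred & (y_te == 1))
        rows.append(
            {
                "fold": fold_idx,
                "auc": float(roc_auc_score(y_te, s_te)),
                "accuracy": float((tp + tn) / y_te.size),
                "sensitivity": float(tp / (tp + fn)) if (tp + fn) else np.nan,
                "specificity": float(tn / (tn + fp)) if (tn + fp) else np.nan,
                "threshold": threshold,
                "n_features": len(kept),
            }
        )
    return CvReport(pipeline=spec, fold_metrics=pd.DataFrame(rows).set_index("fold"))


def run_cv_grid(
    table: pd.DataFrame,
    labels: pd.Series,
    lesion_ids: pd.Series,
    n_folds: int = 5,
    seed: int = 0,
    gate: str = "conventional",
    pipelines: list[PipelineSpec] | None = None,
) -> dict[str, CvReport]:
    """Evaluate the full 18-pipeline grid on one feature table."""
    if pipelines is None:
        pipelines = pipeline_grid(seed)
    folds = make_lesion_folds(lesion_ids, labels, n_folds=n_folds, seed=seed)
    reports = {}
    for spec in pipelines:
        reports[spec.name] = evaluate_pipeline(table, labels, lesion_ids, spec, folds, gate=gate)
    return reports


# ---------------------------------------------------------------------------
# method comparison


@dataclass
class ComparisonReport:
    summary: pd.DataFrame  # per-method mean/sd of the metrics over pipelines
    pairwise_p: pd.DataFrame  # paired t-test p-values between methods


def compare_methods(cv_reports_by_method: dict[str, dict[str, CvReport]]) -> ComparisonReport:
    """Compare habitat-generation methods over their shared pipeline grid.

    Pairing is by identical pipeline spec: for each method pair, a paired
    two-sided t-test on the 18 pipeline-mean test AUCs.  A comparison
    with all-zero differences is reported as p = 1.
    """
    methods = list(cv_reports_by_method)
    grids = [tuple(sorted(r)) for r in cv_reports_by_method.values()]
    if len(set(grids)) != 1:
        raise ValueError("methods were evaluated on different pipeline grids")
    pipeline_names = sorted(grids[0])

    auc = pd.DataFrame(
        {m: [cv_reports_by_method[m][p].mean["auc"] for p in pipeline_names] for m in methods},
        index=pipeline_names,
    )
    summary = pd.DataFrame(
        {
            "mean_auc": auc.mean(),
            "sd_auc": auc.std(ddof=1),
            "mean_accuracy": [
                np.mean([cv_reports_by_method[m][p].mean["accuracy"] for p in pipeline_names])
                for m in methods
            ],
            "mean_sensitivity": [
                np.mean([cv_reports_by_method[m][p].mean["sensitivity"] for p in pipeline_names])
                for m in methods
            ],
            "mean_specificity": [
                np.mean([cv_reports_by_method[m][p].mean["specificity"] for p in pipeline_names])
                for m in methods
            ],
        }
    )
    pvals = pd.DataFrame(np.ones((len(methods), len(methods))), index=methods, columns=methods)
    for i, a in enumerate(methods):
        for b in methods[i + 1:]:
            diff = auc[a] - auc[b]
            if np.allclose(diff, 0.0):
                p = 1.0
            elif np.isclose(diff.std(ddof=1), 0.0):
                p = 0.0  # constant nonzero shift: difference is certain
            else:
                p = float(stats.ttest_rel(auc[a], auc[b]).pvalue)
            pvals.loc[a, b] = pvals.loc[b, a] = p
    return ComparisonReport(summary=summary, pairwise_p=pvals)
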