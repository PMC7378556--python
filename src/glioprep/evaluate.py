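"""Tumour-grade classification harness and the surrounding statistics.

Five classifier families (random forest, naive Bayes, logistic regression,
support-vector machine, multi-layer perceptron) at fixed, seeded default
configurations, evaluated with stratified 5-fold cross-validation.
Feature standardization (column-wise z-scoring) is fitted on the training
rows of each fold only, so held-out rows never influence the scaling.
Reported per fold and model: balanced accuracy and ROC-AUC; the 95%
confidence interval is a percentile bootstrap (1000 resamples) of the
mean over the pooled 25 fold x model scores.

Feature-set models: 1 = first-order only, 2 = texture only, 3 = both,
4 = the robust subset from a paired-cohort robustness report.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import FEATURE_NAMES, FIRST_ORDER_NAMES, TEXTURE_NAMES
from .robustness import RobustnessReport

__all__ = [
    "CLASSIFIER_FAMILIES",
    "FeatureSetModel",
    "ClassificationResult",
    "balanced_accuracy",
    "roc_auc",
    "cross_validate_models",
    "bootstrap_ci",
    "factorial_anova_tukey",
]

CLASSIFIER_FAMILIES = (
    "random_forest",
    "naive_bayes",
    "logistic_regression",
    "svm",
    "neural_network",
)

POSITIVE_CLASS = "high"


def _make_classifiers(seed: int) -> dict[str, object]:
    """Library-default configurations, seeded for determinism."""
    return {
        "random_forest": RandomForestClassifier(random_state=seed),
        "naive_bayes": GaussianNB(),
        "logistic_regression": LogisticRegression(max_iter=1000, random_state=seed),
        "svm": SVC(random_state=seed),
        "neural_network": MLPClassifier(random_state=seed),
    }


@dataclass(frozen=True)
class FeatureSetModel:
    """Which feature columns enter the classifier (models 1-4)."""

    id: int
    robustness: RobustnessReport | None = None

    def __post_init__(self) -> None:
        if self.id not in (1, 2, 3, 4):
            raise ValueError(f"model id must be in 1..4, got {self.id}")
        if self.id == 4:
            if self.robustness is None:
                raise ValueError("model 4 requires a robustness report")
            if len(self.robustness.robust_features) == 0:
                raise ValueError("model 4 requires at least one robust feature")

    @property
    def feature_columns(self) -> list[str]:
        if self.id == 1:
            return list(FIRST_ORDER_NAMES)
        if self.id == 2:
            return list(TEXTURE_NAMES)
        if self.id == 3:
            return list(FEATURE_NAMES)
        return self.robustness.robust_features


@dataclass(frozen=True)
class ClassificationResult:
    """Per-(fold x model) scores with bootstrap CIs and condition metadata."""

    bac_scores: pd.DataFrame   # index fold, columns model families
    auc_scores: pd.DataFrame
    bac_mean: float
    auc_mean: float
    bac_ci95: tuple[float, float]
    auc_ci95: tuple[float, float]
    fold_assignment: dict[str, int]
    fold_scaler_means: dict[int, np.ndarray] = field(default_factory=dict)
    condition: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "condition": self.condition,
            "bac_mean": self.bac_mean,
            "bac_ci95": list(self.bac_ci95),
            "auc_mean": self.auc_mean,
            "auc_ci95": list(self.auc_ci95),
            "bac_scores": {m: self.bac_scores[m].tolist() for m in self.bac_scores.columns},
            "auc_scores": {m: self.auc_scores[m].tolist() for m in self.auc_scores.columns},
        }


def balanced_accuracy(confusion: np.ndarray) -> float:
    """(sensitivity + specificity) / 2 from a 2x2 confusion matrix
    [[TN, FP], [FN, TP]]."""
    c = np.asarray(confusion, dtype=np.float64)
    if c.shape != (2, 2):
        raise ValueError(f"expected a 2x2 confusion matrix, got {c.shape}")
    tn, fp = c[0]
    fn, tp = c[1]
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("both true classes must be present")
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    return float(0.5 * (sens + spec))


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """P(score_pos > score_neg) with ties counted 1/2 (Mann-Whitney)."""
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels, dtype=bool)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = sps.rankdata(s)
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _decision_scores(clf, x: np.ndarray) -> np.ndarray:
    """Continuous scores oriented so larger means 'more positive class'."""
    if hasattr(clf, "decision_function"):
        s = np.asarray(clf.decision_function(x), dtype=np.float64)
        # decision_function is positive towards classes_[1]
        return s if clf.classes_[1] == POSITIVE_CLASS else -s
    proba = clf.predict_proba(x)
    pos_idx = list(clf.classes_).index(POSITIVE_CLASS)
    return np.asarray(proba[:, pos_idx], dtype=np.float64)


def cross_validate_models(
    table: pd.DataFrame, fs: FeatureSetModel, k: int = 5, seed: int = 0
) -> ClassificationResult:
    """Stratified k-fold CV of the five families on one feature table.

    Column-wise z-scoring is fitted per fold on training rows only.
    Returns the k x 5 balanced-accuracy and ROC-AUC score grids plus
    pooled bootstrap CIs.  Deterministic given (table, fs, seed).
    """
    cols = fs.feature_columns
    x_all = table[cols].to_numpy(dtype=np.float64)
    y_all = table["grade"].to_numpy()
    classes, counts = np.unique(y_all, return_counts=True)
    if len(classes) != 2:
        raise ValueError(f"expected exactly 2 grades, got {list(classes)}")
    if counts.min() < k:
        raise ValueError(f"need at least {k} cases per class, got {dict(zip(classes, counts))}")

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    bac = np.zeros((k, len(CLASSIFIER_FAMILIES)))
    auc = np.zeros((k, len(CLASSIFIER_FAMILIES)))
    fold_assignment: dict[str, int] = {}
    fold_scaler_means: dict[int, np.ndarray] = {}
    case_ids = table["case_id"].to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # MLP/logistic convergence chatter
        for f, (train, test) in enumerate(skf.split(x_all, y_all)):
            for cid in case_ids[test]:
                fold_assignment[str(cid)] = f
            scaler = StandardScaler().fit(x_all[train])
            fold_scaler_means[f] = np.array(scaler.mean_, copy=True)
            xtr = scaler.transform(x_all[train])
            xte = scaler.transform(x_all[test])
            ytr, yte = y_all[train], y_all[test]
            y_true = yte == POSITIVE_CLASS
            if y_true.all() or not y_true.any():
                raise ValueError(f"fold {f} lost a class during stratification")
            for m, name in enumerate(CLASSIFIER_FAMILIES):
                clf = _make_classifiers(seed + 1000 * f)[name]
                clf.fit(xtr, ytr)
                pred = clf.predict(xte) == POSITIVE_CLASS
                conf = np.array(
                    [
                        [np.sum(~y_true & ~pred), np.sum(~y_true & pred)],
                        [np.sum(y_true & ~pred), np.sum(y_true & pred)],
                    ]
                )
                bac[f, m] = balanced_accuracy(conf)
                auc[f, m] = roc_auc(_decision_scores(clf, xte), y_true)

    bac_df = pd.DataFrame(bac, columns=list(CLASSIFIER_FAMILIES))
    auc_df = pd.DataFrame(auc, columns=list(CLASSIFIER_FAMILIES))
    bac_ci = bootstrap_ci(bac.ravel(), seed=seed + 7)
    auc_ci = bootstrap_ci(auc.ravel(), seed=seed + 8)
    return ClassificationResult(
        bac_scores=bac_df,
        auc_scores=auc_df,
        bac_mean=float(bac.mean()),
        auc_mean=float(auc.mean()),
        bac_ci95=bac_ci,
        auc_ci95=auc_ci,
        fold_assignment=fold_assignment,
        fold_scaler_means=fold_scaler_means,
        condition={"model": fs.id, "k": k, "seed": seed},
    )


def bootstrap_ci(
    values: np.ndarray, n_boot: int = 1000, level: float = 0.95, seed: int = 0
) -> tuple[float, float]:
    """Percentile bootstrap interval of the mean of `values`."""
    v = np.asarray(values, dtype=np.float64).ravel()
    if v.size == 0:
        raise ValueError("empty input")
    if v.size < 2:
        return (float(v[0]), float(v[0]))
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, v.size, size=(n_boot, v.size))
    means = v[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(means, [100 * alpha, 100 * (1 - alpha)])
    return (float(lo), float(hi))


def factorial_anova_tukey(
    scores: pd.DataFrame,
    response: str,
    factors: list[str],
    alpha: float = 0.05,
) -> dict:
    """One- or two-way ANOVA (type-II sums of squares) + Tukey HSD.

    For each factor with P < alpha, pairwise Tukey HSD mean differences
    with adjusted P values are reported.  Raises on single-level factors.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    if not factors:
        raise ValueError("need at least one factor")
    data = scores[[response] + factors].copy()
    data.columns = ["response"] + [f"f{i}" for i in range(len(factors))]
    for i, factor in enumerate(factors):
        if data[f"f{i}"].nunique() < 2:
            raise ValueError(f"factor {factor!r} has fewer than 2 levels")
    formula = "response ~ " + " + ".join(f"C(f{i})" for i in range(len(factors)))
    fit = ols(formula, data=data).fit()
    anova = sm.stats.anova_lm(fit, typ=2)
    report: dict = {"alpha": alpha, "factors": {}}
    for i, factor in enumerate(factors):
        row = anova.loc[f"C(f{i})"]
        f_val = float(row["F"])
        p_val = float(row["PR(>F)"])
        entry: dict = {"F": f_val, "P": p_val, "significant": bool(p_val < alpha)}
        if p_val < alpha:
            from itertools import combinations

            tk = pairwise_tukeyhsd(data["response"], data[f"f{i}"], alpha=alpha)
            pair_labels = list(combinations(tk.groupsunique, 2))
            entry["tukey"] = [
                {
                    "group1": str(g1),
                    "group2": str(g2),
                    "meandiff": float(md),
                    "p_adj": float(p),
                    "reject": bool(rej),
                }
                for (g1, g2), md, p, rej in zip(
                    pair_labels, tk.meandiffs, tk.pvalues, tk.reject, strict=True
                )
            ]
        report["factors"][factor] = entry
    return report
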