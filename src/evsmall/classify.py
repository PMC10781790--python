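"""Biomarker-panel evaluation.

Stratified 60/40 train/validation split, all-relevant (Boruta-style) feature
selection on the differentially expressed miRNAs, a cost-tuned SVM with
5-fold cross-validation on the training set, confusion-matrix metrics, and
ROC/AUC with bootstrap confidence intervals.

Selection and standardization see training samples only; validation data
enter only at predict time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

DEFAULT_COST_GRID = (0.01, 0.1, 1.0, 10.0, 100.0)


# --------------------------------------------------------------------------
# Split
# --------------------------------------------------------------------------


@dataclass
class SplitSpec:
    train_fraction: float = 0.6
    stratify_by: str = "group"
    seed: int = 0


def stratified_split(metadata: pd.DataFrame, spec: SplitSpec) -> tuple[list[str], list[str]]:
    """Per-class train/validation split (default 60/40), seed-deterministic.

    Rounds the per-class train count to nearest while keeping at least one
    sample of every class on each side.
    """
    rng = np.random.default_rng(spec.seed)
    train_ids: list[str] = []
    val_ids: list[str] = []
    for cls, sub in metadata.groupby(spec.stratify_by, sort=True):
        ids = np.array(sub.index)
        if len(ids) < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 samples")
        rng.shuffle(ids)
        n_train = int(round(spec.train_fraction * len(ids)))
        n_train = min(max(n_train, 1), len(ids) - 1)
        train_ids.extend(ids[:n_train])
        val_ids.extend(ids[n_train:])
    return train_ids, val_ids


# --------------------------------------------------------------------------
# Boruta-style all-relevant feature selection
# --------------------------------------------------------------------------


@dataclass
class FeatureSet:
    """Outcome of all-relevant selection."""

    confirmed: list[str]
    rejected: list[str]
    tentative: list[str]
    decisions: dict[str, str]
    importance_history: pd.DataFrame  # runs x features
    n_runs: int

    @property
    def selected(self) -> list[str]:
        return self.confirmed


def boruta_select(
    X: pd.DataFrame,
    y,
    max_runs: int = 100,
    alpha: float = 0.05,
    n_estimators: int = 500,
    seed: int = 0,
) -> FeatureSet:
    """All-relevant feature selection against shadow features.

    Each run appends an independently shuffled shadow copy of every feature,
    fits a random-forest importance oracle, and scores a "hit" for every
    feature whose importance exceeds the maximum shadow importance. After each
    run, two-sided binomial tests on the hit counts (Bonferroni-corrected
    over the still-undecided features) promote features to confirmed or
    rejected; the loop stops when nothing is tentative or ``max_runs`` is
    reached. Remaining tentative features are resolved by comparing their
    median importance with the median of the per-run maximum shadow
    importance.
    """
    if X.shape[1] < 2:
        raise ValueError("need at least 2 candidate features")
    if X.shape[0] < 8:
        raise ValueError("need at least 8 training samples")
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("labels are degenerate (single class)")
    rng = np.random.default_rng(seed)
    features = list(X.columns)
    status = {f: "tentative" for f in features}
    hits = {f: 0 for f in features}
    history = []
    shadow_max_history = []
    Xv = X.to_numpy(dtype=float)
    n_runs = 0
    for run in range(1, max_runs + 1):
        n_runs = run
        shadow = Xv.copy()
        for j in range(shadow.shape[1]):
            rng.shuffle(shadow[:, j])
        augmented = np.hstack([Xv, shadow])
        forest = RandomForestClassifier(
            n_estimators=n_estimators,
            random_state=int(rng.integers(0, 2**31 - 1)),
            n_jobs=1,
        )
        forest.fit(augmented, y)
        importances = forest.feature_importances_
        real_imp = importances[: len(features)]
        shadow_max = importances[len(features) :].max()
        shadow_max_history.append(shadow_max)
        history.append(dict(zip(features, real_imp)))
        for f, imp in zip(features, real_imp):
            if imp > shadow_max:
                hits[f] += 1
        undecided = [f for f in features if status[f] == "tentative"]
        if not undecided:
            break
        bonf = len(undecided)
        for f in undecided:
            p_hi = stats.binomtest(hits[f], run, 0.5, alternative="greater").pvalue
            p_lo = stats.binomtest(hits[f], run, 0.5, alternative="less").pvalue
            if p_hi * bonf < alpha:
                status[f] = "confirmed"
            elif p_lo * bonf < alpha:
                status[f] = "rejected"
        if all(s != "tentative" for s in status.values()):
            break
    hist_df = pd.DataFrame(history)
    median_shadow = float(np.median(shadow_max_history))
    for f in features:
        if status[f] == "tentative":
            status[f] = (
                "confirmed" if hist_df[f].median() > median_shadow else "rejected"
            )
    return FeatureSet(
        confirmed=[f for f in features if status[f] == "confirmed"],
        rejected=[f for f in features if status[f] == "rejected"],
        tentative=[],
        decisions=status,
        importance_history=hist_df,
        n_runs=n_runs,
    )


# --------------------------------------------------------------------------
# SVM with cross-validation
# --------------------------------------------------------------------------


@dataclass
class TrainedClassifier:
    model: Pipeline
    best_cost: float
    cv_accuracy: float  # mean CV accuracy of the selected cost
    cv_accuracy_by_cost: dict[float, float]
    fold_accuracies: list[float]
    classes: list
    positive_class: object

    def decision_scores(self, X: pd.DataFrame) -> np.ndarray:
        """Continuous margin scores, oriented toward the positive class."""
        scores = self.model.decision_function(X.to_numpy(dtype=float))
        if self.model.named_steps["svc"].classes_[1] != self.positive_class:
            scores = -scores
        return scores

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.model.predict(X.to_numpy(dtype=float))


def train_classifier_cv(
    X: pd.DataFrame,
    y,
    positive_class,
    folds: int = 5,
    seed: int = 0,
    kernel: str = "linear",
    cost_grid=DEFAULT_COST_GRID,
) -> TrainedClassifier:
    """Standardize (train statistics only), tune SVM cost by stratified
    k-fold CV accuracy, refit on the full training set."""
    if X.shape[1] < 1:
        raise ValueError("at least one selected feature required")
    y = np.asarray(y)
    if len(y) < folds:
        raise ValueError("fewer samples than folds")
    Xv = X.to_numpy(dtype=float)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(Xv, y))
    cv_by_cost: dict[float, float] = {}
    fold_acc_by_cost: dict[float, list[float]] = {}
    for cost in cost_grid:
        accs = []
        for tr, te in splits:
            pipe = Pipeline(
                [("scale", StandardScaler()), ("svc", SVC(kernel=kernel, C=cost))]
            )
            pipe.fit(Xv[tr], y[tr])
            accs.append(float(np.mean(pipe.predict(Xv[te]) == y[te])))
        cv_by_cost[cost] = float(np.mean(accs))
        fold_acc_by_cost[cost] = accs
    best_cost = max(cv_by_cost, key=lambda c: (cv_by_cost[c], -c))
    final = Pipeline(
        [("scale", StandardScaler()), ("svc", SVC(kernel=kernel, C=best_cost))]
    )
    final.fit(Xv, y)
    return TrainedClassifier(
        model=final,
        best_cost=best_cost,
        cv_accuracy=cv_by_cost[best_cost],
        cv_accuracy_by_cost=cv_by_cost,
        fold_accuracies=fold_acc_by_cost[best_cost],
        classes=sorted(set(y)),
        positive_class=positive_class,
    )


# --------------------------------------------------------------------------
# Metrics
# --------------------------------------------------------------------------


@dataclass
class ConfusionMetrics:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float  # percent
    specificity: float  # percent
    accuracy: float  # percent


def confusion_metrics(y_true, y_pred, positive_class) -> ConfusionMetrics:
    """Sensitivity/specificity/accuracy (percent, 2 decimals)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    pos = y_true == positive_class
    if not pos.any():
        raise ValueError("sensitivity undefined: no positive-class samples in truth")
    pred_pos = y_pred == positive_class
    tp = int(np.sum(pos & pred_pos))
    fn = int(np.sum(pos & ~pred_pos))
    tn = int(np.sum(~pos & ~pred_pos))
    fp = int(np.sum(~pos & pred_pos))
    sens = 100.0 * tp / (tp + fn)
    spec = 100.0 * tn / (tn + fp) if (tn + fp) else float("nan")
    acc = 100.0 * (tp + tn) / len(y_true)
    return ConfusionMetrics(
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        sensitivity=round(sens, 2),
        specificity=round(spec, 2),
        accuracy=round(acc, 2),
    )


def roc_auc(scores, labels, positive_class=1) -> tuple[pd.DataFrame, float]:
    """ROC staircase over all thresholds and the Mann-Whitney AUC (ties 1/2).

    Returns (DataFrame with columns fpr/tpr/threshold, auc).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == positive_class
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes required for ROC")
    ranks = stats.rankdata(scores)
    auc = (ranks[pos].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    order = np.argsort(-scores, kind="stable")
    sorted_pos = pos[order]
    sorted_scores = scores[order]
    tps = np.cumsum(sorted_pos)
    fps = np.cumsum(~sorted_pos)
    # keep the last point of each tied-score block
    distinct = np.r_[sorted_scores[1:] != sorted_scores[:-1], True]
    points = pd.DataFrame(
        {
            "fpr": np.r_[0.0, fps[distinct] / n0],
            "tpr": np.r_[0.0, tps[distinct] / n1],
            "threshold": np.r_[np.inf, sorted_scores[distinct]],
        }
    )
    return points, float(auc)


def bootstrap_auc_ci(
    scores,
    labels,
    positive_class=1,
    iterations: int = 100,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap CI for the AUC, resampling within each class."""
    if iterations < 2:
        raise ValueError("need at least 2 bootstrap iterations")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    pos_idx = np.flatnonzero(labels == positive_class)
    neg_idx = np.flatnonzero(labels != positive_class)
    if len(pos_idx) == 0 or len(neg_idx) == 0:
        raise ValueError("both classes required")
    aucs = np.empty(iterations)
    for b in range(iterations):
        pi = rng.choice(pos_idx, size=len(pos_idx), replace=True)
        ni = rng.choice(neg_idx, size=len(neg_idx), replace=True)
        idx = np.r_[pi, ni]
        _, aucs[b] = roc_auc(scores[idx], labels[idx], positive_class)
    lo = (1.0 - level) / 2.0
    return float(np.quantile(aucs, lo)), float(np.quantile(aucs, 1.0 - lo))


def compare_auc(
    scores_a,
    scores_b,
    labels,
    positive_class=1,
    iterations: int = 100,
    seed: int = 0,
) -> float:
    """Bootstrap p value for AUC(a) == AUC(b) on the same samples.

    Resamples cases (stratified) jointly for both score sets and returns a
    two-sided p from the bootstrap distribution of the AUC difference.
    """
    if iterations < 2:
        raise ValueError("need at least 2 bootstrap iterations")
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    pos_idx = np.flatnonzero(labels == positive_class)
    neg_idx = np.flatnonzero(labels != positive_class)
    diffs = np.empty(iterations)
    for b in range(iterations):
        pi = rng.choice(pos_idx, size=len(pos_idx), replace=True)
        ni = rng.choice(neg_idx, size=len(neg_idx), replace=True)
        idx = np.r_[pi, ni]
        _, auc_a = roc_auc(scores_a[idx], labels[idx], positive_class)
        _, auc_b = roc_auc(scores_b[idx], labels[idx], positive_class)
        diffs[b] = auc_a - auc_b
    frac_le = np.mean(diffs <= 0)
    frac_ge = np.mean(diffs >= 0)
    return float(min(1.0, 2.0 * min(frac_le, frac_ge)))


# --------------------------------------------------------------------------
# End-to-end panel evaluation
# --------------------------------------------------------------------------


@dataclass
class ClassifierEvaluation:
    selected_features: list[str]
    selection_fallback: bool
    cv_accuracy: float
    train_metrics: ConfusionMetrics
    validation_metrics: ConfusionMetrics
    train_auc: float
    validation_auc: float
    validation_auc_ci: tuple[float, float]
    roc_points: pd.DataFrame
    train_ids: list[str] = field(default_factory=list)
    validation_ids: list[str] = field(default_factory=list)


def evaluate_biomarker_panel(
    expression: pd.DataFrame,
    metadata: pd.DataFrame,
    contrast: tuple[str, str],
    de_features: list[str],
    seed: int = 0,
    train_fraction: float = 0.6,
    boruta_runs: int = 100,
    n_estimators: int = 500,
    folds: int = 5,
    kernel: str = "linear",
    bootstrap_iterations: int = 100,
) -> ClassifierEvaluation:
    """DE features -> Boruta -> cost-tuned SVM -> metrics, leakage-free.

    ``expression`` is features x samples (log scale); the positive class is
    the first group of the contrast (the disease group). When selection
    confirms no feature (null-like cohorts), all input features are used and
    ``selection_fallback`` is set.
    """
    a, b = contrast
    meta = metadata[metadata["group"].isin([a, b])]
    train_ids, val_ids = stratified_split(
        meta, SplitSpec(train_fraction=train_fraction, seed=seed)
    )
    Xt = expression.loc[de_features, train_ids].T
    yt = meta.loc[train_ids, "group"].to_numpy()
    fs = boruta_select(
        Xt, yt, max_runs=boruta_runs, n_estimators=n_estimators, seed=seed
    )
    fallback = not fs.confirmed
    selected = fs.confirmed if fs.confirmed else list(de_features)
    clf = train_classifier_cv(
        Xt[selected], yt, positive_class=a, folds=folds, seed=seed, kernel=kernel
    )
    Xv = expression.loc[selected, val_ids].T
    yv = meta.loc[val_ids, "group"].to_numpy()
    train_pred = clf.predict(Xt[selected])
    val_pred = clf.predict(Xv)
    train_scores = clf.decision_scores(Xt[selected])
    val_scores = clf.decision_scores(Xv)
    _, train_auc = roc_auc(train_scores, yt, positive_class=a)
    roc_points, val_auc = roc_auc(val_scores, yv, positive_class=a)
    ci = bootstrap_auc_ci(
        val_scores, yv, positive_class=a, iterations=bootstrap_iterations, seed=seed
    )
    return ClassifierEvaluation(
        selected_features=selected,
        selection_fallback=fallback,
        cv_accuracy=clf.cv_accuracy,
        train_metrics=confusion_metrics(yt, train_pred, a),
        validation_metrics=confusion_metrics(yv, val_pred, a),
        train_auc=train_auc,
        validation_auc=val_auc,
        validation_auc_ci=ci,
        roc_points=roc_points,
        train_ids=train_ids,
        validation_ids=val_ids,
    )
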