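"""Genotype prediction: four classifier families, minority oversampling,
leave-one-out cross-validation, ROC/AUC, paired bootstrap AUC comparison,
and nested feature selection (halving-schedule backward elimination or
elastic-net logistic at mixing parameter 0.5).

Classifier families and tuning parameters mirror the stock settings of a
classic ML workbench: random forest with 1000 trees and
mtry = floor(log2(p)) + 1; degree-1 polynomial-kernel SVM at C = 1;
logistic regression with a vanishing ridge (1e-8); and a one-hidden-layer
perceptron with (p + 2) / 2 units trained by SGD (learning rate 0.3,
momentum 0.2, 500 epochs).  All randomness derives from a single run seed
through a documented stage-name hash, so every result is reproducible.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold, cross_val_predict
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "FAMILIES",
    "EvaluationReport",
    "AUCComparison",
    "FeatureSelectionResult",
    "derive_seed",
    "mtry_default",
    "oversample_minority",
    "make_classifier",
    "loocv_evaluate",
    "roc_auc",
    "compare_auc_bootstrap",
    "nested_feature_selection",
    "run_model_suite",
]

FAMILIES = ("random_forest", "svm_poly", "logistic_ridge", "mlp")


def derive_seed(base_seed: int, *tokens) -> int:
    """Deterministic sub-seed from a run seed and stage tokens (< 2**31)."""
    h = hashlib.sha256(("|".join([str(base_seed), *map(str, tokens)])).encode())
    return int.from_bytes(h.digest()[:4], "big") % (2**31)


def mtry_default(n_features: int) -> int:
    """Features tried per split in the random forest: floor(log2(p)) + 1
    (7 when p = 93)."""
    if n_features < 1:
        raise ValueError("n_features must be positive")
    return int(np.floor(np.log2(n_features))) + 1


# ---------------------------------------------------------------------------
# Oversampling


def _as_2d(X) -> np.ndarray:
    X = X.to_numpy() if isinstance(X, pd.DataFrame) else np.asarray(X)
    if X.ndim != 2:
        raise ValueError("feature matrix must be 2-D")
    return X


def oversample_minority(X, y, seed: int | None = None):
    """Balance classes by duplicating randomly drawn minority rows (with
    replacement) until class counts are equal; all original rows retained.

    Returns (X_balanced, y_balanced, row_indices) where row_indices maps
    each balanced row back to a row of the input.
    """
    X = _as_2d(X)
    y = np.asarray(y).ravel()
    if len(X) != len(y):
        raise ValueError("X and y lengths differ")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("oversampling requires two classes present")
    if len(classes) > 2:
        raise ValueError("binary labels expected")
    rng = np.random.default_rng(seed)
    idx = np.arange(len(y))
    if counts[0] == counts[1]:
        return X, y, idx
    minority = classes[np.argmin(counts)]
    deficit = int(abs(counts[0] - counts[1]))
    pool = idx[y == minority]
    extra = rng.choice(pool, size=deficit, replace=True)
    order = np.concatenate([idx, extra])
    return X[order], y[order], order


# ---------------------------------------------------------------------------
# Classifier factory


class PlattScaledSVC(BaseEstimator, ClassifierMixin):
    """Polynomial-kernel SVM whose ROC scores come from a held-out-fold
    logistic (Platt) calibration of its decision values.

    The calibrator is a 1-D logistic fit on cross-validated decision values
    of the training data, then applied to the final SVM's decision values —
    a strictly monotone map, so the ranking (hence AUC) of the margins is
    preserved while scores live in [0, 1].
    """

    def __init__(self, C: float = 1.0, degree: int = 1, random_state: int | None = None):
        self.C = C
        self.degree = degree
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).ravel()
        self.classes_ = np.unique(y)
        svc = SVC(kernel="poly", degree=self.degree, C=self.C, coef0=1.0, gamma="scale")
        self.svc_ = clone(svc).fit(X, y)
        n_min = int(np.bincount(np.searchsorted(self.classes_, y)).min())
        cv = StratifiedKFold(
            n_splits=max(2, min(3, n_min)), shuffle=True, random_state=self.random_state
        )
        try:
            d_cv = cross_val_predict(svc, X, y, cv=cv, method="decision_function")
        except ValueError:  # a fold lost one class entirely; fall back in-sample
            d_cv = self.svc_.decision_function(X)
        self.calibrator_ = LogisticRegression(C=1e6, max_iter=1000).fit(
            d_cv.reshape(-1, 1), y
        )
        return self

    def decision_function(self, X):
        return self.svc_.decision_function(np.asarray(X, dtype=float))

    def predict_proba(self, X):
        d = self.decision_function(X).reshape(-1, 1)
        return self.calibrator_.predict_proba(d)

    def predict(self, X):
        return self.svc_.predict(np.asarray(X, dtype=float))


def make_classifier(
    family: str,
    n_features: int,
    random_state: int | None = None,
    n_trees: int = 1000,
):
    """Build a classifier of one of the four families with its stock tuning
    parameters.  Scale-sensitive families are wrapped in a standardizer;
    the forest is scale-invariant and used raw."""
    if family == "random_forest":
        return RandomForestClassifier(
            n_estimators=n_trees,
            max_features=mtry_default(n_features),
            random_state=random_state,
        )
    if family == "svm_poly":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("svm", PlattScaledSVC(C=1.0, degree=1, random_state=random_state)),
            ]
        )
    if family == "logistic_ridge":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("lr", LogisticRegression(C=1.0 / 1e-8, max_iter=5000)),
            ]
        )
    if family == "mlp":
        hidden = max(2, (n_features + 2) // 2)
        return Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "mlp",
                    MLPClassifier(
                        hidden_layer_sizes=(hidden,),
                        solver="sgd",
                        learning_rate_init=0.3,
                        momentum=0.2,
                        max_iter=500,
                        random_state=random_state,
                    ),
                ),
            ]
        )
    raise ValueError(f"unknown model family {family!r}; expected one of {FAMILIES}")


# ---------------------------------------------------------------------------
# ROC / AUC


def roc_auc(scores, labels) -> tuple[np.ndarray, np.ndarray, float]:
    """Pooled ROC curve and AUC (rank statistic; ties contribute 1/2)."""
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel()
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, _ = roc_curve(labels, scores)
    return fpr, tpr, float(roc_auc_score(labels, scores))


@dataclass
class EvaluationReport:
    """Pooled out-of-fold predictions of one model under LOOCV."""

    model: str
    scores: np.ndarray  # per-subject out-of-fold P(label=1)
    labels: np.ndarray
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    accuracy: float
    sensitivity: float
    specificity: float
    threshold: float
    seed: int
    oversample_in_fold: bool
    fold_train_rows: list = field(default_factory=list, repr=False)

    def to_row(self) -> dict:
        return {
            "model": self.model,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
        }


def _confusion_metrics(scores, labels, threshold=0.5):
    pred = (np.asarray(scores) >= threshold).astype(int)
    labels = np.asarray(labels).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    acc = (tp + tn) / len(labels)
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    return acc, sens, spec


def loocv_evaluate(
    X,
    y,
    model: str = "random_forest",
    oversample_in_fold: bool = True,
    seed: int = 0,
    *,
    n_trees: int = 1000,
    threshold: float = 0.5,
    record_folds: bool = False,
) -> EvaluationReport:
    """Leave-one-out cross-validation: each subject is scored by a model
    trained on all others, with minority oversampling applied inside the
    training fold (never touching the held-out subject).  Scores are pooled
    into one ROC; accuracy/sensitivity/specificity use the given score cut.
    """
    X = _as_2d(X)
    y = np.asarray(y).ravel().astype(int)
    n = len(y)
    counts = np.bincount(y, minlength=2)
    if counts.min() < 2:
        raise ValueError("LOOCV needs at least 2 subjects per class")
    scores = np.empty(n)
    fold_rows: list[np.ndarray] = []
    for i in range(n):
        train = np.delete(np.arange(n), i)
        Xt, yt = X[train], y[train]
        if len(np.unique(yt)) < 2:
            raise ValueError(f"training fold for subject {i} contains a single class")
        rows = train
        if oversample_in_fold:
            Xt, yt, order = oversample_minority(Xt, yt, derive_seed(seed, "oversample", i))
            rows = train[order]
        if record_folds:
            fold_rows.append(rows)
        clf = make_classifier(model, X.shape[1], derive_seed(seed, "model", model, i), n_trees)
        clf.fit(Xt, yt)
        scores[i] = clf.predict_proba(X[i : i + 1])[0, list(clf.classes_).index(1)]
    fpr, tpr, auc = roc_auc(scores, y)
    acc, sens, spec = _confusion_metrics(scores, y, threshold)
    return EvaluationReport(
        model=model,
        scores=scores,
        labels=y,
        auc=auc,
        fpr=fpr,
        tpr=tpr,
        accuracy=acc,
        sensitivity=sens,
        specificity=spec,
        threshold=threshold,
        seed=seed,
        oversample_in_fold=oversample_in_fold,
        fold_train_rows=fold_rows,
    )


# ---------------------------------------------------------------------------
# Bootstrap AUC comparison


@dataclass
class AUCComparison:
    model_a: str
    model_b: str
    auc_a: float
    auc_b: float
    delta: float
    p_value: float
    n_boot: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "model_a": self.model_a, "model_b": self.model_b,
            "auc_a": self.auc_a, "auc_b": self.auc_b,
            "delta": self.delta, "p_value": self.p_value,
            "n_boot": self.n_boot, "seed": self.seed,
        }


def _auc_rank(scores, labels):
    return roc_auc_score(labels, scores)


def compare_auc_bootstrap(
    report_a: EvaluationReport,
    report_b: EvaluationReport,
    n_boot: int = 2000,
    seed: int = 0,
) -> AUCComparison:
    """Paired stratified bootstrap test of AUC(a) − AUC(b).

    Positive and negative subjects are resampled with replacement
    separately; both models' AUCs are recomputed on each replicate from
    their pooled out-of-fold scores.  The standardized observed difference
    D = delta / sd(bootstrap deltas) is referred to a standard normal,
    two-sided — the bootstrap ROC-comparison test of the pROC tradition.
    """
    if not np.array_equal(report_a.labels, report_b.labels):
        raise ValueError("reports cover different subjects (label vectors differ)")
    y = report_a.labels
    sa, sb = report_a.scores, report_b.scores
    delta = report_a.auc - report_b.auc
    rng = np.random.default_rng(seed)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    deltas = np.empty(n_boot)
    for b in range(n_boot):
        rp = rng.choice(pos, size=len(pos), replace=True)
        rn = rng.choice(neg, size=len(neg), replace=True)
        take = np.concatenate([rp, rn])
        yb = y[take]
        deltas[b] = _auc_rank(sa[take], yb) - _auc_rank(sb[take], yb)
    sd = float(np.std(deltas, ddof=1))
    if sd == 0.0:
        p = 1.0 if delta == 0.0 else 0.0
    else:
        p = float(2.0 * (1.0 - norm.cdf(abs(delta) / sd)))
    return AUCComparison(
        model_a=report_a.model, model_b=report_b.model,
        auc_a=report_a.auc, auc_b=report_b.auc,
        delta=float(delta), p_value=p, n_boot=n_boot, seed=seed,
    )


# ---------------------------------------------------------------------------
# Nested feature selection


@dataclass
class FeatureSelectionResult:
    scheme: str
    aucs: np.ndarray  # one pooled AUC per repeat
    mean_auc: float
    sd_auc: float
    selected_sets: list  # per repeat: list of per-fold selected index arrays
    seed: int

    def selection_frequency(self, n_features: int) -> np.ndarray:
        counts = np.zeros(n_features)
        total = 0
        for rep in self.selected_sets:
            for sel in rep:
                counts[np.asarray(sel, dtype=int)] += 1
                total += 1
        return counts / max(total, 1)


def _rfe_ranking(Xt, yt, n_trees, seed):
    """Backward elimination over a halving-size schedule, ranked by random-
    forest importance.  Returns the nested candidate feature sets, largest
    first."""
    active = np.arange(Xt.shape[1])
    candidates = [active.copy()]
    step = 0
    while len(active) > 1:
        rf = RandomForestClassifier(
            n_estimators=n_trees,
            max_features=mtry_default(len(active)),
            random_state=derive_seed(seed, "rfe-rank", step),
        ).fit(Xt[:, active], yt)
        order = np.argsort(rf.feature_importances_)[::-1]
        keep = max(1, len(active) // 2)
        active = np.sort(active[order[:keep]])
        candidates.append(active.copy())
        step += 1
    return candidates


def _inner_cv_auc(Xt, yt, cols, model, n_trees, seed, k=5):
    skf = StratifiedKFold(
        n_splits=min(k, int(np.bincount(yt).min())), shuffle=True,
        random_state=derive_seed(seed, "inner-cv"),
    )
    scores = np.empty(len(yt))
    for fold, (tr, te) in enumerate(skf.split(Xt, yt)):
        clf = make_classifier(
            model, len(cols), derive_seed(seed, "inner-model", fold), n_trees
        )
        clf.fit(Xt[np.ix_(tr, cols)], yt[tr])
        scores[te] = clf.predict_proba(Xt[np.ix_(te, cols)])[:, list(clf.classes_).index(1)]
    return roc_auc_score(yt, scores)


def _select_rfe(Xt, yt, model, n_trees, seed):
    candidates = _rfe_ranking(Xt, yt, n_trees, seed)
    best, best_auc = candidates[0], -np.inf
    for cols in candidates:  # largest→smallest; strictly better AUC to shrink
        auc = _inner_cv_auc(Xt, yt, cols, model, n_trees, seed)
        if auc > best_auc or (auc == best_auc and len(cols) < len(best)):
            best, best_auc = cols, auc
    return best


def _select_elastic_net(Xt, yt, seed):
    """Elastic-net penalized logistic regression (mixing parameter 0.5);
    penalty strength chosen by inner 5-fold CV; keeps nonzero-coefficient
    features."""
    scaler = StandardScaler().fit(Xt)
    Xs = scaler.transform(Xt)
    cv = StratifiedKFold(
        n_splits=min(5, int(np.bincount(yt).min())), shuffle=True,
        random_state=derive_seed(seed, "en-cv"),
    )
    en = LogisticRegressionCV(
        Cs=np.logspace(-3, 2, 8), cv=cv,
        l1_ratios=[0.5], solver="saga", scoring="roc_auc",
        max_iter=5000, tol=1e-3,
    ).fit(Xs, yt)
    cols = np.flatnonzero(np.abs(en.coef_.ravel()) > 1e-12)
    if cols.size == 0:  # fully shrunk: degenerate, keep everything
        cols = np.arange(Xt.shape[1])
    return cols


def nested_feature_selection(
    X,
    y,
    scheme: str = "rfe",
    model: str = "random_forest",
    n_repeats: int = 50,
    seed: int = 0,
    *,
    outer_cv: int | str = "loo",
    n_trees: int = 1000,
    oversample_in_fold: bool = True,
) -> FeatureSelectionResult:
    """Feature selection nested inside the cross-validation loop, with the
    outer loop repeated ``n_repeats`` times (distinct derived seeds); the
    pooled out-of-fold AUC of each repeat is summarized by mean ± sd.

    ``outer_cv`` is ``"loo"`` (leave-one-out, the default) or an integer k
    for stratified k-fold at reduced cost.
    """
    if scheme not in ("rfe", "elastic_net"):
        raise ValueError(f"unknown selection scheme {scheme!r}")
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    X = _as_2d(X)
    y = np.asarray(y).ravel().astype(int)
    n = len(y)
    aucs = np.empty(n_repeats)
    selected_sets: list[list[np.ndarray]] = []
    for rep in range(n_repeats):
        rseed = derive_seed(seed, scheme, "repeat", rep)
        if outer_cv == "loo":
            folds = [(np.delete(np.arange(n), i), np.array([i])) for i in range(n)]
        else:
            skf = StratifiedKFold(n_splits=int(outer_cv), shuffle=True, random_state=rseed)
            folds = list(skf.split(X, y))
        scores = np.empty(n)
        rep_sets = []
        for f, (tr, te) in enumerate(folds):
            Xt, yt = X[tr], y[tr]
            if oversample_in_fold:
                Xt, yt, _ = oversample_minority(Xt, yt, derive_seed(rseed, "os", f))
            fseed = derive_seed(rseed, "fold", f)
            if scheme == "rfe":
                cols = _select_rfe(Xt, yt, model, n_trees, fseed)
            else:
                cols = _select_elastic_net(Xt, yt, fseed)
            rep_sets.append(cols)
            clf = make_classifier(model, len(cols), derive_seed(fseed, "outer-model"), n_trees)
            clf.fit(Xt[:, cols], yt)
            scores[te] = clf.predict_proba(X[np.ix_(te, cols)])[:, list(clf.classes_).index(1)]
        aucs[rep] = roc_auc_score(y, scores)
        selected_sets.append(rep_sets)
    return FeatureSelectionResult(
        scheme=scheme,
        aucs=aucs,
        mean_auc=float(aucs.mean()),
        sd_auc=float(aucs.std(ddof=1)) if n_repeats > 1 else 0.0,
        selected_sets=selected_sets,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Model suite (the three feature configurations)


@dataclass
class SuiteResult:
    table: pd.DataFrame  # feature-set x model performance rows
    reports: dict  # (feature_set, model) -> EvaluationReport
    comparisons: list  # AUCComparison objects


def run_model_suite(
    features: pd.DataFrame,
    labels,
    clinical: pd.DataFrame | None = None,
    seed: int = 0,
    *,
    families: tuple[str, ...] = FAMILIES,
    n_boot: int = 2000,
    n_trees: int = 1000,
    oversample_in_fold: bool = True,
) -> SuiteResult:
    """Evaluate the three feature configurations: connectome-only across all
    families, connectome+clinical with the forest, and clinical-only with
    the forest; then run the pairwise bootstrap AUC comparisons among the
    connectome models and against the clinical baselines."""
    y = np.asarray(labels).ravel().astype(int)
    reports: dict[tuple[str, str], EvaluationReport] = {}
    rows = []

    def ev(name, X, model):
        rep = loocv_evaluate(
            X, y, model, oversample_in_fold, derive_seed(seed, "suite", name, model),
            n_trees=n_trees,
        )
        rows.append({"features": name, **rep.to_row()})
        rep.model = f"{name}:{model}"  # unambiguous id for comparisons
        reports[(name, model)] = rep
        return rep

    for fam in families:
        ev("connectome", features, fam)
    if clinical is not None:
        combined = pd.concat([features, clinical], axis=1)
        ev("connectome+clinical", combined, "random_forest")
        ev("clinical", clinical, "random_forest")

    comparisons = []
    fams = [f for f in families]
    for i in range(len(fams)):
        for j in range(i + 1, len(fams)):
            comparisons.append(
                compare_auc_bootstrap(
                    reports[("connectome", fams[i])], reports[("connectome", fams[j])],
                    n_boot, derive_seed(seed, "boot", fams[i], fams[j]),
                )
            )
    if clinical is not None and "random_forest" in fams:
        rf = reports[("connectome", "random_forest")]
        comparisons.append(
            compare_auc_bootstrap(
                rf, reports[("clinical", "random_forest")],
                n_boot, derive_seed(seed, "boot", "rf", "clinical"),
            )
        )
        comparisons.append(
            compare_auc_bootstrap(
                reports[("connectome+clinical", "random_forest")], rf,
                n_boot, derive_seed(seed, "boot", "combined", "rf"),
            )
        )
    return SuiteResult(table=pd.DataFrame(rows), reports=reports, comparisons=comparisons)
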