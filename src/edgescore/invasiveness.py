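"""Invasiveness classification pipeline: standardization, mRMR feature
selection, an 80:20 stratified split, eight classifiers, Shapley feature
ranking and five-fold cross-validation.

Leakage discipline: the scaler and the feature selection are fitted on
training rows only (and re-fitted inside each training fold during
cross-validation); validation rows never influence them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, clone
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.feature_selection import SelectorMixin
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import mutual_info_score, roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from ._shapley import mean_abs_ranking, shapley_values

ENDPOINTS = ("LVI", "VPI", "STAS")


# ------------------------------------------------------------ standardization

def standardize(train: pd.DataFrame, apply_to: pd.DataFrame | None = None):
    """Z-score features using training mean/SD only.

    Constant (zero-variance) training columns are dropped with a warning.
    Returns (train_z, apply_z, scaler, dropped_columns).
    """
    if train.empty:
        raise ValueError("training table is empty")
    variances = train.var(axis=0, ddof=0)
    dropped = list(variances.index[variances == 0.0])
    if dropped:
        warnings.warn(f"dropping zero-variance features: {dropped}", stacklevel=2)
    kept = [c for c in train.columns if c not in dropped]
    scaler = StandardScaler()
    train_z = pd.DataFrame(scaler.fit_transform(train[kept]), columns=kept,
                           index=train.index)
    apply_z = None
    if apply_to is not None:
        apply_z = pd.DataFrame(scaler.transform(apply_to[kept]), columns=kept,
                               index=apply_to.index)
    return train_z, apply_z, scaler, dropped


# ------------------------------------------------------------ mRMR selection

def _quantile_discretize(x: np.ndarray, n_bins: int) -> np.ndarray:
    edges = np.unique(np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1]))
    return np.searchsorted(edges, x, side="right")


@dataclass
class SelectionResult:
    """Ordered mRMR selection with per-step relevance/redundancy scores."""

    selected: list[str]
    relevance: dict[str, float]
    redundancy: list[float]  # mean redundancy of each pick at its step
    scores: list[float]      # greedy criterion value of each pick


class MRMRSelector(SelectorMixin, BaseEstimator):
    """Greedy minimum-redundancy-maximum-relevance feature selection.

    Uses mutual information on quantile-discretized features with the MID
    (difference) criterion: at each step pick the feature maximizing
    I(f; y) - mean_{s in selected} I(f; s).  Deterministic given the data;
    ties broken by column order.

    Parameters
    ----------
    k : number of features to select (default 20).
    n_bins : quantile bins for discretization (default 4, i.e. quartiles).
    """

    def __init__(self, k: int = 20, n_bins: int = 4):
        self.k = k
        self.n_bins = n_bins

    def fit(self, X, y):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        X_df = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X))
        self.feature_names_in_ = np.asarray(X_df.columns, dtype=object)
        y = np.asarray(y)
        n_feat = X_df.shape[1]
        k = self.k
        if k > n_feat:
            warnings.warn(f"k={k} exceeds {n_feat} available features; selecting all",
                          stacklevel=2)
            k = n_feat
        disc = np.column_stack([
            _quantile_discretize(X_df.iloc[:, j].to_numpy(dtype=float), self.n_bins)
            for j in range(n_feat)
        ])
        relevance = np.array([mutual_info_score(disc[:, j], y) for j in range(n_feat)])

        selected: list[int] = []
        redundancy_steps: list[float] = []
        scores: list[float] = []
        mi_cache = np.full((n_feat, n_feat), np.nan)
        remaining = list(range(n_feat))
        for _ in range(k):
            best_j, best_score, best_red = None, -np.inf, 0.0
            for j in remaining:
                if selected:
                    reds = []
                    for s in selected:
                        if np.isnan(mi_cache[j, s]):
                            mi_cache[j, s] = mi_cache[s, j] = mutual_info_score(
                                disc[:, j], disc[:, s])
                        reds.append(mi_cache[j, s])
                    red = float(np.mean(reds))
                else:
                    red = 0.0
                score = relevance[j] - red
                if score > best_score:
                    best_j, best_score, best_red = j, score, red
            selected.append(best_j)
            remaining.remove(best_j)
            redundancy_steps.append(best_red)
            scores.append(float(best_score))

        self.selected_idx_ = np.array(selected)
        self.selected_ = [str(self.feature_names_in_[j]) for j in selected]
        self.relevance_ = {str(self.feature_names_in_[j]): float(relevance[j])
                           for j in range(n_feat)}
        self.redundancy_steps_ = redundancy_steps
        self.scores_ = scores
        self.n_features_in_ = n_feat
        return self

    def _get_support_mask(self):
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[self.selected_idx_] = True
        return mask

    def result(self) -> SelectionResult:
        return SelectionResult(selected=list(self.selected_),
                               relevance=dict(self.relevance_),
                               redundancy=list(self.redundancy_steps_),
                               scores=list(self.scores_))


def mrmr_select(features: pd.DataFrame, labels, k: int = 20,
                n_bins: int = 4) -> SelectionResult:
    """Functional wrapper over :class:`MRMRSelector`."""
    return MRMRSelector(k=k, n_bins=n_bins).fit(features, labels).result()


# ------------------------------------------------------------ classifiers

def default_classifiers(seed: int = 0) -> dict[str, BaseEstimator]:
    """The eight model families, library defaults, fixed seeds."""
    from lightgbm import LGBMClassifier
    from xgboost import XGBClassifier

    return {
        "xgboost": XGBClassifier(random_state=seed, eval_metric="logloss",
                                 verbosity=0, n_jobs=1),
        "lightgbm": LGBMClassifier(random_state=seed, verbose=-1, n_jobs=1),
        "logistic_regression": LogisticRegression(max_iter=2000, random_state=seed),
        "random_forest": RandomForestClassifier(random_state=seed, n_jobs=1),
        "adaboost": AdaBoostClassifier(random_state=seed),
        "decision_tree": DecisionTreeClassifier(random_state=seed),
        "mlp": MLPClassifier(random_state=seed, max_iter=600),
        "svm": SVC(probability=True, random_state=seed),
    }


@dataclass
class ModelEval:
    """Validation performance of one classifier on one endpoint."""

    endpoint: str
    classifier: str
    auc: float
    auc_ci: tuple[float, float]
    sensitivity: float
    specificity: float
    threshold: float
    selected_features: list[str]
    model: BaseEstimator = field(repr=False, default=None)
    X_train: pd.DataFrame = field(repr=False, default=None)
    X_val: pd.DataFrame = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "endpoint": self.endpoint, "classifier": self.classifier,
            "auc": self.auc, "auc_ci_low": self.auc_ci[0],
            "auc_ci_high": self.auc_ci[1], "sensitivity": self.sensitivity,
            "specificity": self.specificity, "threshold": self.threshold,
            "selected_features": list(self.selected_features),
        }


def _bootstrap_auc_ci(y: np.ndarray, scores: np.ndarray, n_boot: int,
                      rng: np.random.Generator) -> tuple[float, float]:
    """Stratified bootstrap percentile CI for the AUC (vectorized U statistic)."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    ps = rng.choice(pos, size=(n_boot, len(pos)))
    ns = rng.choice(neg, size=(n_boot, len(neg)))
    gt = (ps[:, :, None] > ns[:, None, :]).mean(axis=(1, 2))
    eq = (ps[:, :, None] == ns[:, None, :]).mean(axis=(1, 2))
    aucs = gt + 0.5 * eq
    return float(np.quantile(aucs, 0.025)), float(np.quantile(aucs, 0.975))


def _youden_operating_point(y: np.ndarray, scores: np.ndarray):
    fpr, tpr, thr = roc_curve(y, scores)
    j = tpr - fpr
    best = int(np.argmax(j))
    return float(tpr[best]), float(1.0 - fpr[best]), float(thr[best])


def _evaluate_models(X_tr, y_tr, X_va, y_va, endpoint, selected, classifiers,
                     n_bootstrap, seed) -> list[ModelEval]:
    evals = []
    for name, proto in classifiers.items():
        model = clone(proto)
        model.fit(X_tr[selected].to_numpy(), y_tr)
        scores = model.predict_proba(X_va[selected].to_numpy())[:, 1]
        auc = float(roc_auc_score(y_va, scores))
        ci = _bootstrap_auc_ci(y_va, scores,
                               n_bootstrap, np.random.default_rng(seed + 1))
        sens, spec, thr = _youden_operating_point(y_va, scores)
        evals.append(ModelEval(endpoint=endpoint, classifier=name, auc=auc,
                               auc_ci=ci, sensitivity=sens, specificity=spec,
                               threshold=thr, selected_features=list(selected),
                               model=model, X_train=X_tr[selected],
                               X_val=X_va[selected]))
    return evals


def fit_and_evaluate(cohort: pd.DataFrame, endpoint: str,
                     feature_columns: Sequence[str] | None = None,
                     split_fraction: float = 0.2, k: int = 20,
                     classifiers: Mapping[str, BaseEstimator] | None = None,
                     n_bootstrap: int = 2000, seed: int = 0) -> list[ModelEval]:
    """Stratified 80:20 split, train-only standardization + mRMR, 8 models.

    Returns one :class:`ModelEval` per classifier, evaluated on the held-out
    validation fraction with a stratified-bootstrap AUC CI and
    sensitivity/specificity at the Youden-optimal threshold.
    """
    if endpoint not in cohort.columns:
        raise ValueError(f"endpoint {endpoint!r} not in cohort")
    if feature_columns is None:
        from .synthetic import candidate_feature_columns
        feature_columns = [c for c in candidate_feature_columns() if c in cohort.columns]
    if classifiers is None:
        classifiers = default_classifiers(seed)
    y = cohort[endpoint].to_numpy()
    X = cohort[list(feature_columns)]
    for attempt in range(10):  # re-split with next seed if a class is missing
        tr_idx, va_idx = train_test_split(np.arange(len(y)),
                                          test_size=split_fraction,
                                          stratify=y, random_state=seed + attempt)
        if len(np.unique(y[tr_idx])) == 2 and len(np.unique(y[va_idx])) == 2:
            break
    else:
        raise ValueError("could not obtain a two-class split")
    X_tr_z, X_va_z, _, _ = standardize(X.iloc[tr_idx], X.iloc[va_idx])
    selector = MRMRSelector(k=k).fit(X_tr_z, y[tr_idx])
    return _evaluate_models(X_tr_z, y[tr_idx], X_va_z, y[va_idx], endpoint,
                            selector.selected_, classifiers, n_bootstrap, seed)


def shap_rank(model_eval: ModelEval, n_background: int = 8,
              n_permutations: int = 8, max_eval: int = 64,
              seed: int = 0) -> list[tuple[str, float]]:
    """Features of a fitted model ranked by mean |Shapley attribution|.

    Attributions are computed on the validation samples against a
    background drawn from the training set; additivity (attributions sum
    to prediction minus background mean) holds exactly per sample.
    """
    if model_eval.model is None:
        raise RuntimeError("model has not been fitted")
    phi, _ = shap_attributions(model_eval, n_background, n_permutations,
                               max_eval, seed)
    return mean_abs_ranking(phi, list(model_eval.selected_features))


def shap_attributions(model_eval: ModelEval, n_background: int = 8,
                      n_permutations: int = 8, max_eval: int = 64,
                      seed: int = 0):
    """(phi, base) for validation samples; see :func:`shap_rank`."""
    rng = np.random.default_rng(seed)
    X_tr = model_eval.X_train.to_numpy()
    X_va = model_eval.X_val.to_numpy()[:max_eval]
    bg_idx = rng.choice(len(X_tr), size=min(n_background, len(X_tr)), replace=False)
    predict = lambda Z: model_eval.model.predict_proba(Z)[:, 1]
    return shapley_values(predict, X_va, X_tr[bg_idx],
                          n_permutations=n_permutations, rng=rng)


def cross_validate(cohort: pd.DataFrame, endpoint: str,
                   feature_columns: Sequence[str] | None = None,
                   folds: int = 5, k: int = 20,
                   classifiers: Mapping[str, BaseEstimator] | None = None,
                   n_bootstrap: int = 200, seed: int = 0):
    """Stratified k-fold CV; scaler and selection re-fitted per training fold.

    Returns (list of per-fold ModelEval lists, dict classifier -> mean AUC).
    """
    if feature_columns is None:
        from .synthetic import candidate_feature_columns
        feature_columns = [c for c in candidate_feature_columns() if c in cohort.columns]
    if classifiers is None:
        classifiers = default_classifiers(seed)
    y = cohort[endpoint].to_numpy()
    X = cohort[list(feature_columns)]
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    per_fold = []
    for tr_idx, va_idx in skf.split(X, y):
        if len(np.unique(y[va_idx])) < 2:
            raise ValueError("a fold lost one class; stratification failed")
        X_tr_z, X_va_z, _, _ = standardize(X.iloc[tr_idx], X.iloc[va_idx])
        selector = MRMRSelector(k=k).fit(X_tr_z, y[tr_idx])
        per_fold.append(_evaluate_models(X_tr_z, y[tr_idx], X_va_z, y[va_idx],
                                         endpoint, selector.selected_,
                                         classifiers, n_bootstrap, seed))
    mean_auc = {name: float(np.mean([f[i].auc for f in per_fold]))
                for i, name in enumerate(classifiers)}
    return per_fold, mean_auc
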