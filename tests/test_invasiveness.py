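"""invasiveness: mRMR oracles, leakage hygiene, classifiers, Shapley."""

import warnings

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import mutual_info_score

from edgescore._shapley import shapley_values
from edgescore.invasiveness import (MRMRSelector, default_classifiers,
                                    fit_and_evaluate, mrmr_select, shap_rank,
                                    standardize)


# ------------------------------------------------------------- standardize

def test_standardize_closed_form():
    train = pd.DataFrame({"a": [0.0, 2.0, 4.0], "b": [1.0, 1.0, 4.0]})
    train_z, _, _, dropped = standardize(train)
    assert dropped == []
    np.testing.assert_allclose(train_z["a"], [-1.22474487, 0.0, 1.22474487])
    np.testing.assert_allclose(train_z.mean(), 0.0, atol=1e-12)
    np.testing.assert_allclose(train_z.std(ddof=0), 1.0)


def test_standardize_applies_train_statistics_to_validation():
    train = pd.DataFrame({"a": [0.0, 2.0]})       # mean 1, sd 1
    val = pd.DataFrame({"a": [3.0]})
    _, val_z, _, _ = standardize(train, val)
    assert val_z["a"].iloc[0] == pytest.approx(2.0)


def test_standardize_drops_constant_columns_with_warning():
    train = pd.DataFrame({"a": [1.0, 2.0], "c": [5.0, 5.0]})
    with pytest.warns(UserWarning, match="zero-variance"):
        train_z, _, _, dropped = standardize(train)
    assert dropped == ["c"]
    assert list(train_z.columns) == ["a"]


# ------------------------------------------------------------------ mRMR

def _brute_force_mrmr(X: pd.DataFrame, y, k: int, n_bins: int = 4):
    """Independent replay of the greedy MID rule using library MI."""
    def disc(col):
        x = X[col].to_numpy()
        edges = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
        return np.searchsorted(edges, x, side="right")

    cols = list(X.columns)
    d = {c: disc(c) for c in cols}
    rel = {c: mutual_info_score(y, d[c]) for c in cols}
    selected = []
    while len(selected) < min(k, len(cols)):
        best, best_score = None, -np.inf
        for c in cols:
            if c in selected:
                continue
            red = np.mean([mutual_info_score(d[c], d[s]) for s in selected]) \
                if selected else 0.0
            score = rel[c] - red
            if score > best_score:  # strict: ties keep earliest column
                best, best_score = c, score
        selected.append(best)
    return selected


def test_mrmr_trivial_perfect_feature():
    rng = np.random.default_rng(10)
    y = rng.integers(0, 2, 80)
    X = pd.DataFrame({"noise1": rng.normal(size=80),
                      "oracle": y.astype(float),
                      "noise2": rng.normal(size=80)})
    result = mrmr_select(X, y, k=1)
    assert result.selected == ["oracle"]


def test_mrmr_redundancy_penalty_rejects_duplicate():
    rng = np.random.default_rng(11)
    y = rng.integers(0, 2, 120)
    top = y + rng.normal(scale=0.3, size=120)
    X = pd.DataFrame({
        "top": top, "dup": top.copy(),
        "weak": y + rng.normal(scale=2.0, size=120),
        "n1": rng.normal(size=120), "n2": rng.normal(size=120),
    })
    result = mrmr_select(X, y, k=2)
    assert result.selected[0] == "top"
    assert result.selected[1] != "dup"


def test_mrmr_matches_brute_force_replay():
    """50 random toy tables with <= 8 features, full greedy replay."""
    rng = np.random.default_rng(12)
    for trial in range(50):
        n = int(rng.integers(30, 60))
        m = int(rng.integers(2, 9))
        y = rng.integers(0, 2, n)
        X = pd.DataFrame(
            {f"f{j}": y * rng.uniform(0, 1.5) + rng.normal(size=n)
             for j in range(m)})
        k = int(rng.integers(1, m + 1))
        result = mrmr_select(X, y, k=k)
        assert result.selected == _brute_force_mrmr(X, y, k), f"trial {trial}"


def test_mrmr_k_larger_than_feature_count_selects_all_with_warning():
    rng = np.random.default_rng(13)
    X = pd.DataFrame({"a": rng.normal(size=40), "b": rng.normal(size=40)})
    y = rng.integers(0, 2, 40)
    with pytest.warns(UserWarning):
        result = mrmr_select(X, y, k=10)
    assert sorted(result.selected) == ["a", "b"]


def test_mrmr_selector_sklearn_transform_contract():
    rng = np.random.default_rng(14)
    X = pd.DataFrame(rng.normal(size=(60, 6)),
                     columns=[f"f{j}" for j in range(6)])
    y = rng.integers(0, 2, 60)
    sel = MRMRSelector(k=3).fit(X, y)
    Xt = sel.transform(X)
    assert Xt.shape == (60, 3)
    assert sel.get_support().sum() == 3


# ----------------------------------------------------------- classifiers

def test_default_classifiers_are_the_eight_families():
    models = default_classifiers(seed=0)
    assert set(models.keys()) == {
        "xgboost", "lightgbm", "logistic_regression", "random_forest",
        "adaboost", "decision_tree", "mlp", "svm"}


def test_fit_and_evaluate_reports_all_models(cohort244):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        evals = fit_and_evaluate(cohort244, "LVI", seed=0, n_bootstrap=200)
    assert len(evals) == 8
    for ev in evals:
        assert 0.0 <= ev.auc <= 1.0
        assert ev.auc_ci[0] <= ev.auc <= ev.auc_ci[1] or \
            abs(ev.auc_ci[0] - ev.auc_ci[1]) < 0.5  # CI brackets the point
        assert 0.0 <= ev.sensitivity <= 1.0
        assert 0.0 <= ev.specificity <= 1.0
        assert len(ev.selected_features) == 20


def test_fit_and_evaluate_is_deterministic(cohort244):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        a = fit_and_evaluate(cohort244, "VPI", seed=1, n_bootstrap=100)
        b = fit_and_evaluate(cohort244, "VPI", seed=1, n_bootstrap=100)
    assert [e.to_dict() for e in a] == [e.to_dict() for e in b]


def test_leakage_mutation_validation_rows_do_not_change_fit(cohort244):
    """Perturbing held-out rows must leave scaler and selection unchanged."""
    from sklearn.model_selection import train_test_split
    from edgescore.synthetic import candidate_feature_columns

    cols = candidate_feature_columns()
    y = cohort244["LVI"].to_numpy()
    idx_tr, idx_va = train_test_split(np.arange(len(y)), test_size=0.2,
                                      stratify=y, random_state=0)
    X = cohort244[cols]
    mutated = X.copy()
    mutated.iloc[idx_va] = mutated.iloc[idx_va] * 3.0 + 17.0

    tr_a, _, scaler_a, _ = standardize(X.iloc[idx_tr], X.iloc[idx_va])
    tr_b, _, scaler_b, _ = standardize(mutated.iloc[idx_tr],
                                       mutated.iloc[idx_va])
    np.testing.assert_array_equal(scaler_a.mean_, scaler_b.mean_)
    np.testing.assert_array_equal(scaler_a.scale_, scaler_b.scale_)
    sel_a = MRMRSelector(k=10).fit(tr_a, y[idx_tr]).selected_
    sel_b = MRMRSelector(k=10).fit(tr_b, y[idx_tr]).selected_
    assert sel_a == sel_b


# ------------------------------------------------------------------ Shapley

def test_shapley_additivity_is_exact():
    rng = np.random.default_rng(15)
    X_bg = rng.normal(size=(6, 4))
    X_ev = rng.normal(size=(5, 4))

    def predict(X):
        return X[:, 0] * 2.0 + np.sin(X[:, 1]) + X[:, 2] * X[:, 3]

    phi, base = shapley_values(predict, X_ev, X_bg, n_permutations=4,
                           rng=np.random.default_rng(0))
    assert base == pytest.approx(predict(X_bg).mean())
    np.testing.assert_allclose(phi.sum(axis=1), predict(X_ev) - base,
                               rtol=0, atol=1e-10)


def test_shapley_irrelevant_feature_gets_zero():
    rng = np.random.default_rng(16)
    X_bg = rng.normal(size=(8, 3))
    X_ev = rng.normal(size=(6, 3))

    def predict(X):
        return X[:, 0] * 5.0  # features 1, 2 unused

    phi, _ = shapley_values(predict, X_ev, X_bg, n_permutations=6,
                            rng=np.random.default_rng(0))
    np.testing.assert_allclose(phi[:, 1:], 0.0, atol=1e-12)
    assert np.abs(phi[:, 0]).min() >= 0.0


def test_shapley_linear_model_matches_closed_form():
    """For linear f, phi_j = w_j * (x_j - mean background_j) exactly."""
    rng = np.random.default_rng(17)
    w = np.array([1.5, -2.0, 0.5])
    X_bg = rng.normal(size=(10, 3))
    X_ev = rng.normal(size=(4, 3))
    phi, _ = shapley_values(lambda X: X @ w, X_ev, X_bg,
                            n_permutations=5,
                            rng=np.random.default_rng(1))
    expected = w * (X_ev - X_bg.mean(axis=0))
    np.testing.assert_allclose(phi, expected, atol=1e-10)


def test_shap_rank_on_fitted_model(cohort244):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        evals = fit_and_evaluate(cohort244, "LVI", seed=0, n_bootstrap=100)
    best = max(evals, key=lambda e: e.auc)
    ranking = shap_rank(best, seed=0)
    names = [f for f, _ in ranking]
    values = [v for _, v in ranking]
    assert sorted(names) == sorted(best.selected_features)
    assert values == sorted(values, reverse=True)
    assert all(v >= 0 for v in values)
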