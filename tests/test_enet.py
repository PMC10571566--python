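"""Elastic-net logistic model, splitting, ROC/cutpoint and CI arithmetic."""

import warnings

import numpy as np
import pandas as pd
import pytest

from blcasig.enet import (
    ElasticNetLogistic,
    accuracy_ci,
    classify,
    cv_lambda,
    fit_enet,
    optimal_cutpoint,
    predict_response,
    roc_auc,
    stratified_split,
)
from blcasig.exceptions import DomainError


# -- stratified splitting --------------------------------------------------

def test_split_preserves_class_proportions():
    labels = pd.Series([1] * 10 + [0] * 90, index=[f"s{i}" for i in range(100)])
    sp = stratified_split(labels, 0.7, seed=0)
    train = labels[list(sp.train_ids)]
    assert len(sp.train_ids) == 70
    assert int(train.sum()) == 7          # 10 positives -> 7 in train


def test_split_of_102_leaves_31_test_samples():
    labels = pd.Series([0, 1] * 51, index=[f"s{i}" for i in range(102)])
    sp = stratified_split(labels, 0.7, seed=0)
    assert len(sp.test_ids) == 31


def test_split_is_deterministic_and_partitions():
    labels = pd.Series([0] * 20 + [1] * 15, index=[f"s{i}" for i in range(35)])
    a = stratified_split(labels, 0.7, seed=5)
    b = stratified_split(labels, 0.7, seed=5)
    assert a == b
    assert set(a.train_ids) | set(a.test_ids) == set(labels.index)
    assert not set(a.train_ids) & set(a.test_ids)


def test_split_ratio_one_warns_of_empty_test():
    labels = pd.Series([0, 0, 1, 1])
    with pytest.warns(UserWarning):
        sp = stratified_split(labels, 1.0, seed=0)
    assert sp.test_ids == ()


def test_split_single_class_rejected():
    with pytest.raises(DomainError):
        stratified_split(pd.Series([1, 1, 1]), 0.7, seed=0)


# -- prediction arithmetic -------------------------------------------------

def _manual_fit(genes, coef, intercept):
    m = ElasticNetLogistic(lambda_=1.0)
    m.feature_names_in_ = np.asarray(genes, dtype=object)
    m.coef_ = np.asarray(coef, dtype=float)
    m.intercept_ = float(intercept)
    m.classes_ = np.array([0, 1])
    return m


def test_predict_response_closed_forms():
    null = _manual_fit(["g1"], [0.0], 0.0)
    assert predict_response(null, pd.Series({"g1": 5.0})) == pytest.approx(0.5)
    shifted = _manual_fit(["g1"], [0.0], np.log(3))
    assert predict_response(shifted, pd.Series({"g1": 0.0})) == pytest.approx(0.75)
    saturated = _manual_fit(["g1"], [20.0], 0.0)
    assert predict_response(saturated, pd.Series({"g1": 1.0})) > 0.999


def test_predict_response_missing_gene_rejected():
    m = _manual_fit(["g1", "g2"], [1.0, 1.0], 0.0)
    with pytest.raises(DomainError, match="g2"):
        predict_response(m, pd.Series({"g1": 1.0}))


def test_classify_boundary_is_strict():
    assert classify(0.6) == 1
    assert classify(0.5) == 0
    assert classify(0.96, boundary=0.9535) == 1
    with pytest.raises(DomainError):
        classify(1.2)


# -- elastic-net fitting ---------------------------------------------------

def _signal_data(n=80, p=10, seed=0):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.normal(size=(n, p)),
                     columns=[f"g{i}" for i in range(p)])
    eta = 2.0 * X["g0"] - 1.5 * X["g1"]
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    return X, y


def test_huge_lambda_gives_null_model():
    X, y = _signal_data()
    fit = fit_enet(X, y, lambda_=1e6)
    assert np.all(fit.coef_ == 0)
    prev = y.mean()
    assert fit.intercept_ == pytest.approx(np.log(prev / (1 - prev)), abs=0.05)


def test_zero_lambda_sign_matches_separation():
    X = pd.DataFrame({"g0": [-2, -1.5, -1, 1, 1.5, 2.0]})
    y = np.array([0, 0, 0, 1, 1, 1])
    fit = fit_enet(X, y, lambda_=0.0)
    assert fit.coef_[0] > 0


def test_small_lambda_matches_unpenalized_mle_oracle():
    # IRLS oracle via statsmodels on the same data
    import statsmodels.api as sm

    X, y = _signal_data(n=200, p=4, seed=3)
    fit = fit_enet(X, y, lambda_=1e-6)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        oracle = sm.Logit(y, sm.add_constant(X.to_numpy())).fit(disp=0)
    assert fit.intercept_ == pytest.approx(oracle.params[0], rel=0.05, abs=0.02)
    for j in range(4):
        assert fit.coef_[j] == pytest.approx(oracle.params[j + 1], rel=0.05,
                                             abs=0.02)


def test_coefficients_reported_on_input_scale():
    # scaling a predictor by c divides its coefficient by ~c
    X, y = _signal_data(n=150, p=3, seed=5)
    fit1 = fit_enet(X, y, lambda_=0.01)
    X2 = X.copy()
    X2["g0"] = X2["g0"] * 10
    fit2 = fit_enet(X2, y, lambda_=0.01)
    assert fit2.coef_[0] == pytest.approx(fit1.coef_[0] / 10, rel=0.05, abs=1e-4)


def test_nonfinite_input_rejected():
    X, y = _signal_data(n=20, p=2)
    X.iloc[0, 0] = np.inf
    with pytest.raises(DomainError):
        fit_enet(X, y, lambda_=0.1)


def test_cv_pure_noise_selects_null_model():
    rng = np.random.default_rng(7)
    X = pd.DataFrame(rng.normal(size=(60, 15)),
                     columns=[f"g{i}" for i in range(15)])
    y = rng.integers(0, 2, size=60)
    model = ElasticNetLogistic(cv=5, random_state=7).fit(X, y)
    assert len(model.nonzero_genes_) <= 2
    assert model.lambda_min_ >= model.lambda_path_[5]   # near the grid top


def test_cv_keeps_perfect_predictor():
    rng = np.random.default_rng(1)
    X = pd.DataFrame(rng.normal(size=(80, 10)),
                     columns=[f"g{i}" for i in range(10)])
    y = (X["g3"] > 0).astype(int).to_numpy()
    model = ElasticNetLogistic(cv=5, random_state=1).fit(X, y)
    assert "g3" in model.nonzero_genes_


def test_cv_grid_of_length_one():
    X, y = _signal_data(n=60, p=3, seed=2)
    lam, grid, _ = cv_lambda(X, y, k=5, seed=2, n_lambdas=1)
    assert grid.size == 1 and lam == pytest.approx(grid[0])


def test_cv_reduces_folds_with_warning():
    X, y = _signal_data(n=30, p=3, seed=4)
    y = np.array([1] * 5 + [0] * 25)
    with pytest.warns(UserWarning, match="reducing CV folds"):
        ElasticNetLogistic(cv=10, random_state=0).fit(X, y)


def test_cv_model_beats_null_on_signal():
    X, y = _signal_data(n=120, p=8, seed=6)
    tr, te = np.arange(84), np.arange(84, 120)
    model = ElasticNetLogistic(cv=5, random_state=6).fit(X.iloc[tr], y[tr])
    null = fit_enet(X.iloc[tr], y[tr], lambda_=1e6)

    def dev(m):
        p = np.clip(m.predict_proba(X.iloc[te])[:, 1], 1e-12, 1 - 1e-12)
        return -2 * np.mean(y[te] * np.log(p) + (1 - y[te]) * np.log(1 - p))

    assert dev(model) <= dev(null)


def test_fit_is_deterministic():
    X, y = _signal_data(n=60, p=6, seed=8)
    a = ElasticNetLogistic(cv=5, random_state=3).fit(X, y)
    b = ElasticNetLogistic(cv=5, random_state=3).fit(X, y)
    assert a.lambda_min_ == b.lambda_min_
    assert np.array_equal(a.coef_, b.coef_)


# -- ROC / AUC -------------------------------------------------------------

def test_auc_all_pairs_small_case():
    # pos {0.9, 0.4}, neg {0.7, 0.1}: 3 of 4 pairs correctly ordered
    res = roc_auc([0.9, 0.4, 0.7, 0.1], [1, 1, 0, 0])
    assert res.auc == pytest.approx(0.75)


def test_auc_perfect_separation():
    assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]).auc == 1.0


def test_auc_ties_count_half():
    assert roc_auc([0.5, 0.5], [1, 0]).auc == pytest.approx(0.5)


def test_auc_matches_all_pairs_oracle():
    rng = np.random.default_rng(2)
    scores = np.round(rng.random(40), 2)   # induce ties
    labels = rng.integers(0, 2, 40)
    if labels.sum() in (0, 40):
        labels[0] = 1 - labels[0]
    pairs = [(s1, s0) for s1 in scores[labels == 1] for s0 in scores[labels == 0]]
    oracle = np.mean([1.0 if a > b else 0.5 if a == b else 0.0
                      for a, b in pairs])
    assert roc_auc(scores, labels).auc == pytest.approx(oracle)


def test_auc_invariant_under_monotone_transform():
    rng = np.random.default_rng(3)
    scores = rng.random(30)
    labels = rng.integers(0, 2, 30)
    labels[:2] = [0, 1]
    a = roc_auc(scores, labels).auc
    b = roc_auc(np.exp(5 * scores), labels).auc
    assert a == pytest.approx(b)


def test_auc_single_class_rejected():
    with pytest.raises(DomainError):
        roc_auc([0.1, 0.9], [1, 1])


# -- cutpoint --------------------------------------------------------------

def test_cutpoint_midpoint_for_separated_pair():
    cut, acc = optimal_cutpoint([0.1, 0.9], [0, 1])
    assert cut == pytest.approx(0.5)
    assert acc == 1.0


def test_cutpoint_constant_scores_gives_majority_accuracy():
    cut, acc = optimal_cutpoint([0.4] * 5, [1, 1, 1, 0, 0])
    assert acc == pytest.approx(0.6)


def test_cutpoint_dominates_fixed_boundary():
    rng = np.random.default_rng(11)
    scores = rng.random(50)
    labels = rng.integers(0, 2, 50)
    labels[:2] = [0, 1]
    _, acc = optimal_cutpoint(scores, labels)
    fixed = np.mean((scores > 0.5).astype(int) == labels)
    assert acc >= fixed


def test_cutpoint_matches_exhaustive_scan_oracle():
    rng = np.random.default_rng(12)
    scores = np.round(rng.random(25), 2)
    labels = rng.integers(0, 2, 25)
    labels[:2] = [0, 1]
    cut, acc = optimal_cutpoint(scores, labels)
    best = max(np.mean((scores >= c).astype(int) == labels)
               for c in np.r_[-np.inf, np.unique(scores), np.inf])
    assert acc == pytest.approx(best)


# -- accuracy CI -----------------------------------------------------------

def test_accuracy_ci_reproduces_printed_intervals():
    point, lo, hi = accuracy_ci(24, 31)
    assert round(point * 100, 2) == 77.42
    assert round(lo, 3) == 0.589 and round(hi, 4) == 0.9041
    point, lo, hi = accuracy_ci(35, 38)
    assert round(point * 100, 2) == 92.11
    assert round(lo, 4) == 0.7862 and round(hi, 4) == 0.9834


def test_accuracy_ci_degenerate_counts():
    point, lo, hi = accuracy_ci(0, 10)
    assert point == 0.0 and lo == 0.0 and hi < 0.5
    point, lo, hi = accuracy_ci(10, 10)
    assert hi == 1.0


def test_accuracy_ci_brackets_point_and_shrinks():
    for total in (10, 40, 160):
        point, lo, hi = accuracy_ci(int(0.8 * total), total)
        assert lo <= point <= hi
    widths = [accuracy_ci(int(0.8 * t), t)[2] - accuracy_ci(int(0.8 * t), t)[1]
              for t in (10, 40, 160)]
    assert widths[0] > widths[1] > widths[2]


def test_accuracy_ci_invalid_counts_rejected():
    with pytest.raises(DomainError):
        accuracy_ci(5, 4)
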