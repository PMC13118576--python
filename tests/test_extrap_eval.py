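"""Rolling-origin folds, Spearman, AD indicators, shift diagnostics."""

import numpy as np
import pandas as pd
import pytest

from tabletpred import extrap_eval as ee


# ---------------------------------------------------------------------------
# rolling-origin folds


def test_fold_layout_for_n_200():
    plan = ee.rolling_origin_folds(200)
    assert len(plan.folds) == 5
    f0, f4 = plan.folds[0], plan.folds[4]
    assert (len(f0.train), len(f0.dev), len(f0.test)) == (100, 40, 20)
    assert (f0.train[0], f0.train[-1]) == (0, 99)
    assert (f0.dev[0], f0.dev[-1]) == (100, 139)
    assert (f0.test[0], f0.test[-1]) == (140, 159)
    assert (len(f4.train), len(f4.dev), len(f4.test)) == (140, 40, 20)
    assert f4.test[-1] == 199


def test_train_windows_are_nested_and_causal():
    plan = ee.rolling_origin_folds(97)
    for a, b in zip(plan.folds[:-1], plan.folds[1:]):
        assert set(a.train) <= set(b.train)
    for fold in plan.folds:
        assert fold.train.max() < fold.dev.min() <= fold.dev.max() < fold.test.min()


def test_too_few_rows_is_an_error():
    with pytest.raises(ValueError):
        ee.rolling_origin_folds(12)


# ---------------------------------------------------------------------------
# Spearman


def test_spearman_perfect_and_reversed_rankings():
    y = np.array([3.0, 1.0, 4.0, 1.5, 5.0])
    assert ee.spearman_rho(y, y) == pytest.approx(1.0)
    assert ee.spearman_rho(y, -y) == pytest.approx(-1.0)


def test_spearman_matches_rank_pearson_and_no_tie_formula(rng):
    # tie-free fixture: closed-form 1 - 6 sum d^2 / (n(n^2-1))
    y = rng.permutation(20).astype(float)
    yhat = y + rng.normal(scale=3.0, size=20)
    while len(np.unique(yhat)) < 20:  # ensure tie-free
        yhat = y + rng.normal(scale=3.0, size=20)
    from scipy.stats import rankdata

    d = rankdata(y) - rankdata(yhat)
    closed = 1 - 6 * (d**2).sum() / (20 * (20**2 - 1))
    assert ee.spearman_rho(y, yhat) == pytest.approx(closed, abs=1e-12)

    # tied fixture: Pearson of average ranks
    y2 = np.array([1.0, 1.0, 2.0, 3.0, 3.0, 4.0])
    yhat2 = np.array([2.0, 1.0, 2.0, 5.0, 4.0, 4.0])
    oracle = np.corrcoef(rankdata(y2), rankdata(yhat2))[0, 1]
    assert ee.spearman_rho(y2, yhat2) == pytest.approx(oracle, abs=1e-12)


# ---------------------------------------------------------------------------
# AD indicators


def test_leverage_trace_equals_rank_and_selfquery_consistency(rng):
    X = rng.normal(size=(40, 5))
    res = ee.leverage_ad(X, X[:7])
    Xt = np.column_stack([np.ones(40), X])
    assert res.fit_values.sum() == pytest.approx(np.linalg.matrix_rank(Xt))
    assert np.allclose(res.query_values, res.fit_values[:7])


def test_leverage_percentile_coverage_is_about_95(rng):
    X = rng.normal(size=(600, 8))
    res = ee.leverage_ad(X, X)
    assert res.fit_coverage == pytest.approx(95.0, abs=1.0)


def test_mahalanobis_center_is_in_domain_and_rotation_invariant(rng):
    X = rng.normal(size=(200, 4)) * np.array([3.0, 2.0, 1.0, 0.5])
    center = X.mean(axis=0, keepdims=True)
    res = ee.mahalanobis_ad(X, center)
    assert res.query_values[0] == pytest.approx(0.0, abs=1e-12)
    assert res.query_in_domain[0]

    Q, _ = np.linalg.qr(rng.normal(size=(4, 4)))
    res_rot = ee.mahalanobis_ad(X @ Q, center @ Q)
    assert res_rot.query_values[0] == pytest.approx(0.0, abs=1e-10)
    q = rng.normal(size=(10, 4))
    a = ee.mahalanobis_ad(X, q).query_values
    b = ee.mahalanobis_ad(X @ Q, q @ Q).query_values
    assert np.allclose(a, b, atol=1e-8)


def test_mahalanobis_chi_square_calibration(rng):
    X = rng.normal(size=(4000, 5))
    Q = rng.normal(size=(4000, 5))
    res = ee.mahalanobis_ad(X, Q)
    assert res.query_coverage == pytest.approx(97.5, abs=1.5)


def test_knn_distance_of_a_duplicated_fitting_row_is_zero(rng):
    X = rng.normal(size=(30, 3))
    res = ee.knn_ad(X, X[[4]], k=1)
    assert res.query_values[0] == pytest.approx(0.0, abs=1e-12)


def test_knn_matches_brute_force_all_pairs_oracle(rng):
    X = rng.normal(size=(25, 4))
    Q = rng.normal(size=(6, 4))
    k = 5
    res = ee.knn_ad(X, Q, k=k)
    for i in range(len(Q)):
        d = np.sort(np.linalg.norm(X - Q[i], axis=1))[:k]
        assert res.query_values[i] == pytest.approx(d.mean(), rel=1e-10)
    for i in range(len(X)):
        d = np.linalg.norm(X - X[i], axis=1)
        d = np.sort(d)[1 : k + 1]  # exclude self
        assert res.fit_values[i] == pytest.approx(d.mean(), rel=1e-10)


def test_range_ok_is_inclusive_at_the_boundaries(rng):
    X = rng.normal(size=(50, 3))
    res = ee.range_ok(X, X)
    assert res.fit_coverage == 100.0
    at_min = X.min(axis=0, keepdims=True)
    beyond = X.max(axis=0, keepdims=True) + 1e-6
    res2 = ee.range_ok(X, np.vstack([at_min, beyond]))
    assert res2.query_in_domain[0] and not res2.query_in_domain[1]


def test_ad_computations_are_pure_functions(rng):
    X, Q = rng.normal(size=(60, 4)), rng.normal(size=(8, 4))
    a = ee.ad_report(X, Q)
    b = ee.ad_report(X, Q)
    for ind in ee.AD_INDICATORS:
        assert np.array_equal(a[ind].query_values, b[ind].query_values)
        assert a[ind].threshold == b[ind].threshold


# ---------------------------------------------------------------------------
# JSD / PSI


def test_jsd_identical_samples_is_zero(rng):
    x = rng.normal(size=300)
    assert ee.jsd_feature(x, x.copy()) == pytest.approx(0.0, abs=1e-4)


def test_jsd_disjoint_supports_approaches_one(rng):
    a = rng.normal(0.0, 0.1, size=500)
    b = rng.normal(100.0, 0.1, size=500)
    assert ee.jsd_feature(a, b) == pytest.approx(1.0, abs=1e-3)


def test_jsd_is_symmetric(rng):
    a, b = rng.normal(size=200), rng.normal(1.0, 2.0, size=250)
    assert ee.jsd_feature(a, b) == pytest.approx(ee.jsd_feature(b, a), abs=1e-12)


def test_constant_feature_has_zero_jsd():
    assert ee.jsd_feature(np.ones(50), np.ones(30)) == 0.0


def test_jsd_matches_hand_evaluated_kl_terms():
    # two-bin discrete fixture: 30/10 vs 10/30 -> p=(.75,.25), q=(.25,.75)
    a = np.concatenate([np.zeros(30), np.ones(10)])
    b = np.concatenate([np.zeros(10), np.ones(30)])
    p, q = np.array([0.75, 0.25]), np.array([0.25, 0.75])
    m = (p + q) / 2
    expected = 0.5 * (p * np.log2(p / m)).sum() + 0.5 * (q * np.log2(q / m)).sum()
    assert ee.jsd_feature(a, b, n_bins=2) == pytest.approx(expected, abs=1e-4)


def test_jsd_shift_reports_fold_averaged_per_feature_values(rng):
    n = 100
    X = pd.DataFrame({"stable": rng.normal(size=n), "drifting": np.linspace(0, 5, n)})
    plan = ee.rolling_origin_folds(n)
    rep = ee.jsd_shift(X, plan)
    assert rep.jsd["drifting"] > rep.jsd["stable"]
    assert rep.top(1).index[0] == "drifting"
    assert (rep.jsd >= 0).all() and (rep.jsd <= 1).all()
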