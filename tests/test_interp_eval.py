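"""Split plans, metrics and the effect-size statistics."""

import itertools

import numpy as np
import pytest
from scipy import stats

from tabletpred import interp_eval as ie


# ---------------------------------------------------------------------------
# splits


@pytest.mark.parametrize("n,sizes", [(100, (50, 30, 20)), (10, (5, 3, 2)), (101, (50, 30, 21))])
def test_split_sizes_follow_the_5_3_2_rule(n, sizes):
    plan = ie.make_split(n, seed=0)
    assert (len(plan.train), len(plan.dev), len(plan.test)) == sizes
    combined = np.sort(np.concatenate([plan.train, plan.dev, plan.test]))
    assert np.array_equal(combined, np.arange(n))


def test_split_is_deterministic_in_seed():
    a, b = ie.make_split(57, 4), ie.make_split(57, 4)
    assert np.array_equal(a.train, b.train) and np.array_equal(a.test, b.test)
    c = ie.make_split(57, 5)
    assert not np.array_equal(a.train, c.train)


# ---------------------------------------------------------------------------
# metrics


def test_perfect_prediction_gives_r2_one_rmse_zero():
    y = np.array([1.0, 2.0, 5.0])
    assert ie.r2_rmse(y, y) == (1.0, 0.0)


def test_mean_prediction_gives_r2_zero_and_population_sd():
    y = np.array([1.0, 2.0, 3.0, 6.0])
    r2, rmse = ie.r2_rmse(y, np.full(4, y.mean()))
    assert r2 == pytest.approx(0.0)
    assert rmse == pytest.approx(np.std(y))


def test_hand_computed_r2_rmse_example():
    r2, rmse = ie.r2_rmse([1, 2, 3], [1, 2, 4])
    assert rmse == pytest.approx(np.sqrt(1 / 3))
    assert r2 == pytest.approx(0.5)


def test_constant_y_r2_is_undefined_but_rmse_is_returned():
    with pytest.warns(UserWarning, match="constant y"):
        r2, rmse = ie.r2_rmse([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])
    assert np.isnan(r2)
    assert rmse == pytest.approx(np.sqrt(2 / 3))


# ---------------------------------------------------------------------------
# paired improvements and bootstrap


def test_paired_improvements_match_by_model_and_seed():
    mp = {("ET", 0): 10.0, ("ET", 1): 12.0}
    aug = {("ET", 0): 9.0, ("ET", 1): 12.0}
    assert ie.paired_improvements(mp, aug) == [1.0, 0.0]


def test_unpaired_results_are_excluded_with_warning():
    mp = {("ET", 0): 10.0, ("ET", 1): 12.0}
    aug = {("ET", 0): 9.0}
    with pytest.warns(UserWarning, match="unpaired"):
        d = ie.paired_improvements(mp, aug)
    assert d == [1.0]


def test_degenerate_bootstrap_ci_collapses_to_the_constant():
    mean, lo, hi = ie.bootstrap_ci([2.5] * 10, B=100, seed=0)
    assert mean == lo == hi == 2.5


def test_single_resample_bootstrap_ci_is_that_mean():
    mean, lo, hi = ie.bootstrap_ci([1.0, 2.0, 6.0], B=1, seed=3)
    assert lo == hi  # both percentiles of a single resampled mean


def test_bootstrap_ci_has_nominal_coverage_on_gaussian_lists():
    rng = np.random.default_rng(0)
    hits = 0
    n_sim = 400
    for s in range(n_sim):
        d = rng.normal(0.3, 1.0, size=50)
        _, lo, hi = ie.bootstrap_ci(d, B=1000, seed=s)
        hits += lo <= 0.3 <= hi
    assert 0.91 <= hits / n_sim <= 0.975


def test_bootstrap_ci_width_shrinks_with_sample_size():
    rng = np.random.default_rng(1)
    widths = []
    for n in (20, 80, 320):
        d = rng.normal(0.0, 1.0, size=n)
        d = (d - d.mean()) / d.std()  # fix the sample sd so widths ~ 1/sqrt(n)
        _, lo, hi = ie.bootstrap_ci(d, B=4000, seed=n)
        widths.append(hi - lo)
    assert widths[0] > widths[1] > widths[2]
    assert widths[0] / widths[2] == pytest.approx(4.0, rel=0.15)


# ---------------------------------------------------------------------------
# Wilcoxon


def test_wilcoxon_all_positive_small_sample():
    assert ie.wilcoxon_signed_rank([1, 2, 3, 4, 5]) == pytest.approx(0.0625)


def test_wilcoxon_sign_symmetric_list_has_p_one():
    assert ie.wilcoxon_signed_rank([-3, -2, -1, 1, 2, 3]) == pytest.approx(1.0)


def test_wilcoxon_all_zero_is_degenerate():
    with pytest.warns(UserWarning, match="degenerate"):
        assert ie.wilcoxon_signed_rank([0.0, 0.0]) == 1.0


def _enumeration_p(d):
    """Exact two-sided signed-rank p by full 2^n enumeration."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in itertools.product([0, 1], repeat=len(d)):
        ws.append(sum(r for s, r in zip(signs, ranks) if s))
    ws = np.array(ws)
    p = 2 * min((ws <= w_obs).mean(), (ws >= w_obs).mean())
    return min(p, 1.0)


@pytest.mark.parametrize("n,seed", [(5, 0), (8, 1), (12, 2)])
def test_wilcoxon_exact_p_matches_full_enumeration(n, seed):
    d = np.random.default_rng(seed).normal(0.2, 1.0, size=n)
    assert ie.wilcoxon_signed_rank(d) == pytest.approx(_enumeration_p(d), abs=1e-12)


# ---------------------------------------------------------------------------
# agreement


def test_clopper_pearson_closed_form_boundaries():
    lo, hi = ie.clopper_pearson(0, 10)
    assert lo == 0.0
    assert hi == pytest.approx(1 - 0.025 ** (1 / 10))
    lo, hi = ie.clopper_pearson(10, 10)
    assert hi == 1.0
    assert lo == pytest.approx(0.025 ** (1 / 10))


def test_clopper_pearson_matches_statsmodels_oracle():
    from statsmodels.stats.proportion import proportion_confint

    for k, n in [(50, 60), (3, 17), (12, 12)]:
        lo, hi = ie.clopper_pearson(k, n)
        slo, shi = proportion_confint(k, n, alpha=0.05, method="beta")
        assert lo == pytest.approx(slo, abs=1e-12)
        assert hi == pytest.approx(shi, abs=1e-12)


def test_directional_agreement_counts_matching_signs():
    d_by = {
        "a": {0: 1.0, 1: 2.0},  # disc mean + / valid mean +
        "b": {0: -1.0, 1: 3.0},  # disc - / valid +
        "c": {0: -1.0, 1: -2.0},
    }
    res = ie.directional_agreement(d_by, [0], [1])
    assert (res.n, res.k) == (3, 2)
    assert res.ci_low <= res.rate <= res.ci_high


def test_full_agreement_has_ci_upper_one():
    d_by = {i: {0: 1.0, 1: 1.0} for i in range(5)}
    res = ie.directional_agreement(d_by, [0], [1])
    assert res.rate == 1.0 and res.ci_high == 1.0


def test_overlapping_seed_sets_are_rejected():
    with pytest.raises(ValueError, match="overlap"):
        ie.directional_agreement({"a": {0: 1.0}}, [0], [0])
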