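"""Interpolation evaluation and effect-size statistics.

The interpolation protocol repeats random Train/Dev/Test splits
(fractions 0.5/0.3/0.2) over many seeds; models are tuned on Dev,
refitted on Train+Dev and scored on Test with R2 and RMSE.  The benefit
of feature augmentation is the paired improvement

    d = RMSE(MP) - RMSE(MPD or MPDD)

matched by (model, seed); positive d means the augmentation lowered the
error.  Summaries are the mean improvement with a paired percentile
bootstrap CI (B = 50,000), a two-sided Wilcoxon signed-rank test, and a
discovery/validation directional-agreement rate with an exact
Clopper-Pearson binomial interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

TRAIN_FRAC, DEV_FRAC, TEST_FRAC = 0.5, 0.3, 0.2

#: default seed registry: 50 repeated splits, first half discovery
DEFAULT_SEEDS = tuple(range(50))
DISCOVERY_SEEDS = tuple(range(25))
VALIDATION_SEEDS = tuple(range(25, 50))


@dataclass
class SplitPlan:
    seed: int
    train: np.ndarray
    dev: np.ndarray
    test: np.ndarray


def make_split(n_rows: int, seed: int) -> SplitPlan:
    """Random 5:3:2 Train/Dev/Test split, deterministic in (n, seed).

    Sizes: floor(0.5 n), floor(0.3 n), remainder.
    """
    if n_rows < 3:
        raise ValueError("need at least 3 rows to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_rows)
    n_train = int(np.floor(TRAIN_FRAC * n_rows))
    n_dev = int(np.floor(DEV_FRAC * n_rows))
    return SplitPlan(
        seed=seed,
        train=perm[:n_train],
        dev=perm[n_train : n_train + n_dev],
        test=perm[n_train + n_dev :],
    )


def r2_rmse(y, yhat) -> tuple[float, float]:
    """Coefficient of determination and root mean squared error.

    R2 = 1 - sum (y - yhat)^2 / sum (y - ybar)^2.  For a constant y the
    R2 denominator vanishes: NaN is returned with a warning (the RMSE is
    still valid).
    """
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.size < 2:
        raise ValueError("need n >= 2")
    sse = float(np.sum((y - yhat) ** 2))
    rmse = float(np.sqrt(sse / y.size))
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        warnings.warn("constant y: R2 undefined", stacklevel=2)
        return float("nan"), rmse
    return 1.0 - sse / sst, rmse


def paired_improvements(results_mp: dict, results_aug: dict) -> list[float]:
    """Paired RMSE improvements d keyed strictly by (model, seed).

    Both inputs map (model, seed) -> Test RMSE.  Keys present on only
    one side are excluded with a warning.
    """
    common = sorted(set(results_mp) & set(results_aug))
    dropped = (set(results_mp) | set(results_aug)) - set(common)
    if dropped:
        warnings.warn(f"excluding {len(dropped)} unpaired result(s)", stacklevel=2)
    return [float(results_mp[k]) - float(results_aug[k]) for k in common]


def bootstrap_ci(
    d_list, B: int = 50_000, seed: int = 0, alpha: float = 0.05
) -> tuple[float, float, float]:
    """Percentile bootstrap CI of the mean paired improvement.

    Resamples the d-list with replacement B times; returns
    (mean, CI_low, CI_high).
    """
    d = np.asarray(d_list, dtype=float)
    if d.size == 0:
        raise ValueError("empty improvement list")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, d.size, size=(B, d.size))
    means = d[idx].mean(axis=1)
    lo, hi = np.percentile(means, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(d.mean()), float(lo), float(hi)


def wilcoxon_signed_rank(d_list) -> float:
    """Two-sided Wilcoxon signed-rank p-value for median(d) = 0.

    Zeros are removed first; the exact null distribution is used for
    n <= 25 (valid in the absence of rank ties), otherwise the normal
    approximation with tie correction.  An all-zero list is degenerate
    and returns p = 1 with a warning.
    """
    d = np.asarray(d_list, dtype=float)
    d = d[d != 0.0]
    if d.size == 0:
        warnings.warn("all differences are zero: degenerate test, p = 1", stacklevel=2)
        return 1.0
    has_ties = np.unique(np.abs(d)).size < d.size
    method = "exact" if (d.size <= 25 and not has_ties) else "approx"
    res = stats.wilcoxon(d, alternative="two-sided", method=method, correction=False)
    return float(res.pvalue)


def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact (Clopper-Pearson) binomial confidence interval for k/n."""
    if not 0 <= k <= n or n <= 0:
        raise ValueError("need 0 <= k <= n, n > 0")
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


@dataclass
class EffectSizeSummary:
    target: str
    feature_set: str
    model: str
    d_list: list[float]
    d_mean: float
    ci_low: float
    ci_high: float
    wilcoxon_p: float

    @property
    def n_seeds(self) -> int:
        return len(self.d_list)


def summarize_effect(
    target: str,
    feature_set: str,
    model: str,
    results_mp: dict,
    results_aug: dict,
    B: int = 50_000,
    bootstrap_seed: int = 0,
) -> EffectSizeSummary:
    """Full effect-size summary for one (target, feature set, model)."""
    d = paired_improvements(results_mp, results_aug)
    mean, lo, hi = bootstrap_ci(d, B=B, seed=bootstrap_seed)
    p = wilcoxon_signed_rank(d)
    return EffectSizeSummary(target, feature_set, model, d, mean, lo, hi, p)


@dataclass
class AgreementResult:
    n: int
    k: int
    rate: float
    ci_low: float
    ci_high: float


def _sign(x: float) -> int:
    return 0 if x == 0 else (1 if x > 0 else -1)


def directional_agreement(
    d_by_seed: dict, discovery_seeds, validation_seeds, alpha: float = 0.05
) -> AgreementResult:
    """Discovery/validation sign agreement of mean improvements.

    ``d_by_seed`` maps each (target, feature set, model) combination to
    a mapping seed -> d.  A combination agrees when the signs of its
    discovery-mean and validation-mean improvements match (a mean of
    exactly 0 only matches another exact 0).  Returns the rate k/n with
    an exact Clopper-Pearson CI.
    """
    disc, valid = set(discovery_seeds), set(validation_seeds)
    if disc & valid:
        raise ValueError("discovery and validation seed sets overlap")
    n = len(d_by_seed)
    if n == 0:
        raise ValueError("no combinations")
    k = 0
    for combo, per_seed in d_by_seed.items():
        d_disc = [v for s, v in per_seed.items() if s in disc]
        d_valid = [v for s, v in per_seed.items() if s in valid]
        if not d_disc or not d_valid:
            raise ValueError(f"combination {combo!r} lacks discovery or validation seeds")
        if _sign(float(np.mean(d_disc))) == _sign(float(np.mean(d_valid))):
            k += 1
    lo, hi = clopper_pearson(k, n, alpha)
    return AgreementResult(n=n, k=k, rate=k / n, ci_low=lo, ci_high=hi)


def normalized_rmse_percent(rmse: float, y_min: float, y_max: float) -> float:
    """RMSE as a percentage of the observed target range."""
    if y_max <= y_min:
        raise ValueError("empty target range")
    return 100.0 * float(rmse) / (float(y_max) - float(y_min))
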