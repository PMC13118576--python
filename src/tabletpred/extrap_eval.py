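"""Rolling-origin evaluation, applicability domain and covariate shift.

Deployment-like temporal shift is emulated with an expanding-window
rolling-origin scheme: an initial 50/20/10 Train/Dev/Test split of the
time-ordered rows, with the remaining 20% consumed in four 5% steps
(five folds; Dev and Test widths stay constant while Train grows).

Four applicability-domain (AD) indicators say whether a query lies
inside the region covered by the fitting rows (Train+Dev of a fold):

* leverage -- hat value of a linear model, threshold at the 95th
  percentile of the fitting-set hat diagonals;
* Mahalanobis distance -- squared distance in the PCA subspace keeping
  >= 95% variance, chi-square(0.975) threshold;
* kNN distance -- mean Euclidean distance to the k = 5 nearest fitting
  rows, 95th-percentile threshold;
* range OK -- every feature inside the fitting-set min-max bounds.

Covariate shift between fitting and test windows is quantified per
feature with the Jensen-Shannon divergence (base-2 logs, quantile
binning with additive smoothing), fold-averaged, plus PSI as a
secondary index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

INITIAL_TRAIN_FRAC = 0.5
DEV_FRAC = 0.2
TEST_FRAC = 0.1
STEP_FRAC = 0.05
N_STEPS = 4


@dataclass
class Fold:
    train: np.ndarray
    dev: np.ndarray
    test: np.ndarray


@dataclass
class RollingPlan:
    n_rows: int
    folds: list[Fold]


def rolling_origin_folds(n_rows: int) -> RollingPlan:
    """Expanding-window rolling-origin folds over time-ordered rows.

    Fold f (f = 0..4): Train = rows [0, round((0.5 + 0.05 f) n)),
    Dev the next round(0.2 n) rows, Test the next round(0.1 n) rows.
    """
    if n_rows < 20:
        raise ValueError("need at least 20 time-ordered rows")
    n_dev = round(DEV_FRAC * n_rows)
    n_test = round(TEST_FRAC * n_rows)
    if n_dev == 0 or n_test == 0:
        raise ValueError("window widths collapse to zero")
    folds = []
    for f in range(N_STEPS + 1):
        n_train = round((INITIAL_TRAIN_FRAC + STEP_FRAC * f) * n_rows)
        end = n_train + n_dev + n_test
        if end > n_rows:
            raise ValueError("fold exceeds available rows")
        folds.append(
            Fold(
                train=np.arange(0, n_train),
                dev=np.arange(n_train, n_train + n_dev),
                test=np.arange(n_train + n_dev, end),
            )
        )
    return RollingPlan(n_rows=n_rows, folds=folds)


def spearman_rho(y, yhat) -> float:
    """Spearman rank correlation: Pearson correlation of average ranks."""
    ry = stats.rankdata(np.asarray(y, dtype=float))
    rp = stats.rankdata(np.asarray(yhat, dtype=float))
    return float(np.corrcoef(ry, rp)[0, 1])


# ---------------------------------------------------------------------------
# applicability-domain indicators


@dataclass
class ADResult:
    """One indicator's values, flags and threshold for fit and query sets."""

    indicator: str
    threshold: float
    fit_values: np.ndarray
    fit_in_domain: np.ndarray
    query_values: np.ndarray
    query_in_domain: np.ndarray

    @property
    def fit_coverage(self) -> float:
        return 100.0 * float(np.mean(self.fit_in_domain))

    @property
    def query_coverage(self) -> float:
        return 100.0 * float(np.mean(self.query_in_domain))


def leverage_ad(X_fit, X_query, percentile: float = 95.0) -> ADResult:
    """Hat-value leverage with a fitting-set percentile threshold.

    h(x) = x~' (X~' X~)^+ x~ with an intercept column appended; the
    pseudo-inverse handles rank deficiency.  In-domain iff h <= the
    ``percentile``-th percentile of the fitting-set hat diagonals
    (linear-interpolation percentile).
    """
    X_fit = np.asarray(X_fit, dtype=float)
    X_query = np.asarray(X_query, dtype=float)
    if X_fit.size == 0:
        raise ValueError("empty fitting set")
    Xf = np.column_stack([np.ones(len(X_fit)), X_fit])
    Xq = np.column_stack([np.ones(len(X_query)), X_query])
    G = np.linalg.pinv(Xf.T @ Xf)
    h_fit = np.einsum("ij,jk,ik->i", Xf, G, Xf)
    h_query = np.einsum("ij,jk,ik->i", Xq, G, Xq)
    thr = float(np.percentile(h_fit, percentile))
    return ADResult("leverage", thr, h_fit, h_fit <= thr, h_query, h_query <= thr)


def mahalanobis_ad(
    X_fit, X_query, variance_retained: float = 0.95, chi2_q: float = 0.975
) -> ADResult:
    """Squared Mahalanobis distance in a PCA subspace.

    PCA is fitted on the fitting rows and truncated at the smallest
    number of components explaining >= ``variance_retained``; the
    squared distance sums (score / component sd)^2 and the threshold is
    the chi-square quantile ``chi2_q`` with that many degrees of
    freedom.
    """
    X_fit = np.asarray(X_fit, dtype=float)
    X_query = np.asarray(X_query, dtype=float)
    if X_fit.size == 0:
        raise ValueError("empty fitting set")
    pca = PCA()
    scores_fit = pca.fit_transform(X_fit)
    cum = np.cumsum(pca.explained_variance_ratio_)
    n_comp = int(np.searchsorted(cum, variance_retained) + 1)
    n_comp = min(n_comp, scores_fit.shape[1])
    sd = np.sqrt(pca.explained_variance_[:n_comp])
    sd = np.where(sd > 0, sd, 1.0)
    d2_fit = ((scores_fit[:, :n_comp] / sd) ** 2).sum(axis=1)
    scores_q = pca.transform(X_query)[:, :n_comp]
    d2_query = ((scores_q / sd) ** 2).sum(axis=1)
    thr = float(stats.chi2.ppf(chi2_q, df=n_comp))
    return ADResult("mahalanobis", thr, d2_fit, d2_fit <= thr, d2_query, d2_query <= thr)


def knn_ad(X_fit, X_query, k: int = 5, percentile: float = 95.0) -> ADResult:
    """Mean distance to the k nearest fitting rows.

    Fitting-set values exclude the self-distance; threshold is the
    ``percentile``-th percentile of the fitting-set values.
    """
    X_fit = np.asarray(X_fit, dtype=float)
    X_query = np.asarray(X_query, dtype=float)
    if len(X_fit) <= k:
        raise ValueError(f"need more than k={k} fitting rows")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X_fit)
    d_self, _ = nn.kneighbors(X_fit)
    fit_vals = d_self[:, 1:].mean(axis=1)  # drop self (distance 0)
    d_q, _ = nn.kneighbors(X_query, n_neighbors=k)
    q_vals = d_q.mean(axis=1)
    thr = float(np.percentile(fit_vals, percentile))
    return ADResult("knn_distance", thr, fit_vals, fit_vals <= thr, q_vals, q_vals <= thr)


def range_ok(X_fit, X_query) -> ADResult:
    """Per-feature min-max bound check (inclusive)."""
    X_fit = np.asarray(X_fit, dtype=float)
    X_query = np.asarray(X_query, dtype=float)
    if X_fit.size == 0:
        raise ValueError("empty fitting set")
    lo, hi = X_fit.min(axis=0), X_fit.max(axis=0)
    fit_in = np.all((X_fit >= lo) & (X_fit <= hi), axis=1)
    q_in = np.all((X_query >= lo) & (X_query <= hi), axis=1)
    # value reported: number of out-of-range features per sample
    fit_vals = ((X_fit < lo) | (X_fit > hi)).sum(axis=1).astype(float)
    q_vals = ((X_query < lo) | (X_query > hi)).sum(axis=1).astype(float)
    return ADResult("range_ok", 0.0, fit_vals, fit_in, q_vals, q_in)


AD_INDICATORS = ("leverage", "mahalanobis", "knn_distance", "range_ok")


def ad_report(X_fit, X_query, k: int = 5) -> dict[str, ADResult]:
    """All four AD indicators for one (fitting, query) pair."""
    return {
        "leverage": leverage_ad(X_fit, X_query),
        "mahalanobis": mahalanobis_ad(X_fit, X_query),
        "knn_distance": knn_ad(X_fit, X_query, k=k),
        "range_ok": range_ok(X_fit, X_query),
    }


# ---------------------------------------------------------------------------
# covariate-shift diagnostics


def jsd_feature(p_sample, q_sample, n_bins: int = 20, smoothing: float = 1e-6) -> float:
    """Jensen-Shannon divergence between two samples of one feature.

    Histograms use ``n_bins`` quantile bins of the pooled non-missing
    values with additive smoothing and renormalization; logs are base 2
    so the result lies in [0, 1] and is symmetric.  A feature constant
    in both samples has JSD 0.
    """
    p_sample = np.asarray(p_sample, dtype=float)
    q_sample = np.asarray(q_sample, dtype=float)
    p_sample = p_sample[~np.isnan(p_sample)]
    q_sample = q_sample[~np.isnan(q_sample)]
    pooled = np.concatenate([p_sample, q_sample])
    if pooled.size == 0 or np.ptp(pooled) == 0.0:
        return 0.0
    edges = np.unique(np.quantile(pooled, np.linspace(0, 1, n_bins + 1)))
    if len(edges) < 2:
        return 0.0
    edges[0], edges[-1] = -np.inf, np.inf
    p = np.histogram(p_sample, bins=edges)[0].astype(float) + smoothing
    q = np.histogram(q_sample, bins=edges)[0].astype(float) + smoothing
    p /= p.sum()
    q /= q.sum()
    m = 0.5 * (p + q)
    kl_pm = float(np.sum(p * np.log2(p / m)))
    kl_qm = float(np.sum(q * np.log2(q / m)))
    return 0.5 * kl_pm + 0.5 * kl_qm


def psi_feature(p_sample, q_sample, n_bins: int = 20, smoothing: float = 1e-6) -> float:
    """Population stability index on the same quantile bins as JSD."""
    p_sample = np.asarray(p_sample, dtype=float)
    q_sample = np.asarray(q_sample, dtype=float)
    p_sample = p_sample[~np.isnan(p_sample)]
    q_sample = q_sample[~np.isnan(q_sample)]
    pooled = np.concatenate([p_sample, q_sample])
    if pooled.size == 0 or np.ptp(pooled) == 0.0:
        return 0.0
    edges = np.unique(np.quantile(pooled, np.linspace(0, 1, n_bins + 1)))
    if len(edges) < 2:
        return 0.0
    edges[0], edges[-1] = -np.inf, np.inf
    p = np.histogram(p_sample, bins=edges)[0].astype(float) + smoothing
    q = np.histogram(q_sample, bins=edges)[0].astype(float) + smoothing
    p /= p.sum()
    q /= q.sum()
    return float(np.sum((p - q) * np.log(p / q)))


@dataclass
class ShiftReport:
    """Fold-averaged per-feature JSD (and PSI), with top-K ranking."""

    jsd: pd.Series  # fold-averaged, indexed by feature
    psi: pd.Series

    def top(self, n: int = 10) -> pd.Series:
        return self.jsd.sort_values(ascending=False).head(n)

    @property
    def mean_top10_jsd(self) -> float:
        return float(self.top(10).mean())


def jsd_shift(X: pd.DataFrame, plan: RollingPlan, n_bins: int = 20) -> ShiftReport:
    """Per-feature covariate shift across rolling-origin folds.

    For each fold, each feature's JSD (and PSI) between the fitting
    window (Train+Dev) and the Test window is computed, then averaged
    over folds.
    """
    jsd_acc = pd.Series(0.0, index=X.columns)
    psi_acc = pd.Series(0.0, index=X.columns)
    for fold in plan.folds:
        fit_idx = np.concatenate([fold.train, fold.dev])
        for col in X.columns:
            a = X.iloc[fit_idx][col].to_numpy()
            b = X.iloc[fold.test][col].to_numpy()
            jsd_acc[col] += jsd_feature(a, b, n_bins=n_bins)
            psi_acc[col] += psi_feature(a, b, n_bins=n_bins)
    n_folds = len(plan.folds)
    return ShiftReport(jsd=jsd_acc / n_folds, psi=psi_acc / n_folds)
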