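"""The six regression families, hyperparameter search and attribution.

Families: Random Forest (RF), Extra Trees (ET), Lasso, Partial Least
Squares (PLS), Support Vector Regression (SVR) and the multi-branch
neural network (NN).  The five classical learners are tuned by
exhaustive grid search on Dev RMSE over fixed reference grids; the NN
is tuned by a seeded random search over its reference search space with
early stopping and learning-rate decay inside each trial.

Tree ensembles additionally expose decision-path feature attributions:
for each sample, the change in node mean along the decision path is
credited to the feature split at that node, so per-feature
contributions plus the root baseline reproduce the prediction exactly
(local accuracy).  Mean absolute contributions, averaged over repeated
seeds, are the feature-importance measure.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import ExtraTreesRegressor, RandomForestRegressor
from sklearn.linear_model import Lasso
from sklearn.svm import SVR

from .nn import ACTIVATIONS, MultiBranchRegressor, NNConfig

FAMILIES = ("RF", "ET", "Lasso", "PLS", "SVR", "NN")
TREE_FAMILIES = ("RF", "ET")

#: Exhaustive grids for the classical learners, in documented iteration
#: order (itertools.product over the listed rows, first row outermost).
GRIDS: dict[str, dict[str, list]] = {
    "ET": {
        "n_estimators": [50, 100],
        "max_features": [0.3, 0.5, 0.7],
        "max_depth": [None, 10, 20],
        "min_samples_leaf": [1, 5, 10],
        "min_samples_split": [2, 10],
    },
    "RF": {
        "n_estimators": [50, 100],
        "max_features": [0.3, 0.5, 0.7],
        "max_depth": [None, 10, 20],
        "min_samples_leaf": [1, 2, 4],
        "min_samples_split": [2, 5],
    },
    "SVR": {
        "C": [0.001, 0.01, 0.1, 1, 10],
        "kernel": ["linear", "rbf"],
        "gamma": [0.1, 0.5, 1.0],
    },
    "PLS": {"n_components": list(range(1, 11))},
    "Lasso": {"alpha": [0.001, 0.01, 0.1, 1, 10]},
}

#: NN search space: loguniform learning rate, four activations, dropout
#: 0.1-0.5, 1-3 layers of 10-190 units per branch/joint stack, batch
#: size in {8, 16, 32}, 50-300 epochs.
NN_SEARCH_SPACE = {
    "learning_rate": (1e-5, 1e-2),
    "activation": list(ACTIVATIONS),
    "dropout": (0.1, 0.5),
    "n_layers": (1, 3),
    "units": (10, 190),
    "batch_size": [8, 16, 32],
    "epochs": (50, 300),
}

#: Fixed desk-scale defaults used when running the pipeline without a
#: hyperparameter search: the midpoints of the reference grids
#: (rationale in docs/methods.md; fully grown trees interpolate target
#: noise, which distorts paired feature-set comparisons).
DEFAULT_PARAMS = {
    "ET": {"n_estimators": 100, "max_features": 0.5, "max_depth": None,
           "min_samples_leaf": 5, "min_samples_split": 2},
    "RF": {"n_estimators": 100, "max_features": 0.5, "max_depth": None,
           "min_samples_leaf": 2, "min_samples_split": 2},
    "SVR": {"C": 1, "kernel": "rbf", "gamma": 0.1},
    "PLS": {"n_components": 5},
    "Lasso": {"alpha": 0.01},
}


def make_model(family: str, params: dict, seed: int = 0):
    """Instantiate an unfitted learner of one classical family."""
    if family == "RF":
        return RandomForestRegressor(random_state=seed, n_jobs=1, **params)
    if family == "ET":
        return ExtraTreesRegressor(random_state=seed, n_jobs=1, **params)
    if family == "Lasso":
        return Lasso(max_iter=50_000, **params)
    if family == "PLS":
        return PLSRegression(scale=False, **params)
    if family == "SVR":
        return SVR(**params)
    raise ValueError(f"unknown family {family!r} (NN uses MultiBranchRegressor)")


def _rmse(y, yhat) -> float:
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


@dataclass
class SearchResult:
    family: str
    best_params: dict
    best_dev_rmse: float
    log: list = field(default_factory=list)  # (params, dev_rmse) per point


def grid_search(family, X_train, y_train, X_dev, y_dev, seed: int = 0) -> SearchResult:
    """Exhaustive grid search minimizing Dev RMSE; ties keep the first
    grid point encountered.  PLS points with more components than
    features are skipped with a warning."""
    if family not in GRIDS:
        raise ValueError(f"no grid for family {family!r}")
    grid = GRIDS[family]
    names = list(grid)
    X_train = np.asarray(X_train, dtype=float)
    X_dev = np.asarray(X_dev, dtype=float)
    best = None
    log = []
    for values in itertools.product(*grid.values()):
        params = dict(zip(names, values))
        if family == "PLS" and params["n_components"] > min(X_train.shape):
            warnings.warn(f"skipping PLS grid point {params} (too many components)", stacklevel=2)
            continue
        model = make_model(family, params, seed=seed)
        model.fit(X_train, np.asarray(y_train, dtype=float).ravel())
        dev_rmse = _rmse(y_dev, model.predict(X_dev))
        log.append((params, dev_rmse))
        if best is None or dev_rmse < best[1]:
            best = (params, dev_rmse)
    if best is None:
        raise ValueError("no admissible grid point")
    return SearchResult(family, best[0], best[1], log)


def sample_nn_config(rng: np.random.Generator) -> NNConfig:
    """Draw one configuration from :data:`NN_SEARCH_SPACE`."""
    sp = NN_SEARCH_SPACE
    lo, hi = sp["learning_rate"]
    lr = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    def layers() -> tuple[int, ...]:
        n = int(rng.integers(sp["n_layers"][0], sp["n_layers"][1] + 1))
        return tuple(int(rng.integers(sp["units"][0], sp["units"][1] + 1)) for _ in range(n))

    return NNConfig(
        learning_rate=lr,
        activation=str(rng.choice(sp["activation"])),
        dropout=float(rng.uniform(*sp["dropout"])),
        descriptor_layers=layers(),
        psd_layers=layers(),
        joint_layers=layers(),
        batch_size=int(rng.choice(sp["batch_size"])),
        epochs=int(rng.integers(sp["epochs"][0], sp["epochs"][1] + 1)),
    )


def search_nn(
    train_blocks,
    y_train,
    dev_blocks,
    y_dev,
    n_trials: int = 50,
    seed: int = 0,
) -> SearchResult:
    """Seeded random search for the NN over its reference space.

    Each trial trains with early stopping and LR decay and is scored by
    Dev RMSE; trials with non-finite losses are marked failed and the
    search continues.  Fully deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    best = None
    log = []
    for trial in range(n_trials):
        config = sample_nn_config(rng)
        try:
            model = MultiBranchRegressor(config, seed=seed + 1000 + trial)
            model.fit(train_blocks, y_train, dev_blocks, y_dev)
            dev_rmse = _rmse(y_dev, model.predict(dev_blocks))
        except FloatingPointError:
            log.append((config, np.nan))
            continue
        log.append((config, dev_rmse))
        if best is None or dev_rmse < best[1]:
            best = (config, dev_rmse)
    if best is None:
        raise ValueError("all NN trials failed")
    return SearchResult("NN", best[0], best[1], log)


def fit_final(family, best_params, X, y, seed: int = 0):
    """Refit the selected configuration on the combined Train+Dev rows."""
    if family == "NN":
        model = MultiBranchRegressor(best_params, seed=seed)
        return model.fit(X, y)  # X is the block dict for NN
    model = make_model(family, best_params, seed=seed)
    model.fit(np.asarray(X, dtype=float), np.asarray(y, dtype=float).ravel())
    return model


# ---------------------------------------------------------------------------
# decision-path attributions for tree ensembles


def _tree_path_contributions(tree, X: np.ndarray) -> tuple[float, np.ndarray]:
    """Per-feature contributions of one fitted decision tree.

    Walking each sample's decision path, the change in node mean value
    between a parent and the chosen child is credited to the parent's
    split feature.  base + sum(contributions) equals the leaf value.
    """
    t = tree.tree_
    left, right = t.children_left, t.children_right
    feat, thresh = t.feature, t.threshold
    value = t.value.reshape(-1)
    n, p = X.shape
    contrib = np.zeros((n, p))
    for i in range(n):
        node = 0
        while left[node] != -1:
            f = feat[node]
            child = left[node] if X[i, f] <= thresh[node] else right[node]
            contrib[i, f] += value[child] - value[node]
            node = child
    return float(value[0]), contrib


def tree_path_attributions(model, X) -> tuple[float, np.ndarray]:
    """Decision-path attributions of a fitted tree ensemble.

    Returns ``(base, contributions)`` with ``contributions`` of shape
    (n_samples, n_features); ``base + contributions.sum(axis=1)``
    reproduces ``model.predict(X)`` (local accuracy).
    """
    if not isinstance(model, (RandomForestRegressor, ExtraTreesRegressor)):
        raise TypeError("decision-path attribution supports tree ensembles only")
    X = np.asarray(X, dtype=float)
    bases, contribs = [], []
    for est in model.estimators_:
        b, c = _tree_path_contributions(est, X)
        bases.append(b)
        contribs.append(c)
    return float(np.mean(bases)), np.mean(contribs, axis=0)


def mean_abs_attribution(models, X, feature_names=None) -> pd.Series:
    """Mean absolute decision-path attribution per feature.

    ``models`` may be one fitted ensemble or a list of them (e.g. the
    refits from repeated seeds); attributions are averaged over models
    and samples, and returned sorted descending.
    """
    if not isinstance(models, (list, tuple)):
        models = [models]
    X = np.asarray(X, dtype=float)
    acc = np.zeros(X.shape[1])
    for model in models:
        _, contrib = tree_path_attributions(model, X)
        acc += np.abs(contrib).mean(axis=0)
    acc /= len(models)
    if feature_names is None:
        feature_names = [f"x{j}" for j in range(X.shape[1])]
    return pd.Series(acc, index=list(feature_names)).sort_values(ascending=False)
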