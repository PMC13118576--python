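"""End-to-end experiment orchestration.

Glue between the feature-set, model-zoo and evaluation modules: run the
repeated-split interpolation protocol or the rolling-origin
extrapolation protocol for a dataset, producing tidy result ledgers and
the derived effect-size / applicability-domain / shift summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import extrap_eval, interp_eval, model_zoo
from .data_model import Dataset
from .feature_sets import (
    FeatureMatrix,
    apply_preprocessor,
    assemble,
    block_slices,
    fit_preprocessor,
)
from .nn import MultiBranchRegressor, NNConfig


def _target_frame(dataset: Dataset, target: str) -> pd.Series:
    t = dataset.targets
    vals = t.loc[t["target"] == target].set_index("formulation_id")["value"]
    return vals.astype(float)


def _fit_predict(
    family: str,
    fm: FeatureMatrix,
    y: pd.Series,
    train_idx,
    dev_idx,
    test_idx,
    seed: int,
    params: dict | None | str = "default",
    nn_trials: int = 10,
):
    """Tune on Dev (optional), refit on Train+Dev, predict Test.

    ``params='default'`` uses the fixed desk-scale hyperparameters;
    ``params=None`` runs the full search (grid or NN random
    search); an explicit dict is used as-is.
    """
    pre = fit_preprocessor(fm, train_idx)
    Xt = apply_preprocessor(pre, fm, warn_unseen=False).X
    fit_idx = list(train_idx) + list(dev_idx)

    if family == "NN":
        blocks = block_slices(apply_preprocessor(pre, fm, warn_unseen=False))
        cols = blocks

        def take(idx):
            return {
                "main": Xt.iloc[idx][cols["main"]].to_numpy(),
                "descriptor": Xt.iloc[idx][cols["descriptor"]].to_numpy(),
                "psd": Xt.iloc[idx][cols["psd"]].to_numpy(),
            }

        if params == "default":
            config = NNConfig(epochs=100)
        elif params is None:
            res = model_zoo.search_nn(
                take(train_idx), y.iloc[train_idx].to_numpy(),
                take(dev_idx), y.iloc[dev_idx].to_numpy(),
                n_trials=nn_trials, seed=seed,
            )
            config = res.best_params
        else:
            config = params
        model = MultiBranchRegressor(config, seed=seed)
        model.fit(take(fit_idx), y.iloc[fit_idx].to_numpy())
        yhat = model.predict(take(list(test_idx)))
        return model, yhat

    X = Xt.to_numpy(dtype=float)
    yv = y.to_numpy(dtype=float)
    if params == "default":
        chosen = model_zoo.DEFAULT_PARAMS[family]
    elif params is None:
        res = model_zoo.grid_search(
            family, X[train_idx], yv[train_idx], X[dev_idx], yv[dev_idx], seed=seed
        )
        chosen = res.best_params
    else:
        chosen = params
    model = model_zoo.fit_final(family, chosen, X[fit_idx], yv[fit_idx], seed=seed)
    yhat = np.asarray(model.predict(X[list(test_idx)])).ravel()
    return model, yhat


@dataclass
class InterpolationResults:
    ledger: pd.DataFrame  # target, level, model, seed, r2, rmse
    effects: list  # EffectSizeSummary per (target, aug level, model)
    agreement: interp_eval.AgreementResult | None


def evaluate_interpolation(
    dataset: Dataset,
    targets,
    levels=("MP", "MPD"),
    families=("ET",),
    seeds=range(10),
    params="default",
    B: int = 50_000,
    bootstrap_seed: int = 12345,
    profiles=None,
) -> InterpolationResults:
    """Repeated-split interpolation protocol.

    For every target x level x model x seed: split 5:3:2, preprocess on
    Train, refit on Train+Dev, score Test.  Effect sizes compare each
    augmented level against MP, paired by (model, seed); when both seed
    halves are present a directional-agreement summary is added.
    """
    seeds = list(seeds)
    rows = []
    rmse_store: dict = {}
    for target in targets:
        y = _target_frame(dataset, target)
        sub = _subset_dataset(dataset, y.index)
        fms = {lv: assemble(sub, lv, target, profiles=profiles) for lv in levels}
        n = len(y)
        for seed in seeds:
            plan = interp_eval.make_split(n, seed)
            for lv in levels:
                for fam in families:
                    _, yhat = _fit_predict(
                        fam, fms[lv], y, plan.train, plan.dev, plan.test, seed, params
                    )
                    r2, rmse = interp_eval.r2_rmse(y.iloc[plan.test], yhat)
                    rows.append(
                        {
                            "target": target,
                            "level": lv,
                            "model": fam,
                            "seed": seed,
                            "r2": r2,
                            "rmse": rmse,
                        }
                    )
                    rmse_store[(target, lv, fam, seed)] = rmse

    ledger = pd.DataFrame(rows)
    effects = []
    d_by_combo: dict = {}
    aug_levels = [lv for lv in levels if lv != "MP"]
    if "MP" in levels:
        for target in targets:
            for lv in aug_levels:
                for fam in families:
                    mp = {
                        (fam, s): rmse_store[(target, "MP", fam, s)]
                        for s in seeds
                        if (target, "MP", fam, s) in rmse_store
                    }
                    aug = {
                        (fam, s): rmse_store[(target, lv, fam, s)]
                        for s in seeds
                        if (target, lv, fam, s) in rmse_store
                    }
                    eff = interp_eval.summarize_effect(
                        target, lv, fam, mp, aug, B=B, bootstrap_seed=bootstrap_seed
                    )
                    effects.append(eff)
                    d_by_combo[(target, lv, fam)] = {
                        s: mp[(fam, s)] - aug[(fam, s)] for s in seeds
                    }

    agreement = None
    half = len(seeds) // 2
    if half >= 1 and d_by_combo:
        disc, valid = seeds[:half], seeds[half:]
        agreement = interp_eval.directional_agreement(d_by_combo, disc, valid)
    return InterpolationResults(ledger=ledger, effects=effects, agreement=agreement)


def _subset_dataset(dataset: Dataset, formulation_ids) -> Dataset:
    fids = [f for f in dataset.process.index if f in set(formulation_ids)]
    return Dataset(
        materials=dataset.materials,
        compositions=dataset.compositions[
            dataset.compositions["formulation_id"].isin(fids)
        ],
        process=dataset.process.loc[fids],
        targets=dataset.targets[dataset.targets["formulation_id"].isin(fids)],
        psd=dataset.psd,
    )


@dataclass
class ExtrapolationResults:
    fold_metrics: pd.DataFrame  # target, level, model, fold, r2, rmse, rho
    ad_coverage: pd.DataFrame  # target, level, indicator, split, coverage %
    shift: dict  # (target, level) -> ShiftReport


def evaluate_extrapolation(
    dataset: Dataset,
    targets,
    levels=("MP", "MPD"),
    families=("RF", "ET", "Lasso", "PLS", "SVR"),
    params="default",
    profiles=None,
    seed: int = 0,
) -> ExtrapolationResults:
    """Rolling-origin protocol with AD and shift diagnostics.

    Rows are ordered by ``time_index``; each fold fits preprocessing and
    AD thresholds on Train+Dev only.  The NN is excluded from the
    default family list (high training variance across so few folds).
    """
    if not families:
        raise ValueError("empty model family list")
    metric_rows = []
    ad_rows = []
    shift: dict = {}
    for target in targets:
        y = _target_frame(dataset, target)
        sub = _subset_dataset(dataset, y.index)
        order = sub.process["time_index"].astype(float).argsort(kind="stable").to_numpy()
        fids = sub.process.index.to_numpy()[order]
        sub = _subset_dataset(sub, fids)
        y = y.loc[fids]
        plan = extrap_eval.rolling_origin_folds(len(y))
        for lv in levels:
            fm = assemble(sub, lv, target, profiles=profiles)
            cov_acc = {ind: {"Train+Dev": [], "Test": []} for ind in extrap_eval.AD_INDICATORS}
            Xfull_for_shift = None
            for fold in plan.folds:
                fit_idx = np.concatenate([fold.train, fold.dev])
                pre = fit_preprocessor(fm, fit_idx)
                Xt = apply_preprocessor(pre, fm, warn_unseen=False).X
                Xfull_for_shift = Xt
                X_fit = Xt.iloc[fit_idx].to_numpy()
                X_test = Xt.iloc[fold.test].to_numpy()
                for ind, res in extrap_eval.ad_report(X_fit, X_test).items():
                    cov_acc[ind]["Train+Dev"].append(res.fit_coverage)
                    cov_acc[ind]["Test"].append(res.query_coverage)
                for fam in families:
                    _, yhat = _fit_predict(
                        fam, fm, y, fold.train, fold.dev, fold.test, seed, params
                    )
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        r2, rmse = interp_eval.r2_rmse(y.iloc[fold.test], yhat)
                    rho = extrap_eval.spearman_rho(y.iloc[fold.test], yhat)
                    metric_rows.append(
                        {
                            "target": target,
                            "level": lv,
                            "model": fam,
                            "fold": int(fold.train[-1]),
                            "r2": r2,
                            "rmse": rmse,
                            "rho": rho,
                        }
                    )
            for ind in extrap_eval.AD_INDICATORS:
                for split in ("Train+Dev", "Test"):
                    ad_rows.append(
                        {
                            "target": target,
                            "level": lv,
                            "indicator": ind,
                            "split": split,
                            "coverage": float(np.mean(cov_acc[ind][split])),
                        }
                    )
            shift[(target, lv)] = extrap_eval.jsd_shift(Xfull_for_shift, plan)
    return ExtrapolationResults(
        fold_metrics=pd.DataFrame(metric_rows),
        ad_coverage=pd.DataFrame(ad_rows),
        shift=shift,
    )
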