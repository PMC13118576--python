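"""Assembly of the MP / MPD / MPDD design matrices.

MP is the base feature set: material addition rates (one column per
known material, lexical order), the numeric process settings, and the
punch-type category.  MPD appends the per-target scalar-descriptor
block; MPDD further appends the ten mixture-PSD summary statistics.

Preprocessing is leakage-safe: one-hot categories and standardization
parameters are fitted on training rows only and applied as pure
functions elsewhere.  Formulation-ratio columns are never standardized;
every other numeric column is scaled to mean 0 / sd 1 (zero-variance
columns map to 0).  Unseen punch types encode as all-zero dummies.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import psd as psdmod
from .data_model import PROCESS_NUMERIC, PUNCH_COLUMN, Dataset, composition_matrix
from .descriptors import descriptor_block, load_target_profiles

LEVELS = ("MP", "MPD", "MPDD")

ROLE_RATIO = "ratio"
ROLE_PROCESS_NUMERIC = "process_numeric"
ROLE_PROCESS_ONEHOT = "process_onehot"
ROLE_DESCRIPTOR = "descriptor"
ROLE_PSD_SUMMARY = "psd_summary"

#: roles whose columns are standardized by the preprocessor
STANDARDIZED_ROLES = (ROLE_PROCESS_NUMERIC, ROLE_DESCRIPTOR, ROLE_PSD_SUMMARY)


@dataclass
class FeatureMatrix:
    """A design matrix plus per-column role tags.

    ``X`` may still contain the raw categorical punch column (role
    ``process_onehot``); :func:`apply_preprocessor` replaces it with
    dummy columns.
    """

    X: pd.DataFrame
    roles: dict[str, str]
    level: str
    target: str

    @property
    def columns(self) -> list[str]:
        return list(self.X.columns)

    def columns_by_role(self, role: str) -> list[str]:
        return [c for c in self.X.columns if self.roles[c] == role]


def assemble(
    dataset: Dataset,
    level: str,
    target: str,
    profiles: dict | None = None,
) -> FeatureMatrix:
    """Assemble the design matrix for one feature-set level and target.

    Deterministic: identical inputs give identical matrices and column
    order (ratios lexical by material id, then process numerics, punch
    type, descriptors in profile order, PSD summaries in fixed order).
    """
    if level not in LEVELS:
        raise ValueError(f"level must be one of {LEVELS}, got {level!r}")
    wide = composition_matrix(dataset)
    proc = dataset.process.loc[wide.index]

    blocks = [wide]
    roles = {c: ROLE_RATIO for c in wide.columns}

    proc_numeric = [c for c in PROCESS_NUMERIC if c in proc.columns]
    blocks.append(proc[proc_numeric].astype(float).fillna(0.0))
    roles.update({c: ROLE_PROCESS_NUMERIC for c in proc_numeric})

    blocks.append(proc[[PUNCH_COLUMN]])
    roles[PUNCH_COLUMN] = ROLE_PROCESS_ONEHOT

    if level in ("MPD", "MPDD"):
        desc = descriptor_block(dataset, target, profiles=profiles)
        blocks.append(desc)
        roles.update({c: ROLE_DESCRIPTOR for c in desc.columns})

    if level == "MPDD":
        if dataset.psd is None or not len(dataset.psd):
            raise ValueError("MPDD requested but no material has a PSD")
        mixed = psdmod.mixture_psd_matrix(wide, dataset.psd)
        summaries = psdmod.summarize_psd_matrix(mixed)
        blocks.append(summaries)
        roles.update({c: ROLE_PSD_SUMMARY for c in summaries.columns})

    X = pd.concat(blocks, axis=1)
    if X.columns.duplicated().any():
        raise ValueError("duplicate column names across blocks")
    return FeatureMatrix(X=X, roles=roles, level=level, target=target)


@dataclass
class Preprocessor:
    """Frozen preprocessing parameters fitted on training rows."""

    means: pd.Series
    sds: pd.Series
    punch_levels: list[str]
    roles: dict[str, str]
    columns: list[str]  # input column order


def fit_preprocessor(fm: FeatureMatrix, train_index=None) -> Preprocessor:
    """Fit standardization and one-hot parameters on training rows only."""
    X = fm.X if train_index is None else fm.X.iloc[list(train_index)]
    if not len(X):
        raise ValueError("empty training set")
    std_cols = [c for c in X.columns if fm.roles[c] in STANDARDIZED_ROLES]
    means = X[std_cols].mean()
    sds = X[std_cols].std(ddof=0)
    levels = sorted(X[PUNCH_COLUMN].astype(str).unique()) if PUNCH_COLUMN in X else []
    return Preprocessor(
        means=means, sds=sds, punch_levels=levels, roles=dict(fm.roles), columns=list(X.columns)
    )


def apply_preprocessor(pre: Preprocessor, fm: FeatureMatrix, warn_unseen: bool = True) -> FeatureMatrix:
    """Apply a fitted preprocessor; never re-estimates parameters.

    Ratio columns pass through bit-identical; standardized columns use
    the stored (mean, sd), zero-variance columns mapping to 0; the punch
    column becomes one dummy per fitted level (unseen categories encode
    as an all-zero row, with a warning).
    """
    X = fm.X
    out = {}
    roles = {}
    for c in pre.columns:
        role = pre.roles[c]
        if role == ROLE_PROCESS_ONEHOT:
            vals = X[c].astype(str)
            unseen = set(vals.unique()) - set(pre.punch_levels)
            if unseen and warn_unseen:
                warnings.warn(f"unseen punch-type categories {sorted(unseen)}", stacklevel=2)
            for lv in pre.punch_levels:
                name = f"{c}={lv}"
                out[name] = (vals == lv).astype(float)
                roles[name] = ROLE_PROCESS_ONEHOT
        elif c in pre.means.index:
            sd = pre.sds[c]
            col = X[c].astype(float)
            out[c] = (col - pre.means[c]) / sd if sd > 0 else col * 0.0
            roles[c] = role
        else:
            out[c] = X[c].astype(float)
            roles[c] = role
    Xt = pd.DataFrame(out, index=X.index)
    return FeatureMatrix(X=Xt, roles=roles, level=fm.level, target=fm.target)


def encoded_width(fm: FeatureMatrix, pre: Preprocessor) -> int:
    """Design-matrix width after one-hot encoding."""
    k = len(pre.punch_levels)
    n_cat = sum(1 for c in pre.columns if pre.roles[c] == ROLE_PROCESS_ONEHOT)
    return len(pre.columns) - n_cat + n_cat * k


def export_feature_matrix(fm: FeatureMatrix, csv_path, roles_path=None) -> None:
    """Write the matrix to CSV with a sidecar JSON of column roles."""
    fm.X.to_csv(csv_path, index_label="formulation_id")
    if roles_path is not None:
        with open(roles_path, "w") as fh:
            json.dump({"level": fm.level, "target": fm.target, "roles": fm.roles}, fh, indent=2)


def block_slices(fm: FeatureMatrix) -> dict[str, list[str]]:
    """Column lists of the three NN input branches."""
    main = [
        c
        for c in fm.X.columns
        if fm.roles[c] in (ROLE_RATIO, ROLE_PROCESS_NUMERIC, ROLE_PROCESS_ONEHOT)
    ]
    return {
        "main": main,
        "descriptor": fm.columns_by_role(ROLE_DESCRIPTOR),
        "psd": fm.columns_by_role(ROLE_PSD_SUMMARY),
    }
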