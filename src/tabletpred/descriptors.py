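"""Mixture descriptors and engineered formulation features.

Scalar powder properties are defined per material; the prediction target
is a mixture.  Mixture-level descriptors are built as composition-
weighted sums

    p_mix = sum_i x_i * p_i,    sum_i x_i = 1,

a deliberate linear approximation (not a physical interaction model).
Missing material properties are first filled by a k-nearest-neighbour
imputer (k=5).  On top of the mixture scalars, engineered features
capture tablet geometry and compaction stress (spherical-cap R-part
height/volume, 1/weight, compaction pressure), the compositional balance
of the nine raw-material categories, and 21 interaction-only products of
the first seven category ratios.

Which features enter which target's descriptor block is configured in
``data/target_profiles.yaml`` (widths: hardness 44, disintegration time
45, flow function 37, cohesion 37, thickness 43).
"""

from __future__ import annotations

import importlib.resources
import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .data_model import CATEGORIES, PROCESS_NUMERIC, SCALAR_PROPS, Dataset, composition_matrix

#: categories whose pairwise products form the interaction block
INTERACTION_CATEGORIES = CATEGORIES[:7]

GEOMETRY_FEATURES = ("r_part_height", "r_part_volume", "inv_weight", "compaction_pressure")


# ---------------------------------------------------------------------------
# material-level derived properties


def carr_index(rho_bulk, rho_tap):
    """Carr compressibility index (%): 100 * (rho_tap - rho_bulk) / rho_tap.

    Both densities in g/mL, rho_tap >= rho_bulk > 0.
    """
    rho_bulk = np.asarray(rho_bulk, dtype=float)
    rho_tap = np.asarray(rho_tap, dtype=float)
    if (rho_bulk <= 0).any() or (rho_tap <= 0).any():
        raise ValueError("densities must be positive")
    if (rho_tap < rho_bulk).any():
        raise ValueError("tapped density below loose bulk density (measurement inconsistency)")
    out = 100.0 * (rho_tap - rho_bulk) / rho_tap
    return float(out) if out.ndim == 0 else out


def hausner_ratio(rho_bulk, rho_tap):
    """Hausner ratio (-): rho_tap / rho_bulk, >= 1."""
    rho_bulk = np.asarray(rho_bulk, dtype=float)
    rho_tap = np.asarray(rho_tap, dtype=float)
    if (rho_bulk <= 0).any() or (rho_tap <= 0).any():
        raise ValueError("densities must be positive")
    if (rho_tap < rho_bulk).any():
        raise ValueError("tapped density below loose bulk density (measurement inconsistency)")
    out = rho_tap / rho_bulk
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# kNN imputation of scalar properties


def impute_scalar_props(materials: pd.DataFrame, k: int = 5) -> pd.DataFrame:
    """Fill missing scalar properties by a k-nearest-neighbour mean.

    Distance between two materials is the Euclidean distance over their
    mutually observed, standardized scalar properties (column-wise mean
    0 / sd 1 over observed values); neighbour ties break by material-id
    order.  A missing entry becomes the mean of the property over the k
    nearest materials that have it; if fewer than k such neighbours
    exist, all available ones are used.  A property missing for every
    material is an error.
    """
    props = [c for c in SCALAR_PROPS if c in materials.columns]
    X = materials[props].astype(float)
    if X.isna().all(axis=None):
        raise ValueError("no scalar property observed for any material")
    for col in props:
        if X[col].isna().all():
            raise ValueError(f"property {col!r} missing for all materials")

    mu = X.mean()
    sd = X.std(ddof=0).replace(0.0, 1.0)
    Z = ((X - mu) / sd).to_numpy()
    ids = list(X.index)
    order = np.argsort([str(i) for i in ids], kind="stable")  # tie-break by id

    out = X.copy()
    n = len(ids)
    for i in range(n):
        missing_cols = np.where(np.isnan(Z[i]))[0]
        if missing_cols.size == 0:
            continue
        dists = np.full(n, np.inf)
        for j in range(n):
            if j == i:
                continue
            both = ~np.isnan(Z[i]) & ~np.isnan(Z[j])
            if not both.any():
                continue
            dists[j] = float(np.sqrt(np.sum((Z[i, both] - Z[j, both]) ** 2)))
        # stable sort on (distance, material_id order)
        rank = sorted(range(n), key=lambda j: (dists[j], str(ids[j])))
        for c in missing_cols:
            donors = [j for j in rank if np.isfinite(dists[j]) and not np.isnan(Z[j, c])]
            if not donors:
                raise ValueError(
                    f"cannot impute {props[c]!r} for {ids[i]!r}: no comparable neighbour"
                )
            if len(donors) < k:
                warnings.warn(
                    f"fewer than {k} complete neighbours for {ids[i]!r}/{props[c]}; using all",
                    stacklevel=2,
                )
            chosen = donors[:k]
            out.iloc[i, out.columns.get_loc(props[c])] = float(
                np.mean([X.iloc[j, c] for j in chosen])
            )
    result = materials.copy()
    result[props] = out
    return result


# ---------------------------------------------------------------------------
# Eq.-style mixture aggregation


def mix_scalar_descriptors(fractions, property_matrix) -> pd.Series:
    """Composition-weighted mixture descriptors: p_mix = sum_i x_i p_i.

    ``fractions`` is indexed by material id; ``property_matrix`` rows are
    materials, columns are (imputed, complete) scalar properties.
    """
    x = pd.Series(fractions, dtype=float)
    P = pd.DataFrame(property_matrix).astype(float)
    P = P.reindex(x.index)
    if P.isna().any(axis=None):
        raise ValueError("property matrix contains missing values; impute first")
    return P.mul(x, axis=0).sum(axis=0)


# ---------------------------------------------------------------------------
# engineered geometry / pressure / ratio features


def r_part_height(curvature_radius_mm: float, diameter_mm: float) -> float:
    """Spherical-cap height of the convex punch face (mm); 0 for flat."""
    if not curvature_radius_mm or np.isnan(curvature_radius_mm):
        return 0.0
    rc, r = float(curvature_radius_mm), float(diameter_mm) / 2.0
    if rc < r:
        raise ValueError("curvature radius smaller than tablet radius")
    return rc - float(np.sqrt(rc**2 - r**2))


def r_part_volume(curvature_radius_mm: float, diameter_mm: float) -> float:
    """Spherical-cap volume of the convex punch face (mm^3); 0 for flat."""
    h = r_part_height(curvature_radius_mm, diameter_mm)
    if h == 0.0:
        return 0.0
    rc = float(curvature_radius_mm)
    return float(np.pi * h**2 * (3 * rc - h) / 3.0)


def compaction_pressure(force_n: float, diameter_mm: float) -> float:
    """Compaction force normalized by flat tablet cross-section (N/mm^2)."""
    if diameter_mm <= 0:
        raise ValueError("diameter must be positive")
    return float(force_n) / (np.pi * (float(diameter_mm) / 2.0) ** 2)


def category_ratios(fractions: pd.Series, categories: pd.Series) -> pd.Series:
    """Mass fraction summed per raw-material category (9 ratios).

    Fractions are already weight-normalized, so each ratio lies in
    [0, 1] and the nine sum to 1 for a fully categorized formulation.
    """
    cat = categories.reindex(fractions.index)
    out = pd.Series(0.0, index=[f"{c}_ratio" for c in CATEGORIES])
    for c in CATEGORIES:
        out[f"{c}_ratio"] = float(fractions[cat == c].sum())
    return out


def interaction_names() -> list[str]:
    return [
        f"{a}_ratio x {b}_ratio"
        for a, b in itertools.combinations(INTERACTION_CATEGORIES, 2)
    ]


def interaction_terms(ratios: pd.Series) -> pd.Series:
    """21 interaction-only products of the first seven category ratios."""
    vals = {}
    for a, b in itertools.combinations(INTERACTION_CATEGORIES, 2):
        vals[f"{a}_ratio x {b}_ratio"] = float(ratios[f"{a}_ratio"] * ratios[f"{b}_ratio"])
    return pd.Series(vals)


def engineered_features(process_row: pd.Series, fractions: pd.Series, categories: pd.Series) -> pd.Series:
    """All engineered features of one formulation.

    Returns r_part_height/volume, 1/weight, compaction pressure, the 9
    category ratios and the 21 interaction terms (35 values).
    """
    w = float(process_row["target_weight_g"])
    if w <= 0:
        raise ValueError("target weight must be positive")
    rc = process_row.get("curvature_radius_mm", np.nan)
    d = float(process_row["tablet_diameter_mm"])
    feats = pd.Series(
        {
            "r_part_height": r_part_height(rc, d),
            "r_part_volume": r_part_volume(rc, d),
            "inv_weight": 1.0 / w,
            "compaction_pressure": compaction_pressure(float(process_row["compaction_force_n"]), d),
        }
    )
    ratios = category_ratios(fractions, categories)
    return pd.concat([feats, ratios, interaction_terms(ratios)])


# ---------------------------------------------------------------------------
# target profiles and block assembly


def load_target_profiles(path=None) -> dict:
    """Per-target descriptor profiles (shipped YAML unless ``path`` given)."""
    if path is not None:
        with open(path) as fh:
            return yaml.safe_load(fh)
    ref = importlib.resources.files("tabletpred").joinpath("data/target_profiles.yaml")
    return yaml.safe_load(ref.read_text())


def _extra_feature(name: str, block: pd.DataFrame) -> pd.Series:
    """Documented padding features of the reconstruction profiles."""
    if name == "pressure_x_inv_weight":
        return block["compaction_pressure"] * block["inv_weight"]
    if name == "lod_x_solubility":
        return block["loss_on_drying"] * block["solubility_score"]
    raise KeyError(f"unknown extra feature {name!r}")


def descriptor_block(
    dataset: Dataset,
    target: str,
    profiles: dict | None = None,
    imputer_k: int = 5,
) -> pd.DataFrame:
    """Per-formulation scalar-descriptor block for one target.

    Columns, in order: mixture scalars of the target's profile, geometry
    features, documented extras, 9 category ratios, 21 interactions.
    Scalar properties are imputed (kNN, k=5) before mixing.
    """
    profiles = profiles or load_target_profiles()
    if target not in profiles:
        raise KeyError(f"no descriptor profile for target {target!r}")
    prof = profiles[target]

    materials = impute_scalar_props(dataset.materials, k=imputer_k)
    wide = composition_matrix(dataset)
    proc = dataset.process.loc[wide.index]

    scalars = prof.get("scalars", [])
    P = materials.loc[wide.columns, scalars].astype(float)
    mixed = pd.DataFrame(wide.to_numpy() @ P.to_numpy(), index=wide.index, columns=scalars)

    # geometry/pressure (vectorized over formulations)
    rc = proc.get("curvature_radius_mm", pd.Series(np.nan, index=proc.index)).fillna(0.0)
    d = proc["tablet_diameter_mm"].astype(float)
    r = d / 2.0
    with np.errstate(invalid="ignore"):
        h = np.where(rc > 0, rc - np.sqrt(np.maximum(rc**2 - r**2, 0.0)), 0.0)
    geom = pd.DataFrame(
        {
            "r_part_height": h,
            "r_part_volume": np.where(h > 0, np.pi * h**2 * (3 * rc - h) / 3.0, 0.0),
            "inv_weight": 1.0 / proc["target_weight_g"].astype(float),
            "compaction_pressure": proc["compaction_force_n"].astype(float)
            / (np.pi * r**2),
        },
        index=proc.index,
    )

    cats = materials["category"]
    ind = pd.DataFrame(
        {f"{c}_ratio": (cats.reindex(wide.columns) == c).astype(float) for c in CATEGORIES}
    )
    ratios = pd.DataFrame(
        wide.to_numpy() @ ind.to_numpy(), index=wide.index, columns=ind.columns
    )
    inter = pd.DataFrame(
        {
            f"{a}_ratio x {b}_ratio": ratios[f"{a}_ratio"] * ratios[f"{b}_ratio"]
            for a, b in itertools.combinations(INTERACTION_CATEGORIES, 2)
        }
    )

    block = pd.concat([mixed, geom[prof.get("geometry", [])]], axis=1)
    pool = pd.concat([mixed, geom, ratios], axis=1)
    for name in prof.get("extras", []):
        block[name] = _extra_feature(name, pool)
    block = pd.concat([block, ratios, inter], axis=1)
    if block.isna().any(axis=None):
        raise ValueError("descriptor block contains missing values after imputation")
    return block


def descriptor_dim(target: str, profiles: dict | None = None) -> int:
    profiles = profiles or load_target_profiles()
    prof = profiles[target]
    return (
        len(prof.get("scalars", []))
        + len(prof.get("geometry", []))
        + len(prof.get("extras", []))
        + len(CATEGORIES)
        + len(interaction_names())
    )
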