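"""Powder indices, imputation, mixture aggregation, engineered features."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tabletpred import descriptors as dsc
from tabletpred.data_model import CATEGORIES, SCALAR_PROPS


@pytest.mark.parametrize(
    "bulk,tap,ci,hr",
    [(0.5, 0.625, 20.0, 1.25), (0.4, 0.4, 0.0, 1.0), (0.3, 0.6, 50.0, 2.0)],
)
def test_carr_index_and_hausner_ratio_formulas(bulk, tap, ci, hr):
    assert dsc.carr_index(bulk, tap) == pytest.approx(ci)
    assert dsc.hausner_ratio(bulk, tap) == pytest.approx(hr)


def test_density_inconsistency_raises():
    with pytest.raises(ValueError):
        dsc.carr_index(0.7, 0.5)
    with pytest.raises(ValueError):
        dsc.hausner_ratio(0.7, 0.5)


# ---------------------------------------------------------------------------
# kNN imputation


def _materials_frame(values):
    df = pd.DataFrame(values, columns=list(SCALAR_PROPS[:4]))
    df.index = [f"M{i:02d}" for i in range(len(df))]
    df.insert(0, "category", "diluent")
    return df


def test_imputation_is_identity_without_missing_values(small_dataset):
    ds, _ = small_dataset
    complete = dsc.impute_scalar_props(ds.materials).pipe(dsc.impute_scalar_props)
    pd.testing.assert_frame_equal(complete, dsc.impute_scalar_props(ds.materials))


def test_constant_neighbourhood_imputes_the_constant():
    vals = np.tile([0.5, 0.6, 20.0, 1.2], (6, 1))
    df = _materials_frame(vals)
    df.iloc[0, df.columns.get_loc("carr_index")] = np.nan
    out = dsc.impute_scalar_props(df, k=5)
    assert out.loc["M00", "carr_index"] == pytest.approx(20.0)


def test_imputation_matches_brute_force_nearest_neighbour_oracle():
    rng = np.random.default_rng(5)
    vals = rng.normal(size=(10, 4)) + np.array([0.5, 0.6, 15.0, 1.3])
    df = _materials_frame(vals)
    miss = [(0, 2), (3, 0), (7, 3)]
    for i, j in miss:
        df.iloc[i, df.columns.get_loc(SCALAR_PROPS[j])] = np.nan
    out = dsc.impute_scalar_props(df, k=5)

    X = df[list(SCALAR_PROPS[:4])].astype(float)
    mu, sd = X.mean(), X.std(ddof=0)
    Z = ((X - mu) / sd).to_numpy()
    for i, j in miss:
        dists = []
        for q in range(len(df)):
            if q == i:
                continue
            both = ~np.isnan(Z[i]) & ~np.isnan(Z[q])
            dists.append((np.sqrt(((Z[i, both] - Z[q, both]) ** 2).sum()), str(df.index[q]), q))
        donors = [q for _, _, q in sorted(dists) if not np.isnan(Z[q, j])][:5]
        expected = np.mean([X.iloc[q, j] for q in donors])
        assert out.iloc[i, out.columns.get_loc(SCALAR_PROPS[j])] == pytest.approx(expected)


def test_property_missing_everywhere_is_an_error():
    df = _materials_frame(np.ones((6, 4)))
    df["flodex"] = np.nan
    with pytest.raises(ValueError, match="flodex"):
        dsc.impute_scalar_props(df)


# ---------------------------------------------------------------------------
# mixture aggregation


def test_single_component_mixture_equals_the_material():
    P = pd.DataFrame({"a": [2.0, 5.0], "b": [1.0, 7.0]}, index=["M1", "M2"])
    x = pd.Series({"M1": 1.0, "M2": 0.0})
    out = dsc.mix_scalar_descriptors(x, P)
    assert out["a"] == 2.0 and out["b"] == 1.0


def test_fifty_fifty_mixture_is_the_midpoint():
    P = pd.DataFrame({"a": [2.0, 4.0]}, index=["M1", "M2"])
    x = pd.Series({"M1": 0.5, "M2": 0.5})
    assert dsc.mix_scalar_descriptors(x, P)["a"] == pytest.approx(3.0)


def test_random_mixture_matches_explicit_loop_sum():
    rng = np.random.default_rng(2)
    P = pd.DataFrame(rng.normal(size=(5, 3)), index=list("ABCDE"), columns=["p", "q", "r"])
    x = rng.dirichlet(np.ones(5))
    xs = pd.Series(x, index=list("ABCDE"))
    out = dsc.mix_scalar_descriptors(xs, P)
    for col in P.columns:
        expected = sum(x[i] * P.iloc[i][col] for i in range(5))
        assert out[col] == pytest.approx(expected, abs=1e-12)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(alpha=st.floats(0.0, 1.0), seed=st.integers(0, 10_000))
def test_mixture_aggregation_is_linear_and_convex(alpha, seed):
    rng = np.random.default_rng(seed)
    P = pd.DataFrame({"p": rng.normal(size=4)}, index=list("ABCD"))
    x1 = pd.Series(rng.dirichlet(np.ones(4)), index=list("ABCD"))
    x2 = pd.Series(rng.dirichlet(np.ones(4)), index=list("ABCD"))
    blend = alpha * x1 + (1 - alpha) * x2
    lhs = dsc.mix_scalar_descriptors(blend, P)["p"]
    rhs = alpha * dsc.mix_scalar_descriptors(x1, P)["p"] + (1 - alpha) * dsc.mix_scalar_descriptors(x2, P)["p"]
    assert lhs == pytest.approx(rhs, abs=1e-10)
    assert P["p"].min() - 1e-10 <= lhs <= P["p"].max() + 1e-10


# ---------------------------------------------------------------------------
# engineered features


def test_inverse_weight_and_compaction_pressure():
    proc = pd.Series(
        {
            "target_weight_g": 0.5,
            "tablet_diameter_mm": 10.0,
            "compaction_force_n": 7854.0,
            "curvature_radius_mm": np.nan,
        }
    )
    fracs = pd.Series({"M1": 1.0})
    cats = pd.Series({"M1": "diluent"})
    feats = dsc.engineered_features(proc, fracs, cats)
    assert feats["inv_weight"] == pytest.approx(2.0)
    assert feats["compaction_pressure"] == pytest.approx(7854.0 / (np.pi * 25.0), rel=1e-6)
    assert feats["r_part_height"] == 0.0 and feats["r_part_volume"] == 0.0


def test_spherical_cap_geometry():
    assert dsc.r_part_height(10.0, 12.0) == pytest.approx(2.0)
    assert dsc.r_part_volume(10.0, 12.0) == pytest.approx(np.pi * 4.0 * 28.0 / 3.0, rel=1e-6)


def test_interaction_block_is_exactly_the_21_pairwise_products():
    ratios = pd.Series(
        {f"{c}_ratio": v for c, v in zip(CATEGORIES, np.linspace(0.05, 0.2, 9))}
    )
    inter = dsc.interaction_terms(ratios)
    assert len(inter) == 21 == len(list(itertools.combinations(CATEGORIES[:7], 2)))
    for (a, b) in itertools.combinations(CATEGORIES[:7], 2):
        assert inter[f"{a}_ratio x {b}_ratio"] == pytest.approx(
            ratios[f"{a}_ratio"] * ratios[f"{b}_ratio"]
        )
    assert not any("_ratio x " + name.split(" x ")[0] == name for name in inter.index)  # no squares


def test_category_ratios_sum_to_one_for_fully_categorized_formulation(small_dataset):
    ds, _ = small_dataset
    from tabletpred.data_model import composition_matrix

    wide = composition_matrix(ds)
    fracs = wide.iloc[0]
    ratios = dsc.category_ratios(fracs, ds.materials["category"])
    assert ((ratios >= 0) & (ratios <= 1)).all()
    assert ratios.sum() == pytest.approx(1.0)


@pytest.mark.parametrize(
    "target,dim",
    [
        ("hardness", 44),
        ("disintegration_time", 45),
        ("flow_function", 37),
        ("cohesion", 37),
        ("thickness", 43),
    ],
)
def test_descriptor_block_dimensionality_per_target(small_dataset, target, dim):
    ds, _ = small_dataset
    block = dsc.descriptor_block(ds, target)
    assert block.shape[1] == dim == dsc.descriptor_dim(target)
    assert not block.isna().any(axis=None)
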