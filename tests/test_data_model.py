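"""Validation rules and the formulation-uniqueness audit."""

import itertools

import numpy as np
import pandas as pd
import pytest

from tabletpred import data_model, synthetic
from tabletpred.data_model import Dataset, audit_uniqueness, validate_tables


def _tiny_dataset(**overrides):
    materials = pd.DataFrame(
        {
            "category": ["diluent", "disintegrant", "lubricant"],
            "loose_bulk_density": [0.5, 0.6, 0.3],
            "tapped_density": [0.625, 0.75, 0.45],
        },
        index=pd.Index(["M1", "M2", "M3"], name="material_id"),
    )
    compositions = pd.DataFrame(
        {
            "formulation_id": ["F1", "F1", "F2", "F2"],
            "material_id": ["M1", "M2", "M1", "M3"],
            "mass_fraction": [0.9, 0.1, 0.8, 0.2],
        }
    )
    process = pd.DataFrame(
        {
            "compaction_force_n": [8000.0, 12000.0],
            "punch_type": ["flat", "convex"],
            "tablet_diameter_mm": [10.0, 10.0],
            "target_weight_g": [0.4, 0.4],
            "curvature_radius_mm": [np.nan, 12.0],
            "fill_depth_mm": [8.0, 8.0],
            "time_index": [0, 1],
        },
        index=pd.Index(["F1", "F2"], name="formulation_id"),
    )
    targets = pd.DataFrame(
        {"formulation_id": ["F1", "F2"], "target": ["hardness"] * 2, "value": [100.0, 150.0]}
    )
    parts = dict(materials=materials, compositions=compositions, process=process, targets=targets)
    parts.update(overrides)
    return Dataset(**parts)


def test_clean_tables_have_no_findings_and_validation_is_idempotent():
    ds = _tiny_dataset()
    clean, report = validate_tables(ds)
    assert report.ok and not report.findings
    clean2, report2 = validate_tables(clean)
    assert not report2.findings


def test_unknown_material_reference_is_a_referential_integrity_error():
    ds = _tiny_dataset()
    ds.compositions.loc[0, "material_id"] = "M999"
    _, report = validate_tables(ds)
    assert any(f.code == "ref-integrity" for f in report.errors)


def test_kgf_force_column_converts_to_newtons():
    ds = _tiny_dataset()
    proc = ds.process.drop(columns="compaction_force_n")
    proc["compaction_force_kgf"] = [450.0, 450.0]
    ds = _tiny_dataset(process=proc)
    clean, report = validate_tables(ds)
    assert report.ok
    assert clean.process["compaction_force_n"].iloc[0] == pytest.approx(4412.99, abs=0.01)


def test_exact_duplicate_rows_are_flagged():
    ds = _tiny_dataset()
    ds.compositions = pd.concat([ds.compositions, ds.compositions.iloc[[0]]], ignore_index=True)
    # keep the duplicated formulation's sum valid by duplicating its whole block
    ds.compositions.loc[len(ds.compositions)] = ["F1", "M2", 0.1]
    _, report = validate_tables(ds)
    dup = [f for f in report.findings if f.code == "duplicates" and "compositions" in f.message]
    assert dup


@pytest.mark.parametrize(
    "deviation,expect_error,expect_warning",
    [(0.0, False, False), (5e-4, False, True), (0.05, True, False)],
)
def test_composition_sum_tolerance(deviation, expect_error, expect_warning):
    ds = _tiny_dataset()
    ds.compositions.loc[0, "mass_fraction"] += deviation
    clean, report = validate_tables(ds)
    assert any(f.code == "composition-sum" for f in report.errors) == expect_error
    assert any(f.code == "composition-renormalized" for f in report.warnings) == expect_warning
    if not expect_error:
        sums = clean.compositions.groupby("formulation_id")["mass_fraction"].sum()
        assert np.allclose(sums, 1.0, atol=1e-9)


def test_tapped_below_bulk_density_is_an_error():
    ds = _tiny_dataset()
    ds.materials.loc["M1", "tapped_density"] = 0.4
    _, report = validate_tables(ds)
    assert any(f.code == "density-order" for f in report.errors)


def test_missing_time_index_falls_back_to_row_order_with_warning():
    ds = _tiny_dataset()
    ds = _tiny_dataset(process=ds.process.drop(columns="time_index"))
    clean, report = validate_tables(ds)
    assert any(f.code == "time-index-imputed" for f in report.warnings)
    assert list(clean.process["time_index"]) == [0, 1]


# ---------------------------------------------------------------------------
# uniqueness audit


def test_distinct_compositions_count_distinctly():
    ds = _tiny_dataset()
    u = audit_uniqueness(ds)
    assert (u.n_observations, u.n_unique_compositions, u.n_unique_composition_process) == (2, 2, 2)


def test_same_composition_different_force_unique_only_with_process():
    ds = _tiny_dataset()
    ds.compositions = pd.DataFrame(
        {
            "formulation_id": ["F1", "F1", "F2", "F2"],
            "material_id": ["M1", "M2", "M1", "M2"],
            "mass_fraction": [0.9, 0.1, 0.9, 0.1],
        }
    )
    u = audit_uniqueness(ds)
    assert (u.n_observations, u.n_unique_compositions, u.n_unique_composition_process) == (2, 1, 2)


def test_uniqueness_counts_match_brute_force_pairwise_oracle():
    cfg = synthetic.SyntheticConfig(n_formulations=10, seed=3)
    ds, _ = synthetic.generate(cfg)
    # create 4 repeated compositions: copy F0001's composition into 4 rows
    comp = ds.compositions
    donor = comp[comp["formulation_id"] == "F0001"]
    for fid in ["F0002", "F0003", "F0004", "F0005"]:
        comp = comp[comp["formulation_id"] != fid]
        block = donor.copy()
        block["formulation_id"] = fid
        comp = pd.concat([comp, block], ignore_index=True)
    ds.compositions = comp
    u = audit_uniqueness(ds, target="hardness")

    # oracle: exhaustive pairwise comparison of rounded composition maps
    wide = data_model.composition_matrix(ds).round(10)
    fids = list(ds.targets.loc[ds.targets["target"] == "hardness", "formulation_id"])
    classes = []
    for f in fids:
        for cls in classes:
            if (wide.loc[f] == wide.loc[cls[0]]).all():
                cls.append(f)
                break
        else:
            classes.append([f])
    assert u.n_unique_compositions == len(classes)
    assert u.n_observations == len(fids)


def test_uniqueness_with_process_is_at_least_without(small_dataset):
    ds, _ = small_dataset
    u = audit_uniqueness(ds, target="hardness")
    assert u.n_unique_compositions <= u.n_unique_composition_process <= u.n_observations
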