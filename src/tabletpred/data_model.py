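"""Canonical tables for tablet-formulation datasets.

A dataset is five tables keyed by opaque identifiers:

* ``materials`` -- one row per raw material: a category label and scalar
  powder properties (densities, Carr index, Hausner ratio, FLODEX,
  loss on drying and three ordinal scores), any of which may be missing.
* ``psd`` -- optional particle-size distributions, one 80-point frequency
  vector per material on the shared log-spaced diameter grid.
* ``compositions`` -- long-format mass fractions (formulation, material,
  fraction); fractions of a formulation sum to one.
* ``process`` -- per-formulation tableting settings (compaction force,
  punch type, tablet diameter, target weight, curvature radius, fill
  depth) plus an integer acquisition order ``time_index``.
* ``targets`` -- long-format measured responses (formulation, target,
  value) for the five modelled tablet/powder properties.

:func:`validate_tables` enforces the ingestion rules (required fields,
unit normalization, referential integrity, duplicates, composition sums)
and :func:`audit_uniqueness` reports formulation-level uniqueness counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Raw-material categories.  The first seven drive the interaction block.
CATEGORIES = (
    "diluent",
    "disintegrant",
    "polyol",
    "lubricant",
    "binder",
    "glidant",
    "granule",
    "main_component",
    "other",
)

#: Scalar powder properties stored per material (units in parentheses):
#: loose bulk density (g/mL), tapped density (g/mL), Carr index (%),
#: Hausner ratio (-), FLODEX (mm), loss on drying (%), and three ordinal
#: scores (solubility, lipophilicity, flowability contribution).
SCALAR_PROPS = (
    "loose_bulk_density",
    "tapped_density",
    "carr_index",
    "hausner_ratio",
    "flodex",
    "loss_on_drying",
    "solubility_score",
    "lipophilic_score",
    "flowability_score",
)

#: Numeric process/geometry settings (canonical units: N, mm, g).
PROCESS_NUMERIC = (
    "compaction_force_n",
    "tablet_diameter_mm",
    "target_weight_g",
    "curvature_radius_mm",
    "fill_depth_mm",
)

PUNCH_COLUMN = "punch_type"
TIME_COLUMN = "time_index"

TARGET_NAMES = (
    "hardness",
    "disintegration_time",
    "flow_function",
    "cohesion",
    "thickness",
)

#: Targets that must be strictly positive.
POSITIVE_TARGETS = ("hardness", "disintegration_time", "thickness")

KGF_TO_N = 9.80665

COMPOSITION_TOL = 1e-9
#: compositions summing to 1 within this tolerance are renormalized with a
#: warning; larger deviations are rejected.
RENORM_TOL = 1e-3

#: decimal places used when canonicalizing compositions for uniqueness
UNIQ_DECIMALS = 10


@dataclass
class Dataset:
    """The five canonical tables (see module docstring)."""

    materials: pd.DataFrame
    compositions: pd.DataFrame
    process: pd.DataFrame
    targets: pd.DataFrame
    psd: pd.DataFrame | None = None  # index material_id, 80 freq columns

    @property
    def material_ids(self) -> list[str]:
        return sorted(self.materials.index.astype(str))

    @property
    def formulation_ids(self) -> list[str]:
        return list(self.process.index.astype(str))


@dataclass
class Finding:
    severity: str  # "error" | "warning"
    code: str
    message: str


@dataclass
class ValidationReport:
    findings: list[Finding] = field(default_factory=list)

    def add(self, severity: str, code: str, message: str) -> None:
        self.findings.append(Finding(severity, code, message))

    @property
    def errors(self) -> list[Finding]:
        return [f for f in self.findings if f.severity == "error"]

    @property
    def warnings(self) -> list[Finding]:
        return [f for f in self.findings if f.severity == "warning"]

    @property
    def ok(self) -> bool:
        return not self.errors


@dataclass
class UniquenessCounts:
    """Formulation-level uniqueness audit for one target's observations."""

    n_observations: int
    n_unique_compositions: int
    n_unique_composition_process: int | None = None


def composition_matrix(dataset: Dataset) -> pd.DataFrame:
    """Wide composition matrix: formulations x all known materials.

    Columns are material ids in lexical order; absent pairs are 0.
    Row order follows ``dataset.process`` (acquisition order).
    """
    wide = dataset.compositions.pivot_table(
        index="formulation_id",
        columns="material_id",
        values="mass_fraction",
        aggfunc="sum",
        fill_value=0.0,
    )
    wide = wide.reindex(
        index=dataset.process.index, columns=dataset.material_ids, fill_value=0.0
    )
    wide.columns = wide.columns.astype(str)
    return wide.astype(float)


def _check_required_columns(
    df: pd.DataFrame, required: tuple[str, ...], table: str, report: ValidationReport
) -> bool:
    missing = [c for c in required if c not in df.columns]
    if missing:
        report.add("error", "missing-columns", f"{table}: missing required columns {missing}")
        return False
    return True


def validate_tables(dataset: Dataset, permissive: bool = False) -> tuple[Dataset, ValidationReport]:
    """Validate and clean the five tables.

    Returns the cleaned dataset (units normalized, compositions
    renormalized within tolerance, duplicates reported) and a report
    listing every finding.  Referential-integrity violations and
    compositions deviating from a unit sum beyond ``RENORM_TOL`` are
    errors; the cleaned dataset should only be used when ``report.ok``.

    With ``permissive=False`` unknown columns are rejected.
    """
    report = ValidationReport()
    materials = dataset.materials.copy()
    compositions = dataset.compositions.copy()
    process = dataset.process.copy()
    targets = dataset.targets.copy()
    psd = None if dataset.psd is None else dataset.psd.copy()

    # --- materials -------------------------------------------------------
    if "category" not in materials.columns:
        report.add("error", "missing-columns", "materials: missing 'category'")
    else:
        bad = set(materials["category"]) - set(CATEGORIES)
        if bad:
            report.add("error", "bad-category", f"materials: unknown categories {sorted(bad)}")
    known_mat_cols = {"category", *SCALAR_PROPS}
    extra = [c for c in materials.columns if c not in known_mat_cols]
    if extra and not permissive:
        report.add("error", "unknown-columns", f"materials: unknown columns {extra}")

    for col in ("loose_bulk_density", "tapped_density"):
        if col in materials.columns:
            vals = materials[col].dropna()
            if (vals <= 0).any():
                report.add("error", "out-of-range", f"materials: non-positive {col}")
    if {"loose_bulk_density", "tapped_density"} <= set(materials.columns):
        both = materials[["loose_bulk_density", "tapped_density"]].dropna()
        bad_rows = both.index[both["tapped_density"] < both["loose_bulk_density"]]
        if len(bad_rows):
            report.add(
                "error",
                "density-order",
                f"materials: tapped < loose bulk density for {list(map(str, bad_rows))}",
            )

    n_dup = int(materials.reset_index().duplicated().sum())
    if n_dup:
        report.add("warning", "duplicates", f"materials: {n_dup} exact duplicate row(s)")

    # --- psd -------------------------------------------------------------
    if psd is not None and len(psd):
        sums = psd.sum(axis=1)
        off = sums[(sums - 1.0).abs() > COMPOSITION_TOL]
        renorm = off[(off - 1.0).abs() <= RENORM_TOL]
        if len(renorm):
            psd.loc[renorm.index] = psd.loc[renorm.index].div(renorm, axis=0)
            report.add(
                "warning", "psd-renormalized", f"psd: renormalized {len(renorm)} distribution(s)"
            )
        bad = off[(off - 1.0).abs() > RENORM_TOL]
        if len(bad):
            report.add(
                "error", "psd-sum", f"psd: frequencies far from unit sum for {list(bad.index)}"
            )
        if (psd.to_numpy() < 0).any():
            report.add("error", "psd-negative", "psd: negative frequencies")
        unknown = set(psd.index.astype(str)) - set(materials.index.astype(str))
        if unknown:
            report.add("error", "ref-integrity", f"psd: unknown material ids {sorted(unknown)}")

    # --- compositions ----------------------------------------------------
    if _check_required_columns(
        compositions, ("formulation_id", "material_id", "mass_fraction"), "compositions", report
    ):
        unknown = set(compositions["material_id"].astype(str)) - set(
            materials.index.astype(str)
        )
        if unknown:
            report.add(
                "error",
                "ref-integrity",
                f"compositions: reference unknown material ids {sorted(unknown)}",
            )
        if (compositions["mass_fraction"] < 0).any():
            report.add("error", "out-of-range", "compositions: negative mass fractions")

        n_dup = int(compositions.duplicated().sum())
        if n_dup:
            report.add("warning", "duplicates", f"compositions: {n_dup} exact duplicate row(s)")

        sums = compositions.groupby("formulation_id")["mass_fraction"].sum()
        off = sums[(sums - 1.0).abs() > COMPOSITION_TOL]
        renorm_ids = off[(off - 1.0).abs() <= RENORM_TOL].index
        if len(renorm_ids):
            scale = compositions["formulation_id"].map(sums)
            mask = compositions["formulation_id"].isin(renorm_ids)
            compositions.loc[mask, "mass_fraction"] /= scale[mask]
            report.add(
                "warning",
                "composition-renormalized",
                f"compositions: renormalized {len(renorm_ids)} formulation(s)",
            )
        bad_ids = off[(off - 1.0).abs() > RENORM_TOL].index
        if len(bad_ids):
            report.add(
                "error",
                "composition-sum",
                f"compositions: mass fractions far from unit sum for {sorted(map(str, bad_ids))}",
            )

    # --- process ---------------------------------------------------------
    if "compaction_force_kgf" in process.columns and "compaction_force_n" not in process.columns:
        process["compaction_force_n"] = process.pop("compaction_force_kgf") * KGF_TO_N
        report.add("warning", "unit-converted", "process: compaction force converted kgf -> N")
    known_proc = {*PROCESS_NUMERIC, PUNCH_COLUMN, TIME_COLUMN}
    extra = [c for c in process.columns if c not in known_proc]
    if extra and not permissive:
        report.add("error", "unknown-columns", f"process: unknown columns {extra}")
    for col, label in (
        ("compaction_force_n", "compaction force"),
        ("tablet_diameter_mm", "tablet diameter"),
        ("target_weight_g", "target weight"),
    ):
        if col in process.columns and (process[col].dropna() <= 0).any():
            report.add("error", "out-of-range", f"process: non-positive {label}")
    if TIME_COLUMN not in process.columns:
        process[TIME_COLUMN] = np.arange(len(process))
        report.add(
            "warning",
            "time-index-imputed",
            "process: no time_index column; using file row order",
        )

    n_dup = int(process.reset_index().duplicated().sum())
    if n_dup:
        report.add("warning", "duplicates", f"process: {n_dup} exact duplicate row(s)")

    # --- targets ---------------------------------------------------------
    if _check_required_columns(targets, ("formulation_id", "target", "value"), "targets", report):
        bad = set(targets["target"]) - set(TARGET_NAMES)
        if bad:
            report.add("error", "bad-target", f"targets: unknown target names {sorted(bad)}")
        if (~np.isfinite(targets["value"].astype(float))).any():
            report.add("error", "out-of-range", "targets: non-finite values")
        for name in POSITIVE_TARGETS:
            vals = targets.loc[targets["target"] == name, "value"]
            if (vals <= 0).any():
                report.add("error", "out-of-range", f"targets: non-positive {name} values")
        unknown = set(targets["formulation_id"].astype(str)) - set(process.index.astype(str))
        if unknown:
            report.add(
                "error",
                "ref-integrity",
                f"targets: reference unknown formulation ids {sorted(unknown)[:5]}",
            )

    clean = Dataset(
        materials=materials, compositions=compositions, process=process, targets=targets, psd=psd
    )
    return clean, report


def _composition_key(fracs: pd.Series) -> tuple:
    """Canonical composition key: sorted (material, rounded fraction) pairs."""
    items = [
        (str(m), round(float(v), UNIQ_DECIMALS))
        for m, v in fracs.items()
        if round(float(v), UNIQ_DECIMALS) != 0.0
    ]
    return tuple(sorted(items))


def _process_key(row: pd.Series) -> tuple:
    vals = []
    for col in (*PROCESS_NUMERIC, PUNCH_COLUMN):
        if col in row.index:
            v = row[col]
            vals.append(None if pd.isna(v) else (round(float(v), UNIQ_DECIMALS) if not isinstance(v, str) else v))
    return tuple(vals)


def audit_uniqueness(
    dataset: Dataset, target: str | None = None, include_process: bool = True
) -> UniquenessCounts:
    """Count unique formulations among a target's observations.

    Uniqueness is exact equality of the canonicalized composition map
    (fractions rounded to 10 decimals, zero entries dropped); with
    ``include_process`` the process tuple participates as well.

    ``target=None`` audits every observation in ``targets``.
    """
    targets = dataset.targets
    if target is not None:
        targets = targets[targets["target"] == target]
    wide = composition_matrix(dataset)

    comp_keys = {}
    for fid in wide.index:
        comp_keys[str(fid)] = _composition_key(wide.loc[fid])

    obs_fids = targets["formulation_id"].astype(str).tolist()
    n_obs = len(obs_fids)
    n_unique_comp = len({comp_keys[f] for f in obs_fids})
    n_unique_comp_proc = None
    if include_process:
        proc_keys = {str(f): _process_key(dataset.process.loc[f]) for f in dataset.process.index}
        n_unique_comp_proc = len({(comp_keys[f], proc_keys[f]) for f in obs_fids})
    return UniquenessCounts(n_obs, n_unique_comp, n_unique_comp_proc)


# ---------------------------------------------------------------------------
# CSV round-trip


def load_dataset(
    materials_csv,
    compositions_csv,
    process_csv,
    targets_csv,
    psd_csv=None,
) -> Dataset:
    """Read the canonical CSV tables (see docs/schemas for layouts)."""
    materials = pd.read_csv(materials_csv, index_col="material_id")
    compositions = pd.read_csv(compositions_csv)
    process = pd.read_csv(process_csv, index_col="formulation_id")
    targets = pd.read_csv(targets_csv)
    psd = None
    if psd_csv is not None:
        psd = pd.read_csv(psd_csv, index_col="material_id")
        if {"diameter_um", "frequency"} <= set(psd.reset_index().columns):
            # long layout
            long = pd.read_csv(psd_csv)
            psd = long.pivot(index="material_id", columns="diameter_um", values="frequency")
            psd = psd.sort_index(axis=1)
    return Dataset(
        materials=materials, compositions=compositions, process=process, targets=targets, psd=psd
    )


def save_dataset(dataset: Dataset, outdir) -> None:
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    dataset.materials.to_csv(out / "materials.csv", index_label="material_id")
    dataset.compositions.to_csv(out / "compositions.csv", index=False)
    dataset.process.to_csv(out / "process.csv", index_label="formulation_id")
    dataset.targets.to_csv(out / "targets.csv", index=False)
    if dataset.psd is not None:
        dataset.psd.to_csv(out / "psd.csv", index_label="material_id")
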