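"""Schema-faithful synthetic formulation datasets with known ground truth.

The generator emulates the structure of a pre-formulation development
database: a small library of raw materials grouped into excipient
categories (default counts: 8 diluents, 9 disintegrants, 4 polyols,
4 lubricants, 2 binders, 2 glidants = 29 materials) with scalar powder
properties and two-component lognormal-mixture PSDs on the shared
80-point grid, a stream of time-ordered formulations (compositions
sampled from per-category templates with Dirichlet perturbation,
compaction force uniform in 4400-19,600 N, two punch types), and
targets produced by documented closed-form response surfaces plus
Gaussian noise.  Scalar properties and PSDs are censored at stated
missingness rates.  An optional drift transform shifts post-onset
compositions and introduces a reserve material unused before onset.

All randomness flows from one master seed through named substreams, so
materials, formulations and noise are independently reproducible.  The
returned ground truth stores every coefficient and the noiseless target
values for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data_model import Dataset, composition_matrix
from .descriptors import carr_index, hausner_ratio
from .psd import FINE_THRESHOLD_UM, default_grid

DEFAULT_CATEGORY_COUNTS = {
    "diluent": 8,
    "disintegrant": 9,
    "polyol": 4,
    "lubricant": 4,
    "binder": 2,
    "glidant": 2,
}

#: per-category means for (loose bulk density g/mL, Hausner ratio,
#: FLODEX mm, loss-on-drying %, PSD median um); truncated-normal draws
#: around these.  Chosen as typical excipient values, with no claim of
#: matching any proprietary dataset.
CATEGORY_PROFILES = {
    "diluent": (0.45, 1.25, 12.0, 3.5, 90.0),
    "disintegrant": (0.55, 1.35, 16.0, 5.0, 55.0),
    "polyol": (0.65, 1.20, 10.0, 1.0, 150.0),
    "lubricant": (0.30, 1.45, 22.0, 2.5, 12.0),
    "binder": (0.40, 1.40, 20.0, 4.0, 70.0),
    "glidant": (0.25, 1.55, 28.0, 1.5, 8.0),
    "granule": (0.55, 1.15, 8.0, 3.0, 250.0),
    "main_component": (0.50, 1.40, 18.0, 4.0, 40.0),
    "other": (0.50, 1.30, 15.0, 3.0, 60.0),
}

FORCE_RANGE_N = (4400.0, 19600.0)
PUNCH_TYPES = ("flat", "convex")


@dataclass
class DriftConfig:
    """Temporal drift after ``onset`` (fraction of the stream).

    The drift is a ramp, not a step: the usage of a reserve
    disintegrant (absent before onset) and the tilt of the category
    balance both grow linearly from the onset to the end of the stream,
    emulating progressive formulation renewal where the newest rows are
    always the most novel."""

    onset: float = 0.6
    composition_shift: float = 0.5  # 0..1, strength of the tilt
    introduce_material: bool = True


@dataclass
class SyntheticConfig:
    n_per_category: dict = field(default_factory=lambda: dict(DEFAULT_CATEGORY_COUNTS))
    n_formulations: int = 600
    scalar_missing_rate: float = 0.10
    psd_missing_rate: float = 0.15
    #: per-target noise scales (hardness N, DT lognormal sd, flow -, cohesion kPa, thickness mm)
    noise_sd: dict = field(
        default_factory=lambda: {
            "hardness": 8.0,
            "disintegration_time": 0.12,
            "flow_function": 0.8,
            "cohesion": 0.05,
            "thickness": 0.02,
        }
    )
    target_mode: str = "mechanistic"  # or "null"
    drift: DriftConfig | None = None
    seed: int = 0


def _streams(seed: int) -> dict[str, np.random.Generator]:
    root = np.random.SeedSequence(seed)
    names = ("materials", "psd", "missing", "formulations", "process", "noise")
    children = root.spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def gen_materials(config: SyntheticConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Materials table and PSD table (before missingness is applied
    scalar properties are mutually consistent: CI/HR derive from the
    drawn densities)."""
    rngs = _streams(config.seed)
    rng = rngs["materials"]
    rng_psd = rngs["psd"]
    rng_miss = rngs["missing"]
    grid = default_grid()
    log_grid = np.log(grid)

    rows = {}
    psd_rows = {}
    for cat, n in config.n_per_category.items():
        mu_bulk, mu_hr, mu_flodex, mu_lod, med_um = CATEGORY_PROFILES[cat]
        for i in range(n):
            mid = f"{cat[:3].upper()}{i + 1:02d}"
            bulk = float(np.clip(rng.normal(mu_bulk, 0.06), 0.15, 1.2))
            hr = float(np.clip(rng.normal(mu_hr, 0.08), 1.02, 1.9))
            tap = bulk * hr
            rows[mid] = {
                "category": cat,
                "loose_bulk_density": bulk,
                "tapped_density": tap,
                "carr_index": carr_index(bulk, tap),
                "hausner_ratio": hausner_ratio(bulk, tap),
                "flodex": float(np.clip(rng.normal(mu_flodex, 3.0), 4.0, 34.0)),
                "loss_on_drying": float(np.clip(rng.normal(mu_lod, 0.8), 0.1, 8.0)),
                "solubility_score": int(rng.integers(0, 3)),
                "lipophilic_score": int(rng.integers(0, 2)),
                "flowability_score": int(rng.integers(-1, 2)),
            }
            # two-component lognormal mixture on the log grid
            med = med_um * float(np.exp(rng.normal(0, 0.25)))
            sigma = float(rng.uniform(0.35, 0.7))
            fines_frac = float(rng.uniform(0.05, 0.35))
            fines_med = float(np.clip(med * 0.12, grid[0] * 2, 30.0))
            dens = (1 - fines_frac) * np.exp(
                -0.5 * ((log_grid - np.log(med)) / sigma) ** 2
            ) + fines_frac * np.exp(-0.5 * ((log_grid - np.log(fines_med)) / 0.45) ** 2)
            psd_rows[mid] = dens / dens.sum()

    materials = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    materials.index.name = "material_id"
    psd = pd.DataFrame.from_dict(psd_rows, orient="index").sort_index()
    psd.index.name = "material_id"
    psd.columns = [f"d_{d:.4g}um" for d in grid]

    # censor scalar properties (never all of a property)
    props = [c for c in materials.columns if c != "category"]
    for col in props:
        mask = rng_miss.random(len(materials)) < config.scalar_missing_rate
        if mask.all():
            mask[0] = False
        materials.loc[mask, col] = np.nan
    # censor whole PSDs
    psd_missing = rng_miss.random(len(psd)) < config.psd_missing_rate
    if psd_missing.all():
        psd_missing[0] = False
    psd = psd.loc[~psd_missing]
    return materials, psd


def _reserve_material(materials: pd.DataFrame) -> str:
    """The drift reserve: last disintegrant in id order (excluded from
    pre-onset composition sampling)."""
    dis = sorted(materials.index[materials["category"] == "disintegrant"])
    return dis[-1]


#: (mean fraction, sd) of each category's share in a formulation
CATEGORY_SHARE = {
    "diluent": (0.55, 0.10),
    "disintegrant": (0.08, 0.03),
    "polyol": (0.22, 0.08),
    "lubricant": (0.012, 0.004),
    "binder": (0.04, 0.015),
    "glidant": (0.006, 0.002),
    "granule": (0.0, 0.0),
    "main_component": (0.0, 0.0),
    "other": (0.0, 0.0),
}


def gen_formulations(
    config: SyntheticConfig, materials: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compositions (long) and process tables for the formulation stream."""
    rngs = _streams(config.seed)
    rng = rngs["formulations"]
    rng_proc = rngs["process"]
    reserve = _reserve_material(materials)
    by_cat = {
        c: sorted(m for m in materials.index[materials["category"] == c] if m != reserve)
        for c in CATEGORY_SHARE
    }

    comp_rows = []
    proc_rows = {}
    n = config.n_formulations
    onset_row = int(config.drift.onset * n) if config.drift else n
    for t in range(n):
        fid = f"F{t + 1:04d}"
        drifted = config.drift is not None and t >= onset_row
        # ramp in (0, 1]: how far past the onset this row sits
        ramp = (t - onset_row + 1) / max(n - onset_row, 1) if drifted else 0.0
        shift = (config.drift.composition_shift * ramp) if drifted else 0.0
        weights = {}
        for cat, (mu, sd) in CATEGORY_SHARE.items():
            pool = by_cat.get(cat, [])
            if not pool or mu == 0.0:
                continue
            if cat == "diluent":
                mu = mu * (1.0 - 0.4 * shift)  # diluents give way to the newcomer
            elif cat == "polyol":
                mu = mu * (1.0 + 0.5 * shift)
            share = max(float(rng.normal(mu, sd)), 0.001)
            picks = list(rng.choice(pool, size=min(2, len(pool)) if cat == "diluent" else 1, replace=False))
            if drifted and cat == "diluent":
                # tilt toward the lexically-last diluents
                picks = [pool[-1 - i] for i in range(len(picks))]
            alpha = rng.dirichlet(np.ones(len(picks)) * 5.0)
            for m, a in zip(picks, alpha):
                weights[m] = weights.get(m, 0.0) + share * float(a)
        if drifted and config.drift.introduce_material:
            weights[reserve] = 0.04 + 0.30 * shift
        total = sum(weights.values())
        for m, w in sorted(weights.items()):
            comp_rows.append(
                {"formulation_id": fid, "material_id": m, "mass_fraction": w / total}
            )

        punch = PUNCH_TYPES[int(rng_proc.integers(0, 2))]
        diameter = float(rng_proc.choice([8.0, 10.0, 12.0]))
        proc_rows[fid] = {
            "compaction_force_n": float(rng_proc.uniform(*FORCE_RANGE_N)),
            "punch_type": punch,
            "tablet_diameter_mm": diameter,
            "target_weight_g": float(rng_proc.uniform(0.25, 0.60)),
            "curvature_radius_mm": (
                float(diameter * rng_proc.uniform(0.8, 1.3)) if punch == "convex" else np.nan
            ),
            "fill_depth_mm": float(rng_proc.uniform(6.0, 12.0)),
            "time_index": t,
        }

    compositions = pd.DataFrame(comp_rows)
    process = pd.DataFrame.from_dict(proc_rows, orient="index")
    process.index.name = "formulation_id"
    return compositions, process


def _complete_materials(config: SyntheticConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Uncensored materials/PSD tables (the generator's latent truth)."""
    full_cfg = replace(config, scalar_missing_rate=0.0, psd_missing_rate=0.0)
    return gen_materials(full_cfg)


def gen_targets(
    materials: pd.DataFrame,
    psd: pd.DataFrame,
    compositions: pd.DataFrame,
    process: pd.DataFrame,
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, dict]:
    """Targets from documented closed-form response surfaces.

    Mechanistic mode (coefficients in the returned ground truth):

    * hardness [N] = h0 + h1 * pressure + h2 * (HR_mix - 1.1)^2
      + h3 * binder_ratio - noise sd ``noise_sd['hardness']``;
    * disintegration time [min] = exp(g0 + g1 * hardness*
      - g2 * disintegrant_ratio - g3 * fines) with lognormal noise,
      strictly decreasing in the disintegrant ratio;
    * flow function [-] = f0 + f1 * flowability_mix - f2 * fines
      + f3 * glidant_ratio;
    * cohesion [kPa] = c0 + c1 * fines - c2 * flowability_mix;
    * thickness [mm] = 10 * weight / (rho_eff * area_cm2),
      rho_eff = r0 + r1 * pressure + r2 * (HR_mix - 1).

    The latent (uncensored) material properties drive the surfaces, so
    the descriptor pipeline can genuinely recover them.  Null mode makes
    every target a linear function of process settings and raw
    composition columns only (descriptors carry no signal).
    """
    rng_noise = _streams(config.seed)["noise"]
    full_mats, full_psd = _complete_materials(config)
    ds = Dataset(
        materials=full_mats,
        compositions=compositions,
        process=process,
        targets=pd.DataFrame(columns=["formulation_id", "target", "value"]),
        psd=full_psd,
    )
    wide = composition_matrix(ds)
    proc = process.loc[wide.index]
    grid = default_grid()

    pressure = proc["compaction_force_n"].to_numpy() / (
        np.pi * (proc["tablet_diameter_mm"].to_numpy() / 2.0) ** 2
    )
    hr_mix = (wide.to_numpy() @ full_mats.loc[wide.columns, "hausner_ratio"].to_numpy())
    flow_mix = (wide.to_numpy() @ full_mats.loc[wide.columns, "flowability_score"].to_numpy())
    cats = full_mats["category"]
    dis_ratio = wide.to_numpy() @ (cats.reindex(wide.columns) == "disintegrant").to_numpy(float)
    bin_ratio = wide.to_numpy() @ (cats.reindex(wide.columns) == "binder").to_numpy(float)
    gli_ratio = wide.to_numpy() @ (cats.reindex(wide.columns) == "glidant").to_numpy(float)
    P = full_psd.reindex(wide.columns).to_numpy(float)
    mixed_psd = wide.to_numpy() @ P
    mixed_psd /= mixed_psd.sum(axis=1, keepdims=True)
    fines = mixed_psd[:, grid <= FINE_THRESHOLD_UM].sum(axis=1)

    coeffs: dict[str, dict] = {}
    noiseless: dict[str, np.ndarray] = {}
    sd = config.noise_sd

    if config.target_mode == "mechanistic":
        coeffs["hardness"] = {"h0": 15.0, "h1": 0.55, "h2": 900.0, "h3": 250.0}
        c = coeffs["hardness"]
        hard = c["h0"] + c["h1"] * pressure + c["h2"] * (hr_mix - 1.1) ** 2 + c["h3"] * bin_ratio
        noiseless["hardness"] = hard

        coeffs["disintegration_time"] = {"g0": 0.9, "g1": 0.008, "g2": 6.0, "g3": 2.5}
        g = coeffs["disintegration_time"]
        noiseless["disintegration_time"] = np.exp(
            g["g0"] + g["g1"] * hard - g["g2"] * dis_ratio - g["g3"] * fines
        )

        coeffs["flow_function"] = {"f0": 9.0, "f1": 3.0, "f2": 14.0, "f3": 250.0}
        f = coeffs["flow_function"]
        noiseless["flow_function"] = (
            f["f0"] + f["f1"] * flow_mix - f["f2"] * fines + f["f3"] * gli_ratio
        )

        coeffs["cohesion"] = {"c0": 0.30, "c1": 1.6, "c2": 0.06}
        cc = coeffs["cohesion"]
        noiseless["cohesion"] = cc["c0"] + cc["c1"] * fines - cc["c2"] * flow_mix

        coeffs["thickness"] = {"r0": 0.85, "r1": 0.0012, "r2": 0.4}
        r = coeffs["thickness"]
        rho_eff = r["r0"] + r["r1"] * pressure + r["r2"] * (hr_mix - 1.0)
        area_cm2 = np.pi * (proc["tablet_diameter_mm"].to_numpy() / 20.0) ** 2
        noiseless["thickness"] = 10.0 * proc["target_weight_g"].to_numpy() / (rho_eff * area_cm2)
    elif config.target_mode == "null":
        # null surfaces: driven solely by fill depth, a process setting
        # that sits in MP directly and from which no descriptor or PSD
        # summary is derived -- the augmented blocks are pure nuisance
        fill = proc["fill_depth_mm"].to_numpy()
        coeffs["null"] = {"a0": 40.0, "a1": 6.0}
        a = coeffs["null"]
        noiseless["hardness"] = a["a0"] + a["a1"] * fill
        noiseless["disintegration_time"] = 2.0 + 0.8 * fill
        noiseless["flow_function"] = 4.0 + 0.6 * fill
        noiseless["cohesion"] = 0.2 + 0.04 * fill
        noiseless["thickness"] = 2.0 + 0.15 * fill
    else:
        raise ValueError(f"unknown target_mode {config.target_mode!r}")

    rows = []
    for name, mu in noiseless.items():
        scale = sd.get(name, 0.0)
        if name == "disintegration_time" and config.target_mode == "mechanistic":
            vals = mu * np.exp(rng_noise.normal(0.0, scale, size=len(mu)))
        else:
            vals = mu + rng_noise.normal(0.0, scale, size=len(mu))
            vals = np.maximum(vals, 1e-3) if name in ("hardness", "thickness") else vals
        for fid, v in zip(wide.index, vals):
            rows.append({"formulation_id": fid, "target": name, "value": float(v)})
    targets = pd.DataFrame(rows)
    ground_truth = {
        "mode": config.target_mode,
        "coefficients": coeffs,
        "noiseless": {k: v.tolist() for k, v in noiseless.items()},
        "formulation_ids": list(wide.index),
    }
    return targets, ground_truth


def generate(config: SyntheticConfig) -> tuple[Dataset, dict]:
    """Full synthetic dataset plus ground-truth record."""
    materials, psd = gen_materials(config)
    compositions, process = gen_formulations(config, materials)
    targets, ground_truth = gen_targets(materials, psd, compositions, process, config)
    ds = Dataset(
        materials=materials, compositions=compositions, process=process, targets=targets, psd=psd
    )
    return ds, ground_truth
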