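"""Particle-size distributions on the shared 80-point diameter grid.

Laser-diffraction PSDs are stored as frequency vectors aligned to a
common geometric grid of 80 diameters from 0.115 um to 5000 um.  Mixture
PSDs are composition-weighted averages of the component PSDs (materials
with no measured PSD contribute a zero vector), renormalized so that the
non-missing contributions sum to one.  An 80-dim mixture PSD is reduced
to exactly ten summary statistics for modelling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

GRID_MIN_UM = 0.115
GRID_MAX_UM = 5000.0
GRID_SIZE = 80

#: Column names of the ten-summary block, in fixed order.
SUMMARY_NAMES = (
    "PSD d10 (um)",
    "PSD d50 (um)",
    "PSD d90 (um)",
    "PSD mean (um)",
    "PSD std (um)",
    "PSD skewness",
    "PSD kurtosis",
    "PSD fraction <= 25 um",
    "PSD fraction >= 150 um",
    "PSD entropy",
)

FINE_THRESHOLD_UM = 25.0
COARSE_THRESHOLD_UM = 150.0


def default_grid() -> np.ndarray:
    """The shared geometric diameter grid (um), 0.115 .. 5000, 80 points."""
    return np.geomspace(GRID_MIN_UM, GRID_MAX_UM, GRID_SIZE)


def validate_distribution(freq: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    freq = np.asarray(freq, dtype=float)
    if freq.shape != (GRID_SIZE,):
        raise ValueError(f"distribution must have {GRID_SIZE} bins, got {freq.shape}")
    if (freq < 0).any():
        raise ValueError("negative PSD frequencies")
    s = freq.sum()
    if abs(s - 1.0) > tol:
        raise ValueError(f"PSD frequencies sum to {s!r}, expected 1")
    return freq


def mix_psd(
    fractions: np.ndarray | pd.Series,
    material_psds: np.ndarray,
    missing_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Composition-weighted mixture PSD.

    ``material_psds`` is (n_materials, 80); rows flagged in
    ``missing_mask`` (or containing NaN) are treated as zero vectors so
    they do not contribute, and the result is renormalized to unit sum.

    Raises ``ValueError`` when every component with positive fraction is
    missing (the mixture PSD is undefined).
    """
    x = np.asarray(fractions, dtype=float)
    P = np.asarray(material_psds, dtype=float)
    if missing_mask is None:
        missing_mask = np.isnan(P).any(axis=1)
    missing_mask = np.asarray(missing_mask, dtype=bool)
    P = np.where(missing_mask[:, None], 0.0, np.nan_to_num(P))
    mixed = x @ P
    total = mixed.sum()
    if total <= 0:
        raise ValueError("all components with nonzero fraction lack a PSD")
    return mixed / total


def mixture_psd_matrix(fractions: pd.DataFrame, psd: pd.DataFrame) -> pd.DataFrame:
    """Vectorized mixture PSDs for many formulations.

    ``fractions``: formulations x material ids (wide composition matrix);
    ``psd``: material id -> 80 frequencies (rows may be absent = missing).
    """
    mats = fractions.columns
    P = psd.reindex(mats).to_numpy(dtype=float)
    missing = np.isnan(P).any(axis=1)
    P = np.where(missing[:, None], 0.0, np.nan_to_num(P))
    mixed = fractions.to_numpy(dtype=float) @ P
    totals = mixed.sum(axis=1)
    if (totals <= 0).any():
        bad = fractions.index[totals <= 0]
        raise ValueError(f"formulations with no PSD information: {list(bad)[:5]}")
    mixed = mixed / totals[:, None]
    return pd.DataFrame(mixed, index=fractions.index)


def _weighted_quantile(freq: np.ndarray, grid: np.ndarray, q: float, log_space: bool) -> float:
    """Quantile of a discrete PSD by interpolating the cumulative mass.

    Interpolation is linear in log-diameter by default (PSDs live on a
    log grid); a point mass returns its own diameter.
    """
    cum = np.cumsum(freq)
    d = np.log(grid) if log_space else grid
    if q <= cum[0]:
        out = d[0]
    else:
        out = np.interp(q, cum, d)
    return float(np.exp(out)) if log_space else float(out)


@dataclass
class PSDSummaryOptions:
    """Conventions for the summary statistics (defaults documented in
    docs/methods.md): quantiles interpolated in log-diameter, moments in
    linear diameter, excess kurtosis, natural-log entropy."""

    quantiles_in_log: bool = True
    moments_in_log: bool = False
    excess_kurtosis: bool = True
    entropy_base: float = np.e


def summarize_psd(
    freq: np.ndarray,
    grid: np.ndarray | None = None,
    options: PSDSummaryOptions | None = None,
) -> dict[str, float]:
    """The ten PSD summary statistics of a distribution.

    d10/d50/d90 (um), frequency-weighted mean/std/skewness/excess
    kurtosis of diameter, mass fractions at <=25 um and >=150 um
    (inclusive, evaluated at grid points), and Shannon entropy
    (-sum p ln p).  For a point mass the quantiles equal that diameter
    and skewness/kurtosis are defined as 0.
    """
    if grid is None:
        grid = default_grid()
    opts = options or PSDSummaryOptions()
    p = validate_distribution(freq)
    grid = np.asarray(grid, dtype=float)

    d = np.log(grid) if opts.moments_in_log else grid
    mean = float(p @ d)
    var = float(p @ (d - mean) ** 2)
    std = float(np.sqrt(var))
    if std > 0:
        skew = float(p @ (d - mean) ** 3) / std**3
        kurt = float(p @ (d - mean) ** 4) / std**4
        if opts.excess_kurtosis:
            kurt -= 3.0
    else:
        skew = kurt = 0.0  # degenerate convention

    if std == 0.0:
        # point mass: all quantiles collapse onto the occupied bin
        d_at = float(grid[np.argmax(p)])
        d10 = d50 = d90 = d_at
    else:
        d10 = _weighted_quantile(p, grid, 0.10, opts.quantiles_in_log)
        d50 = _weighted_quantile(p, grid, 0.50, opts.quantiles_in_log)
        d90 = _weighted_quantile(p, grid, 0.90, opts.quantiles_in_log)

    with np.errstate(divide="ignore", invalid="ignore"):
        logs = np.where(p > 0, np.log(p), 0.0)
    entropy = float(-(p * logs).sum() / np.log(opts.entropy_base))

    if opts.moments_in_log:
        mean = float(np.exp(mean))  # report geometric mean in um

    return {
        "PSD d10 (um)": d10,
        "PSD d50 (um)": d50,
        "PSD d90 (um)": d90,
        "PSD mean (um)": mean,
        "PSD std (um)": std,
        "PSD skewness": skew,
        "PSD kurtosis": kurt,
        "PSD fraction <= 25 um": float(p[grid <= FINE_THRESHOLD_UM].sum()),
        "PSD fraction >= 150 um": float(p[grid >= COARSE_THRESHOLD_UM].sum()),
        "PSD entropy": entropy,
    }


def summarize_psd_matrix(
    psd_matrix: pd.DataFrame,
    grid: np.ndarray | None = None,
    options: PSDSummaryOptions | None = None,
) -> pd.DataFrame:
    """Row-wise :func:`summarize_psd` for a formulations x 80 matrix."""
    rows = {
        idx: summarize_psd(psd_matrix.loc[idx].to_numpy(), grid, options)
        for idx in psd_matrix.index
    }
    out = pd.DataFrame.from_dict(rows, orient="index")
    return out[list(SUMMARY_NAMES)]
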