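"""Across-specimen consistency of coarse (27-sector) staining patterns.

Each specimen's 27 sector intensities are standardized to mean 0, SD 1,
removing global staining-intensity differences between individuals.  For
every sector, a two-sided one-sample t test across specimens then asks
whether that sector's standardized intensity deviates consistently from the
specimen mean; the 27 p-values of a marker are adjusted together with the
Benjamini–Hochberg step-up procedure and thresholded at q < 0.05.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .grid_io import SectorGrid


def standardize_sectors(grid: SectorGrid) -> pd.DataFrame:
    """Demean and scale a grid's sector intensities to mean 0, sample SD 1.

    Returns the (i, j, k, z) frame; raises on zero variance (a perfectly
    flat grid carries no pattern to compare).
    """
    rec = grid.included
    y = rec["y"].to_numpy(float)
    if len(y) < 2 or np.unique(y).size < 2:
        raise ValueError("standardization requires >= 2 distinct sector values")
    z = (y - y.mean()) / y.std(ddof=1)
    out = rec[["i", "j", "k"]].copy()
    out["z"] = z
    return out.reset_index(drop=True)


@dataclasses.dataclass
class ConsistencyResult:
    """Per-sector t/p/q values for one marker across specimens."""

    marker: str
    table: pd.DataFrame  # columns i, j, k, t, p, q, significant
    n_specimens: int


def sector_ttests(marker: str, standardized: list[pd.DataFrame],
                  q_threshold: float = 0.05) -> ConsistencyResult:
    """One-sample t tests (vs 0, df = n-1) per sector, BH-adjusted.

    ``standardized`` holds one (i, j, k, z) frame per specimen with a common
    sector layout.  A sector whose cross-specimen values are identically
    zero is a perfect null (t = 0, p = 1); one with zero variance around a
    nonzero mean has an undefined t and is flagged and excluded from the
    FDR family.
    """
    if len(standardized) < 2:
        raise ValueError("need >= 2 specimens")
    merged = standardized[0][["i", "j", "k"]].copy()
    mat = []
    for s, df in enumerate(standardized):
        df = df.sort_values(["i", "j", "k"]).reset_index(drop=True)
        if not df[["i", "j", "k"]].equals(
                merged.sort_values(["i", "j", "k"]).reset_index(drop=True)):
            raise ValueError("sector layouts differ across specimens")
        mat.append(df["z"].to_numpy())
    Z = np.vstack(mat)  # specimens x sectors
    n = Z.shape[0]
    mean = Z.mean(axis=0)
    t = np.full(Z.shape[1], np.nan)
    p = np.full(Z.shape[1], np.nan)
    # a sector identical across specimens has no sampling variance
    nonzero_sd = np.ptp(Z, axis=0) > 0
    tt = stats.ttest_1samp(Z[:, nonzero_sd], popmean=0.0, axis=0)
    t[nonzero_sd] = tt.statistic
    p[nonzero_sd] = tt.pvalue
    null_flat = (~nonzero_sd) & (mean == 0)
    t[null_flat] = 0.0
    p[null_flat] = 1.0
    qv, sig = fdr_adjust(p[~np.isnan(p)], q_threshold)
    q = np.full_like(p, np.nan)
    s = np.zeros(len(p), bool)
    q[~np.isnan(p)] = qv
    s[~np.isnan(p)] = sig
    layout = standardized[0].sort_values(["i", "j", "k"]).reset_index(drop=True)
    table = layout[["i", "j", "k"]].copy()
    table["t"], table["p"], table["q"], table["significant"] = t, p, q, s
    return ConsistencyResult(marker=marker, table=table, n_specimens=n)


def fdr_adjust(pvalues: np.ndarray,
               q_threshold: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg adjusted q-values and ``q < threshold`` flags."""
    p = np.asarray(pvalues, float)
    if p.size == 0:
        return np.array([]), np.array([], bool)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values outside [0, 1]")
    _, q, _, _ = multipletests(p, alpha=q_threshold, method="fdr_bh")
    return q, q < q_threshold


def run_consistency(grids: list[SectorGrid],
                    q_threshold: float = 0.05) -> list[ConsistencyResult]:
    """Standardize and test all markers present in ``grids`` (adjusting each
    marker's 27 sectors as its own FDR family)."""
    by_marker: dict[str, list[pd.DataFrame]] = {}
    for g in sorted(grids, key=lambda g: (g.marker, g.specimen_id)):
        by_marker.setdefault(g.marker, []).append(standardize_sectors(g))
    return [sector_ttests(marker, frames, q_threshold)
            for marker, frames in sorted(by_marker.items())]
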