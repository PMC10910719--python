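"""Bin-level quality control.

Bins where read counts do not scale linearly with copy number (poor
mappability, extreme GC, collapsed repeats) are identified on a reference
population of diploid cells and masked before any per-cell inference.  The
pipeline is: per-cell normalisation -> per-bin median across cells (per
sequencing technology) -> hard thresholds -> smooth-trend residual and
density filters -> intersection of per-technology masks and blacklists.

QC is usually run at fine resolution (100 kb) and the resulting mask
aggregated onto the coarser analysis grid (500 kb).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.stats import gaussian_kde

from .exceptions import EmptyCellError, TooFewBinsError
from .grid import BinGrid, CellCounts

#: default thresholds (config keys qc.*)
MEDIAN_HI = 4.0
MEDIAN_LO = 0.10
MAPPABILITY_MIN = 70.0
SD_MULT = 2.0
DENSITY_QUANTILE = 0.99
AGGREGATE_INVALID_FRACTION = 0.5


def normalize_cell_counts(counts: CellCounts, grid: BinGrid) -> np.ndarray:
    """Divide a cell's per-bin counts by its mean count over valid bins.

    Returns a vector aligned to the full grid; the mean of the returned
    values over valid bins is exactly 1.
    """
    x = np.asarray(counts.counts, float)
    if len(x) != grid.n_bins:
        raise ValueError("counts not aligned to grid")
    valid = grid.valid
    mean = x[valid].mean() if valid.any() else 0.0
    if mean <= 0:
        raise EmptyCellError(f"empty cell {counts.cell_id!r}")
    return x / mean


def median_bin_quality(norm: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Element-wise median of normalised counts across cells (rows).

    The caller is responsible for grouping cells by sequencing technology and
    calling this once per group.
    """
    arr = np.asarray(norm, float)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.shape[0] < 1:
        raise ValueError("need at least one cell")
    return np.median(arr, axis=0)


def hard_filter(
    medians: np.ndarray,
    grid: BinGrid,
    median_hi: float = MEDIAN_HI,
    median_lo: float = MEDIAN_LO,
    mappability_min: float = MAPPABILITY_MIN,
) -> np.ndarray:
    """Boolean removal mask for the threshold stage.

    A bin is removed if its median normalised count exceeds ``median_hi``,
    falls below ``median_lo``, or its mappability is below
    ``mappability_min`` (union of the three conditions).
    """
    medians = np.asarray(medians, float)
    return (
        (medians > median_hi)
        | (medians < median_lo)
        | (grid.mappability < mappability_min)
    )


def _spline_basis(x: np.ndarray, df: int = 6, degree: int = 3) -> np.ndarray:
    """Cubic B-spline design matrix with ``df`` basis functions."""
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi <= lo:
        return np.ones((len(x), 1))
    n_interior = max(df - degree - 1, 0)
    interior = np.quantile(x, np.linspace(0, 1, n_interior + 2)[1:-1]) if n_interior else np.array([])
    # pad the boundary knots slightly so all points are strictly interior
    eps = 1e-9 * (hi - lo) + 1e-12
    t = np.r_[[lo - eps] * (degree + 1), interior, [hi + eps] * (degree + 1)]
    return BSpline.design_matrix(x, t, degree).toarray()


def _smooth_fit(x: np.ndarray, y: np.ndarray, df: int = 6) -> np.ndarray:
    """Least-squares smooth trend of y on x (additive-model style smoother)."""
    B = _spline_basis(x, df=df)
    coef, *_ = np.linalg.lstsq(B, y, rcond=None)
    return B @ coef


def _low_density_mask(x: np.ndarray, y: np.ndarray, quantile: float) -> np.ndarray:
    """True for points outside the top-``quantile`` high-density region of a
    2-D kernel density estimate over (x, y)."""
    pts = np.vstack([x, y])
    # standardise to give both axes equal weight in the KDE bandwidth
    sd = pts.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    try:
        dens = gaussian_kde((pts - pts.mean(axis=1, keepdims=True)) / sd)(
            (pts - pts.mean(axis=1, keepdims=True)) / sd
        )
    except np.linalg.LinAlgError:
        return np.zeros(len(x), bool)
    return dens < np.quantile(dens, 1.0 - quantile)


def smooth_residual_filter(
    medians: np.ndarray,
    grid: BinGrid,
    keep: np.ndarray | None = None,
    sd_mult: float = SD_MULT,
    density_quantile: float = DENSITY_QUANTILE,
    mode: str = "full",
    df: int = 6,
) -> np.ndarray:
    """Removal mask from the smooth-trend residual and density criteria.

    Fits a smooth trend of the per-bin median against GC content and against
    mappability (additive spline smoother) and removes bins whose residual
    deviates by more than ``sd_mult`` standard deviations.  Additionally
    removes bins outside the high-density region (top ``density_quantile``
    mass) of 2-D kernel density estimates over (gc, median) and
    (mappability, median).

    Parameters
    ----------
    keep
        Boolean mask of bins surviving the hard filter; only those enter the
        fit.  Removed-by-hard-filter bins are reported as not-removed here
        (they are already gone).
    mode
        ``"full"`` applies both criteria; ``"density_only"`` applies only the
        KDE criterion (the X-chromosome mode).
    """
    medians = np.asarray(medians, float)
    if keep is None:
        keep = np.ones(len(medians), bool)
    idx = np.flatnonzero(keep)
    if len(idx) < 50:
        raise TooFewBinsError(f"too few bins for trend fit ({len(idx)} < 50)")
    med = medians[idx]
    gc = grid.gc[idx]
    mp = grid.mappability[idx]

    removal = np.zeros(len(medians), bool)
    if mode not in ("full", "density_only"):
        raise ValueError(f"unknown mode {mode!r}")

    if mode == "full":
        trend = _smooth_fit(gc, med, df=df) + _smooth_fit(mp, med - _smooth_fit(gc, med, df=df), df=df)
        resid = med - trend
        sd = resid.std()
        if sd > 1e-9 * max(1.0, float(np.abs(med).max())):
            removal[idx[np.abs(resid) > sd_mult * sd]] = True

    if np.ptp(med) > 0:
        removal[idx[_low_density_mask(gc, med, density_quantile)]] = True
        removal[idx[_low_density_mask(mp, med, density_quantile)]] = True
    return removal


def total_count_filter(bin_totals: np.ndarray, sd_mult: float = SD_MULT) -> np.ndarray:
    """Removal mask based only on deviations of total read counts per bin.

    Used for the Y chromosome, where per-cell counts are too sparse for the
    median-based criteria.  Deviations are measured robustly (MAD-scaled)
    around the median total.
    """
    totals = np.asarray(bin_totals, float)
    med = np.median(totals)
    mad = np.median(np.abs(totals - med)) * 1.4826
    if mad == 0:
        return np.zeros(len(totals), bool)
    return np.abs(totals - med) > sd_mult * mad


def combine_technology_masks(
    masks: list[np.ndarray], blacklist: np.ndarray | None = None
) -> np.ndarray:
    """Final validity mask: a bin is valid iff valid in *every* technology
    mask and not blacklisted.

    Parameters
    ----------
    masks
        List of boolean *validity* masks (True = keep), one per technology.
    blacklist
        Optional boolean mask of bins to exclude (True = remove), e.g.
        centromere/telomere regions.
    """
    if not masks:
        raise ValueError("need at least one mask")
    n = len(masks[0])
    for m in masks:
        if len(m) != n:
            raise ValueError("masks have mismatched lengths")
    valid = np.logical_and.reduce([np.asarray(m, bool) for m in masks])
    if blacklist is not None:
        if len(blacklist) != n:
            raise ValueError("blacklist has mismatched length")
        valid &= ~np.asarray(blacklist, bool)
    return valid


def aggregate_mask(
    fine_valid: np.ndarray,
    fine_grid: BinGrid,
    coarse_grid: BinGrid,
    invalid_fraction: float = AGGREGATE_INVALID_FRACTION,
) -> np.ndarray:
    """Aggregate a fine-resolution validity mask onto a coarser grid.

    A coarse bin is invalid iff more than ``invalid_fraction`` of the fine
    bins it covers are invalid (fine bins with no coarse parent are ignored).
    """
    fine_valid = np.asarray(fine_valid, bool)
    centers = (fine_grid.start + fine_grid.end) // 2
    parent = coarse_grid.bin_of(fine_grid.chrom, centers)
    out = np.ones(coarse_grid.n_bins, bool)
    for j in range(coarse_grid.n_bins):
        sel = parent == j
        if not np.any(sel):
            out[j] = False
            continue
        frac_invalid = 1.0 - fine_valid[sel].mean()
        out[j] = frac_invalid <= invalid_fraction
    return out


def reference_qc_mask(
    cells: list[CellCounts],
    grid: BinGrid,
    blacklist: np.ndarray | None = None,
    median_hi: float = MEDIAN_HI,
    median_lo: float = MEDIAN_LO,
    mappability_min: float = MAPPABILITY_MIN,
    sd_mult: float = SD_MULT,
    density_quantile: float = DENSITY_QUANTILE,
) -> np.ndarray:
    """End-to-end QC on a diploid reference population.

    Groups cells by technology, runs the hard and smooth filters per group,
    and intersects the per-technology masks (and optional blacklist).
    Returns the final validity mask over the grid.
    """
    tech = {}
    for c in cells:
        tech.setdefault(c.technology, []).append(c)
    masks = []
    for cells_t in tech.values():
        norm = np.vstack([normalize_cell_counts(c, grid) for c in cells_t])
        medians = median_bin_quality(norm)
        removed = hard_filter(medians, grid, median_hi, median_lo, mappability_min)
        removed |= smooth_residual_filter(
            medians, grid, keep=~removed, sd_mult=sd_mult, density_quantile=density_quantile
        )
        masks.append(~removed)
    return combine_technology_masks(masks, blacklist=blacklist)
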