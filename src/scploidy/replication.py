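"""Detection of replicating (S-phase) cells.

A cell in S phase has replicated its early-replicating genome but not yet its
late-replicating genome, so within a copy-number segment the read counts
carry a transient trend in replication time.  Per segment l we compute a
partial Spearman rank correlation tau_l between counts and replication time,
controlling for the GC/mappability bias coefficient s(gc, map) obtained from
a per-cell negative-binomial generalised additive model

    log mu_j = beta0 + beta1 * nu_j + s(gc_j, map_j),

where nu_j is the bin's segment level.  The per-cell *cycling activity* is
the segment-length-weighted median of the tau_l.  Across a population the
activity distribution is symmetric around ~0 for non-replicating cells with
a positive tail of S-phase cells; the classification threshold is the
population median plus 1.5 left-half standard deviations.  A conditional
mutual-information measure between counts and replication time (given copy
number state) catches individual outliers via the boxplot rule
(Q3 + 1.5 IQR).  No training data is required.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.interpolate import BSpline
from scipy.stats import rankdata

from .exceptions import TooFewBinsError
from .grid import BinGrid, CellCounts
from .segment import SegmentedProfile, segment_pelt

ACTIVITY_SD_MULT = 1.5

#: penalty scale of the conservative segmentation used for the trend test.
#: Replication inflation is a transient sub-copy-step signal that must stay
#: *inside* segments for the within-segment trend to be visible; the
#: ploidy-stage segmentation (low penalty plus split repair) would chase the
#: few-bin replication domains and erase the trend.
CYCLE_PENALTY_SCALE = 2.5
MI_IQR_MULT = 1.5
MIN_GAM_BINS = 500
MIN_STATE_BINS = 50
MI_RT_BINS = 4
MI_COUNT_BINS = 10


@dataclass
class GamBias:
    """Per-bin GC/mappability bias on the log-mean scale (centered)."""

    s: np.ndarray  # per analysis bin
    beta0: float
    beta1: float
    fallback: bool = False  # True when the additive (non-tensor) basis was used


@dataclass
class CyclingResult:
    """Per-cell replication summary."""

    tau: np.ndarray  # per-segment partial Spearman statistic
    seg_lengths: np.ndarray
    activity: float  # length-weighted median of tau
    mi: float  # conditional mutual information (nats)


def _bspline_basis(x: np.ndarray, df: int, degree: int = 3) -> np.ndarray:
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi <= lo:
        return np.ones((len(x), 1))
    n_interior = max(df - degree - 1, 0)
    interior = (
        np.quantile(x, np.linspace(0, 1, n_interior + 2)[1:-1]) if n_interior else np.array([])
    )
    eps = 1e-9 * (hi - lo) + 1e-12
    t = np.r_[[lo - eps] * (degree + 1), interior, [hi + eps] * (degree + 1)]
    return BSpline.design_matrix(x, t, degree).toarray()


def _estimate_glm_alpha(y: np.ndarray, mu: np.ndarray) -> float:
    """Moment estimate of NB overdispersion from a fitted mean."""
    num = np.sum((y - mu) ** 2 - mu)
    den = np.sum(mu**2)
    return max(1e-8, float(num / den)) if den > 0 else 1e-8


def fit_gc_map_gam(
    counts: np.ndarray,
    nu: np.ndarray,
    grid: BinGrid,
    basis_df: int = 4,
    min_bins: int = MIN_GAM_BINS,
    ridge: float = 0.01,
) -> GamBias:
    """Per-cell NB regression-spline GAM of counts on (nu, gc, mappability).

    The GC/mappability surface is a tensor product of cubic B-spline bases
    (``basis_df`` functions per margin) with a light ridge penalty on the
    smooth coefficients (penalised regression splines); if the bivariate fit
    fails, additive univariate smooths are used and the result flagged.
    Inputs are over the grid's valid bins; the returned ``s`` is centered to
    mean zero.
    """
    valid = grid.valid
    y = np.asarray(counts)[valid].astype(float)
    nu = np.asarray(nu, float)
    if len(nu) != len(y):
        raise ValueError("nu must align with the valid bins")
    if len(y) < min_bins:
        raise TooFewBinsError(f"GAM needs >= {min_bins} valid bins, got {len(y)}")
    gc = grid.gc[valid]
    mp = grid.mappability[valid]

    Bg = _bspline_basis(gc, basis_df)
    Bm = _bspline_basis(mp, basis_df)
    tensor = np.einsum("ij,ik->ijk", Bg, Bm).reshape(len(y), -1)
    additive = np.hstack([Bg, Bm])

    for smooth, fallback in ((tensor, False), (additive, True)):
        S = smooth - smooth.mean(axis=0, keepdims=True)
        # drop numerically dependent columns
        q, r = np.linalg.qr(S)
        keep = np.abs(np.diag(r)) > 1e-8 * max(1.0, np.abs(np.diag(r)).max())
        S = S[:, keep]
        X = np.column_stack([np.ones(len(y)), nu, S])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pois = sm.GLM(y, X, family=sm.families.Poisson()).fit(maxiter=100)
                alpha = _estimate_glm_alpha(y, pois.fittedvalues)
                mod = sm.GLM(y, X, family=sm.families.NegativeBinomial(alpha=alpha))
                if ridge > 0:
                    pen = np.zeros(X.shape[1])
                    pen[2:] = ridge  # penalise only the smooth block
                    res = mod.fit_regularized(
                        method="elastic_net", alpha=pen, L1_wt=0.0, maxiter=200
                    )
                else:
                    res = mod.fit(start_params=pois.params, maxiter=100)
            params = res.params
        except Exception:
            if fallback:
                raise
            continue
        if not np.all(np.isfinite(params)):
            if fallback:
                raise RuntimeError("GAM fit produced non-finite coefficients")
            continue
        s_vals = S @ params[2:]
        s_vals = s_vals - s_vals.mean()
        return GamBias(s=s_vals, beta0=float(params[0]), beta1=float(params[1]), fallback=fallback)
    raise RuntimeError("unreachable")


def partial_spearman_trend(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> float:
    """Partial Spearman correlation of x and y controlling for z.

    tau = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2)) where the r are
    Spearman (midrank) correlations.  Returns 0 when x or y has no variance
    or when a control correlation is (numerically) perfect.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    z = np.asarray(z, float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0
    rx = rankdata(x)
    ry = rankdata(y)
    rz = rankdata(z)

    def corr(a, b):
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            return 0.0
        return float(np.corrcoef(a, b)[0, 1])

    r_xy = corr(rx, ry)
    r_xz = corr(rx, rz)
    r_yz = corr(ry, rz)
    den = (1.0 - r_xz**2) * (1.0 - r_yz**2)
    if den <= 1e-12:
        return 0.0
    return float(np.clip((r_xy - r_xz * r_yz) / np.sqrt(den), -1.0, 1.0))


def weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Lower weighted median: smallest v with cumulative weight >= half."""
    values = np.asarray(values, float)
    weights = np.asarray(weights, float)
    order = np.argsort(values)
    v = values[order]
    w = weights[order]
    cum = np.cumsum(w)
    return float(v[np.searchsorted(cum, 0.5 * w.sum())])


def cycling_activity(tau: np.ndarray, lengths: np.ndarray) -> float:
    """Length-weighted median of the per-segment trend statistics."""
    tau = np.asarray(tau, float)
    lengths = np.asarray(lengths, float)
    ok = np.isfinite(tau)
    if not np.any(ok):
        raise ValueError("no valid segment statistics")
    return weighted_median(tau[ok], lengths[ok])


def segment_trend_statistics(
    counts: np.ndarray,
    profile: SegmentedProfile,
    grid: BinGrid,
    gam: GamBias,
    min_seg_len: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-segment tau_l and lengths for segments of at least ``min_seg_len``."""
    valid = grid.valid
    y = np.asarray(counts)[valid].astype(float)
    rt = grid.reptime[valid]
    taus, lens = [], []
    for a, b in zip(profile.starts, profile.ends):
        if b - a < min_seg_len:
            continue
        order = np.argsort(rt[a:b], kind="stable")
        taus.append(
            partial_spearman_trend(y[a:b][order], rt[a:b][order], gam.s[a:b][order])
        )
        lens.append(b - a)
    return np.asarray(taus, float), np.asarray(lens, float)


def dynamic_threshold(
    activities: np.ndarray, sd_mult: float = ACTIVITY_SD_MULT, refine: int = 0
) -> float:
    """Population cutoff: median + sd_mult * left-half SD.

    The left-half SD is the root mean squared deviation from the median over
    cells at or below the median (the reflected left half), so a positive
    S-phase tail does not inflate the spread estimate.  When the replicating
    fraction is large even the median is dragged into the tail; passing
    ``refine`` > 0 recomputes the cutoff on the cells below the previous one
    (used by the population classifier), at the cost of shifting the cutoff
    ~10% low on a purely symmetric population.
    """
    a = np.asarray(activities, float)
    if len(a) < 20:
        raise ValueError("need >= 20 cells to estimate the activity threshold")

    def one_pass(v):
        med = float(np.median(v))
        left = v[v <= med]
        sd_left = float(np.sqrt(np.mean((left - med) ** 2)))
        return med + sd_mult * sd_left

    cutoff = one_pass(a)
    for _ in range(refine):
        kept = a[a <= cutoff]
        if len(kept) < 20 or len(kept) == len(a):
            break
        cutoff = one_pass(kept)
    return cutoff


def _discretize(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Quantile-bin with duplicate edges dropped (ties collapse bins)."""
    uniq = np.unique(x)
    if len(uniq) <= n_bins:
        return np.searchsorted(uniq, x)
    edges = np.unique(np.quantile(x, np.linspace(0, 1, n_bins + 1)))[1:-1]
    return np.searchsorted(edges, x, side="right")


def _plugin_mi(a: np.ndarray, b: np.ndarray) -> float:
    """Plug-in mutual information (nats) of two discrete vectors."""
    tab = pd.crosstab(a, b).to_numpy(float)
    p = tab / tab.sum()
    pa = p.sum(axis=1, keepdims=True)
    pb = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log(p / (pa * pb))
    return float(np.nansum(terms))


def mutual_information_measure(
    counts: np.ndarray,
    reptime: np.ndarray,
    cn: np.ndarray,
    n_rt_bins: int = MI_RT_BINS,
    n_count_bins: int = MI_COUNT_BINS,
    min_state_bins: int = MIN_STATE_BINS,
) -> float:
    """Mutual information between counts and replication time given CN state.

    Within each copy-number state holding at least ``min_state_bins`` bins,
    replication time is quantile-binned (default quartiles) and counts
    quantile-binned (default deciles), and the plug-in empirical MI is
    computed; states are combined weighted by their bin fraction.  All three
    inputs align on the same bins.
    """
    counts = np.asarray(counts, float)
    reptime = np.asarray(reptime, float)
    cn = np.asarray(cn)
    if not (len(counts) == len(reptime) == len(cn)):
        raise ValueError("inputs must align")
    total = 0.0
    weight = 0.0
    for state in np.unique(cn):
        sel = cn == state
        n = int(sel.sum())
        if n < min_state_bins:
            continue
        a = _discretize(counts[sel], n_count_bins)
        b = _discretize(reptime[sel], n_rt_bins)
        total += n * _plugin_mi(a, b)
        weight += n
    return total / weight if weight > 0 else 0.0


def mi_outlier_threshold(mis: np.ndarray, iqr_mult: float = MI_IQR_MULT) -> float:
    """Boxplot upper fence of the population MI values: Q3 + iqr_mult * IQR."""
    mis = np.asarray(mis, float)
    q1, q3 = np.quantile(mis, [0.25, 0.75])
    return float(q3 + iqr_mult * (q3 - q1))


def classify_s_phase(
    activities: np.ndarray,
    mis: np.ndarray,
    sd_mult: float = ACTIVITY_SD_MULT,
    iqr_mult: float = MI_IQR_MULT,
) -> pd.DataFrame:
    """Unsupervised population-wide S-phase call.

    A cell is S phase iff its cycling activity exceeds the dynamic population
    threshold OR its conditional MI exceeds the boxplot upper fence.  Returns
    a frame with per-cell calls, the firing branch, and the thresholds used.
    """
    activities = np.asarray(activities, float)
    mis = np.asarray(mis, float)
    cutoff = dynamic_threshold(activities, sd_mult=sd_mult, refine=1)
    mi_cut = mi_outlier_threshold(mis, iqr_mult=iqr_mult)
    by_act = activities > cutoff
    by_mi = mis > mi_cut
    reason = np.where(
        by_act & by_mi, "activity+mi", np.where(by_act, "activity", np.where(by_mi, "mi", ""))
    )
    return pd.DataFrame(
        {
            "cycling_activity": activities,
            "mi": mis,
            "activity_threshold": cutoff,
            "mi_threshold": mi_cut,
            "s_phase": by_act | by_mi,
            "reason": reason,
        }
    )


def cycle_segmentation(counts, grid: BinGrid) -> SegmentedProfile:
    """Conservative copy-number segmentation for the trend test (no split
    repair, higher penalty, so replication domains stay within segments)."""
    if isinstance(counts, np.ndarray):
        counts = CellCounts(cell_id="cycle", counts=counts)
    return segment_pelt(
        counts, grid, penalty_scale=CYCLE_PENALTY_SCALE, repair_threshold=None
    )


def cell_cycle_features(
    counts: np.ndarray,
    grid: BinGrid,
    rho: float,
    profile: SegmentedProfile | None = None,
    cn: np.ndarray | None = None,
) -> dict:
    """The four per-cell features used by supervised replication classifiers.

    Returns rho (read depth per copy), a global overdispersion estimate, the
    cycling activity, and the conditional MI measure.  Training a classifier
    on these is downstream of this package.  ``profile`` defaults to the
    conservative :func:`cycle_segmentation`.
    """
    counts = np.asarray(counts)
    if profile is None:
        profile = cycle_segmentation(counts, grid)
    gam = fit_gc_map_gam(counts, profile.nu_per_bin, grid)
    tau, lens = segment_trend_statistics(counts, profile, grid, gam)
    activity = cycling_activity(tau, lens) if len(tau) else 0.0
    valid = grid.valid
    y = counts[valid].astype(float)
    if cn is None:
        cn = np.rint(profile.nu_per_bin / max(rho, 1e-9))
    mi = mutual_information_measure(y, grid.reptime[valid], cn)
    overdisp = float(np.average(profile.alpha, weights=profile.lengths))
    return {
        "rho": rho,
        "overdispersion": overdisp,
        "cycling_activity": activity,
        "mi": mi,
    }
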