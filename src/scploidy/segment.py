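"""Change-point segmentation of binned read counts.

Counts in a segment are modelled as negative binomial,

    Pr(Y=y | m, alpha) = Gamma(y + 1/alpha) / (y! Gamma(1/alpha))
                         * (alpha m / (1 + alpha m))^y
                         * (1 / (1 + alpha m))^(1/alpha),

with mean ``m`` and overdispersion ``alpha`` (variance = m + alpha m^2; the
Poisson limit as alpha -> 0).  The cost of a segment is its negative
log-likelihood with the mean plugged in as the sample mean and alpha as the
method-of-moments estimate (s^2 - m) / m^2, clamped at zero.  The optimal
partition per chromosome minimises total cost plus a per-segment penalty and
is found with PELT; an O(n^2) exhaustive optimal-partitioning routine with
the identical cost is provided as an oracle.

This is an *initial* segmentation: its job is to summarise each bin by a
segment level so the ploidy grid can be fitted, not to produce final calls.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .grid import BinGrid, CellCounts

#: alpha below this is treated as the Poisson limit
ALPHA_POISSON = 1e-8

#: per-segment penalty = PENALTY_SCALE * log(n bins on chromosome);
#: calibrated so a simulated diploid cell at rho = 100 incurs well under one
#: spurious breakpoint per chromosome on average while short +/-1 events on
#: a tetraploid background remain detectable
PENALTY_SCALE = 1.0

MIN_SEG_LEN = 3

#: cost-improvement threshold of the post-PELT split-repair pass: a segment
#: is split at its best internal changepoint when doing so improves the NB
#: cost by more than this.  Much lower than the PELT penalty: missing a weak
#: boundary leaves a mixed segment whose level lies between copy-number
#: states and corrupts the ploidy-scale evidence, whereas a spurious split
#: of a homogeneous segment is harmless there.
REPAIR_THRESHOLD = 4.0

#: conservative PELT pruning margin: a candidate is pruned only when it is
#: worse than the incumbent by more than this.  The plug-in MoM alpha makes
#: the cost only approximately subadditive, so a safety margin keeps pruning
#: exact in practice (verified against the exhaustive oracle).
PRUNE_MARGIN = 30.0


def nb_neg_loglik(y: np.ndarray, m: float, alpha: float) -> float:
    """Negative log-likelihood of counts ``y`` under NB(mean=m, alpha).

    At ``alpha`` below 1e-8 the Poisson limit is used.
    """
    y = np.asarray(y)
    if y.ndim != 1 or len(y) == 0:
        raise ValueError("y must be a non-empty 1-D vector")
    if np.any(y < 0) or not np.issubdtype(y.dtype, np.integer) and np.any(y != np.floor(y)):
        raise ValueError("y must be non-negative integers")
    if m <= 0:
        raise ValueError("m must be positive")
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    yf = y.astype(np.float64)
    from scipy.special import gammaln

    if alpha < ALPHA_POISSON:
        ll = yf * math.log(m) - m - gammaln(yf + 1.0)
        return float(-ll.sum())
    r = 1.0 / alpha
    am = alpha * m
    ll = (
        gammaln(yf + r)
        - gammaln(r)
        - gammaln(yf + 1.0)
        + yf * math.log(am / (1.0 + am))
        - r * math.log1p(am)
    )
    return float(-ll.sum())


def estimate_alpha_mm(y: np.ndarray) -> float:
    """Method-of-moments NB overdispersion (s^2 - m) / m^2, clamped at 0.

    Uses the unbiased sample variance.  Returns 0 with a warning when the
    sample mean is zero.
    """
    y = np.asarray(y, float)
    if len(y) < 2:
        raise ValueError("need at least 2 observations")
    m = y.mean()
    if m == 0:
        warnings.warn("all-zero segment: alpha set to 0", stacklevel=2)
        return 0.0
    s2 = y.var(ddof=1)
    return max(0.0, (s2 - m) / (m * m))


# ---------------------------------------------------------------------------
# numba kernels


@njit(cache=True)
def _seg_cost(y, i, j, c1, c2, c3):
    """NB neg log-lik of y[i:j] with plug-in mean and MoM alpha.

    c1/c2/c3 are prefix sums of y, y^2 and lgamma(y+1).
    """
    n = j - i
    s = c1[j] - c1[i]
    if s == 0.0:
        return 0.0  # degenerate all-zero segment: pmf mass 1 at 0 as m -> 0
    m = s / n
    if n > 1:
        var = (c2[j] - c2[i] - n * m * m) / (n - 1)
    else:
        var = 0.0
    alpha = (var - m) / (m * m)
    lgfact = c3[j] - c3[i]
    if alpha < ALPHA_POISSON:
        return -(s * math.log(m) - s - lgfact)
    r = 1.0 / alpha
    t = 0.0
    for k in range(i, j):
        t += math.lgamma(y[k] + r)
    am = alpha * m
    ll = t - n * math.lgamma(r) - lgfact + s * math.log(am / (1.0 + am)) - n * r * math.log1p(am)
    return -ll


@njit(cache=True)
def _pelt(y, c1, c2, c3, penalty, min_len, prune_margin):
    """PELT over one chromosome; returns (F, cp) arrays.

    ``prune_margin = inf`` disables pruning entirely, turning this into the
    exhaustive optimal-partitioning recursion.
    """
    n = len(y)
    F = np.full(n + 1, np.inf)
    F[0] = -penalty
    cp = np.zeros(n + 1, np.int64)
    cand = np.empty(n + 1, np.int64)
    cand[0] = 0
    ncand = 1
    vals = np.empty(n + 1)
    for s in range(1, n + 1):
        best = np.inf
        arg = 0
        for ci in range(ncand):
            t = cand[ci]
            if s - t < min_len or not np.isfinite(F[t]):
                vals[ci] = np.inf
                continue
            v = F[t] + _seg_cost(y, t, s, c1, c2, c3) + penalty
            vals[ci] = v
            if v < best:
                best = v
                arg = t
        F[s] = best
        cp[s] = arg
        k = 0
        for ci in range(ncand):
            t = cand[ci]
            if s - t < min_len:
                keep = np.isfinite(F[t])  # not yet evaluable; keep if reachable
            else:
                keep = vals[ci] - penalty <= F[s] + prune_margin
            if keep:
                cand[k] = t
                k += 1
        ncand = k
        cand[ncand] = s
        ncand += 1
    return F, cp


@njit(cache=True)
def _best_split(y, i, j, c1, c2, c3, min_len):
    """Best single split of y[i:j]: scan with a normal-approximation score,
    return (position, exact NB cost improvement) at the best scan point."""
    n = j - i
    if n < 2 * min_len:
        return -1, 0.0
    # normal-approx scan: between-group sum of squares over pooled variance
    s_all = c1[j] - c1[i]
    m_all = s_all / n
    var_all = (c2[j] - c2[i] - n * m_all * m_all) / max(n - 1, 1)
    if var_all <= 0:
        return -1, 0.0
    best_t = -1
    best_score = 0.0
    for t in range(i + min_len, j - min_len + 1):
        nl = t - i
        nr = j - t
        ml = (c1[t] - c1[i]) / nl
        mr = (c1[j] - c1[t]) / nr
        score = nl * nr / n * (ml - mr) ** 2
        if score > best_score:
            best_score = score
            best_t = t
    if best_t < 0:
        return -1, 0.0
    gain = (
        _seg_cost(y, i, j, c1, c2, c3)
        - _seg_cost(y, i, best_t, c1, c2, c3)
        - _seg_cost(y, best_t, j, c1, c2, c3)
    )
    return best_t, gain


@njit(cache=True)
def _repair_bounds(y, c1, c2, c3, bounds, min_len, threshold):
    """Recursively split segments whose best internal changepoint improves
    the NB cost by more than ``threshold`` (a boundary the penalty missed).

    Returns the refined sorted boundary array.
    """
    out = np.empty(len(y) + 1, np.int64)
    n_out = 0
    stack = np.empty(2 * (len(y) + 1), np.int64)
    for b in range(len(bounds) - 1):
        top = 0
        stack[0] = bounds[b]
        stack[1] = bounds[b + 1]
        top = 2
        while top > 0:
            j = stack[top - 1]
            i = stack[top - 2]
            top -= 2
            t, gain = _best_split(y, i, j, c1, c2, c3, min_len)
            if t >= 0 and gain > threshold:
                stack[top] = i
                stack[top + 1] = t
                stack[top + 2] = t
                stack[top + 3] = j
                top += 4
            else:
                out[n_out] = i
                n_out += 1
    out[n_out] = bounds[-1]
    n_out += 1
    res = out[:n_out]
    return np.sort(np.unique(res))


def _backtrack(cp: np.ndarray, n: int) -> np.ndarray:
    bounds = [n]
    s = n
    while s > 0:
        s = int(cp[s])
        bounds.append(s)
    return np.array(bounds[::-1], dtype=np.int64)


def _prefix_sums(y: np.ndarray):
    from scipy.special import gammaln

    yf = y.astype(np.float64)
    c1 = np.concatenate([[0.0], np.cumsum(yf)])
    c2 = np.concatenate([[0.0], np.cumsum(yf * yf)])
    c3 = np.concatenate([[0.0], np.cumsum(gammaln(yf + 1.0))])
    return yf, c1, c2, c3


def _segment_vector(
    y: np.ndarray,
    penalty: float,
    min_seg_len: int,
    prune_margin: float,
    repair_threshold: float | None,
) -> np.ndarray:
    """Segment one chromosome's counts; returns segment boundary indices."""
    n = len(y)
    if n < max(min_seg_len, 2):
        return np.array([0, n], dtype=np.int64)
    yf, c1, c2, c3 = _prefix_sums(y)
    F, cp = _pelt(yf, c1, c2, c3, penalty, min_seg_len, prune_margin)
    if not np.isfinite(F[n]):
        bounds = np.array([0, n], dtype=np.int64)
    else:
        bounds = _backtrack(cp, n)
    if repair_threshold is not None and n >= 2 * min_seg_len:
        bounds = _repair_bounds(yf, c1, c2, c3, bounds, min_seg_len, repair_threshold)
    return bounds


def exhaustive_objective(y: np.ndarray, penalty: float, min_seg_len: int = MIN_SEG_LEN) -> float:
    """Objective value of exhaustive optimal partitioning (O(n^2) oracle)."""
    y = np.asarray(y)
    yf, c1, c2, c3 = _prefix_sums(y)
    F, _ = _pelt(yf, c1, c2, c3, penalty, min_seg_len, np.inf)
    return float(F[len(y)])


def pelt_objective(y: np.ndarray, penalty: float, min_seg_len: int = MIN_SEG_LEN,
                   prune_margin: float = PRUNE_MARGIN) -> float:
    """Objective value reached by the pruned PELT recursion."""
    y = np.asarray(y)
    yf, c1, c2, c3 = _prefix_sums(y)
    F, _ = _pelt(yf, c1, c2, c3, penalty, min_seg_len, prune_margin)
    return float(F[len(y)])


# ---------------------------------------------------------------------------
# segmented profiles


@dataclass
class SegmentedProfile:
    """Segmentation of one cell's counts over the analysis bins.

    All indices refer to the vector of bins the segmentation was run on
    (normally the valid bins of the grid, in genomic order).
    """

    starts: np.ndarray  # segment start index (inclusive)
    ends: np.ndarray  # segment end index (exclusive)
    chrom_code: np.ndarray  # chromosome code per segment
    mean: np.ndarray  # per-segment NB mean (sample mean)
    alpha: np.ndarray  # per-segment MoM overdispersion
    nu: np.ndarray  # per-segment level: median of raw counts
    n_bins: int = 0
    seg_id: np.ndarray = field(default=None, repr=False)

    @property
    def lengths(self) -> np.ndarray:
        return self.ends - self.starts

    @property
    def n_segments(self) -> int:
        return len(self.starts)

    @property
    def nu_per_bin(self) -> np.ndarray:
        """Segment level broadcast to bins."""
        return np.repeat(self.nu, self.lengths)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "start_bin": self.starts,
                "end_bin": self.ends,
                "chrom_code": self.chrom_code,
                "n_bins": self.lengths,
                "mean": self.mean,
                "alpha": self.alpha,
                "nu": self.nu,
            }
        )


def segment_counts(
    y: np.ndarray,
    chrom_codes: np.ndarray | None = None,
    penalty_scale: float = PENALTY_SCALE,
    min_seg_len: int = MIN_SEG_LEN,
    prune_margin: float = PRUNE_MARGIN,
    repair_threshold: float | None = REPAIR_THRESHOLD,
) -> SegmentedProfile:
    """Segment a count vector, independently per chromosome.

    Parameters
    ----------
    y
        Non-negative integer counts over the analysis bins.
    chrom_codes
        Integer chromosome label per bin (contiguous blocks); segments never
        span a chromosome boundary.  ``None`` treats the vector as one
        chromosome.
    penalty_scale
        The per-segment penalty on each chromosome is
        ``penalty_scale * log(n_chromosome_bins)``.
    """
    y = np.asarray(y)
    if np.any(y < 0):
        raise ValueError("counts must be non-negative")
    n = len(y)
    if chrom_codes is None:
        chrom_codes = np.zeros(n, dtype=np.int64)
    chrom_codes = np.asarray(chrom_codes)
    starts, ends, chroms = [], [], []
    boundaries = np.flatnonzero(np.diff(chrom_codes)) + 1
    blocks = np.split(np.arange(n), boundaries)
    for block in blocks:
        if len(block) == 0:
            continue
        off = block[0]
        yy = y[block]
        penalty = penalty_scale * math.log(max(len(yy), 2))
        bounds = _segment_vector(yy, penalty, min_seg_len, prune_margin, repair_threshold)
        for a, b in zip(bounds[:-1], bounds[1:]):
            starts.append(off + a)
            ends.append(off + b)
            chroms.append(chrom_codes[off])
    starts = np.array(starts, dtype=np.int64)
    ends = np.array(ends, dtype=np.int64)
    mean = np.array([y[a:b].mean() for a, b in zip(starts, ends)])
    alpha = np.array(
        [
            estimate_alpha_mm(y[a:b]) if b - a >= 2 and y[a:b].any() else 0.0
            for a, b in zip(starts, ends)
        ]
    )
    nu = np.array([float(np.median(y[a:b])) for a, b in zip(starts, ends)])
    seg_id = np.repeat(np.arange(len(starts)), ends - starts)
    return SegmentedProfile(
        starts=starts,
        ends=ends,
        chrom_code=np.array(chroms),
        mean=mean,
        alpha=alpha,
        nu=nu,
        n_bins=n,
        seg_id=seg_id,
    )


def segment_pelt(
    counts: CellCounts,
    grid: BinGrid,
    penalty_scale: float = PENALTY_SCALE,
    min_seg_len: int = MIN_SEG_LEN,
    prune_margin: float = PRUNE_MARGIN,
    repair_threshold: float | None = REPAIR_THRESHOLD,
) -> SegmentedProfile:
    """Segment a cell's counts over the valid bins of ``grid``."""
    valid = grid.valid
    y = np.asarray(counts.counts)[valid]
    codes = grid.chrom_codes[valid]
    return segment_counts(
        y,
        codes,
        penalty_scale=penalty_scale,
        min_seg_len=min_seg_len,
        prune_margin=prune_margin,
        repair_threshold=repair_threshold,
    )


def profile_to_seg_frame(
    profile: SegmentedProfile, grid: BinGrid, cell_id: str
) -> pd.DataFrame:
    """SEG-like table (cell, chrom, start, end, n_bins, mean, alpha, nu)."""
    valid_idx = np.flatnonzero(grid.valid)
    chroms = grid.chrom
    starts_bp = grid.start
    ends_bp = grid.end
    rows = []
    for a, b, m, al, nu in zip(
        profile.starts, profile.ends, profile.mean, profile.alpha, profile.nu
    ):
        bins = valid_idx[a:b]
        rows.append(
            {
                "cell": cell_id,
                "chrom": chroms[bins[0]],
                "start": int(starts_bp[bins[0]]),
                "end": int(ends_bp[bins[-1]]),
                "n_bins": int(b - a),
                "mean": float(m),
                "alpha": float(al),
                "nu": float(nu),
            }
        )
    return pd.DataFrame(rows)
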