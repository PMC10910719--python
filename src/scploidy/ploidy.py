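"""Absolute ploidy estimation from segmented counts.

The marginal distribution of segment levels of a single cell clusters around
integer multiples of the (unknown) reads-per-copy scaling factor rho.  We fit
a constrained Gaussian mixture whose component means are pinned to a 1-D
integer grid, mu_k = k * xi for k = 1..T, with per-component standard
deviations and Dirichlet-process stick-breaking weights truncated at T
components.  The fitted spacing xi identifies rho only up to an integer
divisor, so candidate solutions rho = xi / m are enumerated, each implying a
ploidy p = mean_j round(nu_j / rho) over valid autosomal bins, inside a
biologically plausible ploidy window (default 1.1-8.0).  Selection starts at
the lowest-ploidy candidate and refines the grid (doubling or tripling the
ploidy) only when precise segments sit at half- or third-phases of the
current spacing (see :func:`phase_vote`); a doubled genome without
distinguishing odd states is therefore deliberately assigned the lower
solution -- the unidentifiability the read-density module resolves.

The optimiser is a MAP EM: the E-step computes responsibilities, the M-step
updates xi by a precision-weighted regression of levels on component index,
the sigma_k from weighted residuals (floored and capped relative to xi), and
the stick-breaking weights from their Beta posterior means.  Restarts over a
log-spaced grid of initial spacings avoid half-spacing local optima; the
stick-breaking prior prefers low component indices and therefore the widest
grid consistent with the data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .exceptions import EmptyCellError, MixtureFitError, PloidyWindowError
from .grid import BinGrid, CellCounts
from .segment import SegmentedProfile, segment_pelt

PLOIDY_WINDOW = (1.1, 8.0)
TRUNCATION = 16
RESTARTS = 10

#: sigma_k bounds relative to the grid spacing: the floor prevents component
#: collapse on (near-)noiseless data, the cap keeps neighbouring grid
#: components distinguishable so the likelihood cannot be satisfied by one
#: huge blurred component.
SIGMA_FLOOR_FRAC = 0.01
SIGMA_CAP_FRAC = 0.5

#: stick-breaking concentration
DP_GAMMA = 1.0

#: minimum genomic mass (bins) of precise off-grid segments required before
#: the solution ladder advances to a finer candidate grid
PHASE_EVIDENCE_BINS = 30.0

#: a segment is "precise" (eligible as grid evidence) when the standard
#: error of its level is at most this fraction of the candidate spacing
PHASE_PRECISION = 0.10


@dataclass
class MixtureFit:
    """Constrained grid-mixture fit: means fixed at k * xi.

    ``objective`` is the weighted log-likelihood; ``score`` additionally
    includes the stick-breaking ordering term (see
    :func:`fit_constrained_mixture`) and is what restarts are compared on.
    """

    xi: float
    sigmas: np.ndarray  # (T,) per-component SD
    weights: np.ndarray  # (T,) stick-breaking weights, sum <= 1
    objective: float
    seed: int
    converged: bool = True
    n_iter: int = 0
    score: float = -np.inf

    @property
    def truncation(self) -> int:
        return len(self.sigmas)


@dataclass
class PloidySolution:
    """A selected (rho, ploidy) solution with its candidate list."""

    rho: float
    ploidy: float
    copy_number: np.ndarray  # integer CN per analysis bin
    rmse: float
    candidates: list  # list of (rho, ploidy, rmse) tuples
    window: tuple
    fit: MixtureFit | None = None
    profile: SegmentedProfile | None = None
    refit: bool = False

    def to_record(self) -> dict:
        return {
            "rho": self.rho,
            "ploidy": self.ploidy,
            "rmse": self.rmse,
            "n_candidates": len(self.candidates),
            "window_lo": self.window[0],
            "window_hi": self.window[1],
            "flag_refit": self.refit,
        }


def _stick_breaking_weights(n_k: np.ndarray, gamma: float) -> np.ndarray:
    """Posterior-mean stick-breaking weights from component masses n_k."""
    T = len(n_k)
    tail = np.concatenate([np.cumsum(n_k[::-1])[::-1][1:], [0.0]])  # sum_{i>k} n_i
    v = (1.0 + n_k) / (1.0 + gamma + n_k + tail)
    pi = np.empty(T)
    rem = 1.0
    for k in range(T):
        pi[k] = v[k] * rem
        rem *= 1.0 - v[k]
    return pi


def _em_once(
    values: np.ndarray,
    weights: np.ndarray,
    xi0: float,
    T: int,
    gamma: float,
    max_iter: int,
    tol: float,
) -> MixtureFit:
    """Run MAP EM from one initial spacing; deterministic."""
    v = values
    w = weights
    W = w.sum()
    xi = float(xi0)
    sig = np.full(T, max(0.15 * xi, 1e-6))
    pi = _stick_breaking_weights(np.full(T, W / T), gamma)
    ks = np.arange(1, T + 1)

    obj = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mu = ks * xi
        # E-step in log space
        log_comp = (
            np.log(np.maximum(pi, 1e-300))[None, :]
            - 0.5 * np.log(2 * np.pi * sig[None, :] ** 2)
            - 0.5 * ((v[:, None] - mu[None, :]) / sig[None, :]) ** 2
        )
        m = log_comp.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(log_comp - m).sum(axis=1))
        new_obj = float((w * lse).sum())
        r = np.exp(log_comp - lse[:, None])
        # M-step
        wr = w[:, None] * r
        n_k = wr.sum(axis=0)
        prec = 1.0 / sig**2
        num = float((wr * (v[:, None] * ks[None, :]) * prec[None, :]).sum())
        den = float((n_k * ks**2 * prec).sum())
        if den > 0:
            xi = num / den
        xi = max(xi, 1e-12)
        resid2 = (wr * (v[:, None] - ks[None, :] * xi) ** 2).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            s2 = np.where(n_k > 1e-12, resid2 / np.maximum(n_k, 1e-12), (0.15 * xi) ** 2)
        sig = np.sqrt(np.maximum(s2, 0.0))
        sig = np.clip(sig, SIGMA_FLOOR_FRAC * xi, SIGMA_CAP_FRAC * xi)
        pi = _stick_breaking_weights(n_k, gamma)
        if new_obj - obj < tol * (abs(obj) + 1.0) and it > 5:
            obj = new_obj
            converged = True
            break
        obj = new_obj
    # stick-breaking ordering score: mass assigned to component k pays the
    # a-priori cost of reaching the k-th stick, E[pi_k | GEM(gamma)] =
    # gamma^(k-1)/(1+gamma)^k.  This is the complexity term a point-estimate
    # EM loses relative to the full DP objective; without it, subdividing the
    # grid (xi -> xi/m, occupying components m, 2m, ...) can win on
    # likelihood alone.  It makes the coarsest grid consistent with the data
    # the best-scoring one.
    log_prior_k = (ks - 1) * np.log(gamma) - ks * np.log1p(gamma)
    score = obj + float(n_k @ log_prior_k)
    return MixtureFit(
        xi=xi, sigmas=sig, weights=pi, objective=obj, seed=0,
        converged=converged, n_iter=it, score=score,
    )


def fit_constrained_mixture(
    values: np.ndarray,
    weights: np.ndarray | None = None,
    T: int = TRUNCATION,
    seed: int = 0,
    restarts: int = RESTARTS,
    gamma: float = DP_GAMMA,
    max_iter: int = 200,
    tol: float = 1e-9,
) -> MixtureFit:
    """Fit the constrained grid mixture to segment levels.

    Parameters
    ----------
    values
        Segment levels (nu), in read counts; non-positive values are ignored.
    weights
        Per-value weights, normally segment lengths in bins.
    T
        Truncation of the stick-breaking process (number of grid components).
    seed
        Recorded for provenance; the optimiser itself is deterministic.
    restarts
        Number of initial spacings on a log-spaced grid over
        [min(values)/8, max(values)].

    Returns
    -------
    MixtureFit
        The restart with the best penalised objective.

    Raises
    ------
    MixtureFitError
        If no restart converges; the error carries the best fit so far.
    """
    values = np.asarray(values, float)
    if weights is None:
        weights = np.ones_like(values)
    weights = np.asarray(weights, float)
    keep = values > 0
    values, weights = values[keep], weights[keep]
    if len(values) == 0:
        raise EmptyCellError("no positive segment levels to fit")

    vmin, vmax = values.min(), values.max()
    lo = max(vmin / 8.0, 1e-6)
    hi = max(vmax, lo * (1 + 1e-9))
    inits = list(np.geomspace(lo, hi, max(restarts, 2)))
    # one extra data-driven initial spacing: the median positive gap between
    # distinct sorted levels, a direct estimate of the grid spacing
    uniq = np.unique(values)
    gaps = np.diff(uniq)
    gaps = gaps[gaps > max(1e-9, 0.02 * vmax)]
    if len(gaps):
        inits.append(float(np.median(gaps)))

    fits = [
        _em_once(values, weights, xi0, T, gamma, max_iter, tol) for xi0 in inits
    ]
    for f in fits:
        f.seed = seed
    ok = [f for f in fits if f.converged and np.isfinite(f.score)]
    if not ok:
        best = max(fits, key=lambda f: f.score if np.isfinite(f.score) else -np.inf)
        raise MixtureFitError("constrained mixture did not converge", best_fit=best)
    return max(ok, key=lambda f: f.score)


class Candidate(NamedTuple):
    """One candidate scaling factor with its fit statistics.

    ``rmse`` is the bin-weighted RMSE of nu/rho to the nearest integers.
    """

    rho: float
    ploidy: float
    rmse: float


def compute_ploidy(c: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Ploidy p = mean of the integer copy numbers (over ``mask`` if given)."""
    c = np.asarray(c, float)
    if mask is not None:
        c = c[np.asarray(mask, bool)]
    if len(c) == 0:
        raise ValueError("no bins to average")
    return float(c.mean())


def _solution_stats(nu_bin: np.ndarray, rho: float, autosomal: np.ndarray):
    ratio = nu_bin / rho
    c = np.maximum(np.rint(ratio), 0.0)
    rmse = float(np.sqrt(np.mean((ratio - c) ** 2)))
    p = compute_ploidy(c, autosomal)
    return c.astype(np.int64), p, rmse


def weighted_quantile(values: np.ndarray, weights: np.ndarray, q: float) -> float:
    """Lower weighted quantile (smallest v with cumulative weight >= q)."""
    order = np.argsort(values)
    cum = np.cumsum(weights[order])
    return float(values[order][np.searchsorted(cum, q * cum[-1])])


def _segment_evidence(profile: SegmentedProfile):
    """Per-segment (level, SE, length) for grid-phase evidence.

    Levels are segment medians corrected for the NB mean-median offset
    (approximately (1 + 2 alpha m)/6), so that levels of different
    copy-number states are integer multiples of a common spacing; without the
    correction the skew offset grows with the state and bends the grid.  The
    per-segment MoM alpha is unreliable on short segments and is floored with
    the cell-global (length-weighted median) overdispersion.
    """
    n = profile.lengths.astype(float)
    alpha0 = weighted_quantile(profile.alpha, n, 0.5)
    alpha = np.maximum(profile.alpha, alpha0)
    m = profile.nu + (1.0 + 2.0 * alpha * profile.nu) / 6.0
    var_bin = np.maximum(m + alpha * m**2, 1.0)
    se = np.sqrt(var_bin / np.maximum(n, 1.0))
    return m, se, n


def _is_level_mixture(y: np.ndarray, a: int, b: int, rho: float) -> bool:
    """True when a segment's two halves (at its best internal split) sit at
    clearly different levels: the segment straddles an undetected boundary
    between adjacent grid states rather than occupying a genuine
    intermediate state."""
    from .segment import MIN_SEG_LEN, _best_split, _prefix_sums

    seg = y[a:b]
    if len(seg) < 2 * MIN_SEG_LEN:
        return False
    yf, c1, c2, c3 = _prefix_sums(seg)
    t, _ = _best_split(yf, 0, len(seg), c1, c2, c3, MIN_SEG_LEN)
    if t < 0:
        return False
    return abs(seg[:t].mean() - seg[t:].mean()) > 0.5 * rho


def phase_vote(
    profile: SegmentedProfile,
    rho: float,
    min_mass: float = PHASE_EVIDENCE_BINS,
    precision: float = PHASE_PRECISION,
    counts_vec: np.ndarray | None = None,
) -> int | None:
    """Does the data demand a refinement of the rho-grid?  Returns 2, 3 or None.

    Each sufficiently precise segment (level SE at most ``precision`` of the
    spacing, at least 10 bins) casts a vote by the phase of its level on the
    candidate grid, ph = frac(level / rho).  Genuine copy-number states of a
    half-spacing solution sit at phase ~1/2 and of a third-spacing solution
    at ~1/3; noise-carved segments stay within a fraction of the bin noise
    of the grid, so the half-phase band is specific.  Segments straddling an
    undetected boundary between *adjacent* grid states can mimic half-phase
    levels; with the raw counts available (``counts_vec``) such segments are
    recognised by their internal structure — their two halves sit at
    different grid states — and excluded.  A single supporting segment must
    in addition be phase-consistent with exactly 1/2 within 1.5 of its own
    level SE.  The one-third band competes directly with mixture phases and
    is held to a control band of arbitrary phases.
    """
    m, se, n = _segment_evidence(profile)
    ph = m / rho - np.floor(m / rho)
    u = se / rho
    el = (u <= precision) & (n >= 10)

    def band(lo, hi):
        return n[el & (((ph >= lo) & (ph <= hi)) | ((ph >= 1 - hi) & (ph <= 1 - lo)))].sum()

    e2_mask = el & (ph >= 0.39) & (ph <= 0.61)
    if counts_vec is not None:
        for idx in np.flatnonzero(e2_mask):
            if _is_level_mixture(
                counts_vec, profile.starts[idx], profile.ends[idx], rho
            ):
                e2_mask[idx] = False
    e2 = n[e2_mask].sum()
    e3 = band(0.26, 0.39)
    ctrl = band(0.12, 0.26)
    e2_ok = e2 >= min_mass
    if e2_ok and e2_mask.sum() == 1:
        sole = int(np.flatnonzero(e2_mask)[0])
        e2_ok = abs(ph[sole] - 0.5) <= max(1.5 * u[sole], 0.03)
    if e2_ok:
        return 2
    if e3 >= max(min_mass, 2.0 * ctrl) and e3 > 2.0 * e2:
        return 3
    return None


def enumerate_candidates(
    fit: MixtureFit,
    nu_bin: np.ndarray,
    autosomal: np.ndarray | None = None,
    window: tuple = PLOIDY_WINDOW,
    include_multiples: bool = False,
    max_divisor: int = 64,
) -> list:
    """Candidate scaling factors rho = xi/m (optionally xi*m) inside the window.

    Each candidate is a :class:`Candidate` (rho, ploidy, rmse); ploidy is
    computed on autosomal bins, RMSE on all bins (bin-weighted, equivalent to
    weighting segments by their length).  Candidates are ordered by
    increasing ploidy.
    """
    nu_bin = np.asarray(nu_bin, float)
    if autosomal is None:
        autosomal = np.ones(len(nu_bin), bool)
    lo, hi = window
    cands = []
    rhos = [fit.xi / m for m in range(1, max_divisor + 1)]
    if include_multiples:
        rhos += [fit.xi * m for m in range(2, max_divisor + 1)]
    for rho in sorted(set(rhos), reverse=True):
        _, p, rmse = _solution_stats(nu_bin, rho, autosomal)
        if lo <= p <= hi:
            cands.append(Candidate(float(rho), float(p), float(rmse)))
        elif p > hi:
            break  # ploidy grows monotonically as rho shrinks
    if not cands:
        raise PloidyWindowError(
            f"no solution in ploidy window ({lo}, {hi}) for xi={fit.xi:.3g}"
        )
    return cands


def _refine_rho(profile: SegmentedProfile, rho: float, iters: int = 3) -> float:
    """Polish rho at fixed integer assignment.

    Weighted least squares on the reads scale, then a local scan minimising
    the copy-scale RMSE (the selection metric itself, whose optimum sits at
    a slightly different rho than the reads-scale one).
    """
    nu = profile.nu
    w = profile.lengths.astype(float)
    for _ in range(iters):
        c = np.rint(nu / rho)
        ok = c > 0
        den = float((w[ok] * c[ok] ** 2).sum())
        if den <= 0:
            return rho
        rho = float((w[ok] * nu[ok] * c[ok]).sum() / den)
    best, best_rho = np.inf, rho
    for cand in rho * np.linspace(0.96, 1.04, 161):
        ratio = nu / cand
        c = np.maximum(np.rint(ratio), 0.0)
        mse = float((w * (ratio - c) ** 2).sum())
        if mse < best:
            best, best_rho = mse, cand
    return best_rho


#: an advance to a finer candidate grid is vetoed when it inflates the plain
#: RMSE by more than this factor: subdividing the grid k-fold multiplies the
#: pure-noise RMSE by ~k, whereas a genuine refinement is offset by the
#: off-grid states it resolves.
ADVANCE_RMSE_VETO = 1.4


def select_solution(
    candidates: list,
    nu_bin: np.ndarray,
    autosomal: np.ndarray | None = None,
    window: tuple = PLOIDY_WINDOW,
    tie_tol: float = 1e-6,
    profile: SegmentedProfile | None = None,
    counts_vec: np.ndarray | None = None,
) -> PloidySolution:
    """Pick the solution among the candidates; preference to the lowest ploidy.

    With segment information available, selection climbs a ladder: starting
    from the lowest-ploidy candidate, the grid is refined to the candidate at
    double (or triple) the ploidy whenever :func:`phase_vote` finds precise
    segments stranded at half- (third-) phases of the current grid, subject
    to an RMSE-inflation veto (``ADVANCE_RMSE_VETO``).  Without a profile
    (bare candidate lists), the plain RMSE is minimised with near-exact ties
    (< ``tie_tol``) broken toward the lowest ploidy.  The selected rho is
    polished by weighted least squares at fixed integer assignment.
    """
    if not candidates:
        raise PloidyWindowError("empty candidate list")
    nu_bin = np.asarray(nu_bin, float)
    if autosomal is None:
        autosomal = np.ones(len(nu_bin), bool)

    if profile is not None:
        order = sorted(range(len(candidates)), key=lambda i: candidates[i][1])
        cur = 0
        for rung in range(6):  # ploidy can at most double a few times in window
            cd = candidates[order[cur]]
            # each further refinement demands five times the evidence: a
            # genuinely doubled solution places a macroscopic fraction of
            # the genome on the finer grid's odd states, while mixture
            # artifacts contribute only tens of bins -- and successive
            # doublings are a priori increasingly implausible (a genuinely
            # doubled genome is resolved by the read-density step, not by
            # count evidence alone)
            k = phase_vote(
                profile,
                cd.rho,
                min_mass=PHASE_EVIDENCE_BINS * 5.0**rung,
                counts_vec=counts_vec,
            )
            if k is None:
                break
            target = cd.ploidy * k
            opts = [
                j
                for j in range(cur + 1, len(order))
                if abs(candidates[order[j]][1] - target) < 0.15 * target
            ]
            if not opts:
                break
            nxt = min(opts, key=lambda j: abs(candidates[order[j]][1] - target))
            if candidates[order[nxt]][2] > ADVANCE_RMSE_VETO * cd.rmse:
                break
            cur = nxt
        rho = _refine_rho(profile, candidates[order[cur]].rho)
    else:
        best_rmse = min(c[2] for c in candidates)
        near = [c for c in candidates if c[2] - best_rmse < tie_tol]
        rho = min(near, key=lambda c: c[1])[0]

    c_vec, p, rmse = _solution_stats(nu_bin, rho, autosomal)
    return PloidySolution(
        rho=float(rho),
        ploidy=p,
        copy_number=c_vec,
        rmse=rmse,
        candidates=candidates,
        window=window,
    )


def fit_cell_ploidy(
    counts: CellCounts,
    grid: BinGrid,
    window: tuple = PLOIDY_WINDOW,
    T: int = TRUNCATION,
    seed: int = 0,
    restarts: int = RESTARTS,
    penalty_scale: float | None = None,
    profile: SegmentedProfile | None = None,
) -> PloidySolution:
    """Steps 1-3 for one cell: segment, fit the grid mixture, select rho.

    ``profile`` may be supplied to reuse an existing segmentation (e.g. when
    refitting with a new window).
    """
    if profile is None:
        kw = {} if penalty_scale is None else {"penalty_scale": penalty_scale}
        profile = segment_pelt(counts, grid, **kw)
    fit = fit_constrained_mixture(
        profile.nu, weights=profile.lengths.astype(float), T=T, seed=seed, restarts=restarts
    )
    nu_bin = profile.nu_per_bin
    autosomal = grid.autosomal[grid.valid]
    cands = enumerate_candidates(fit, nu_bin, autosomal, window=window)
    y_valid = np.asarray(counts.counts, float)[grid.valid]
    sol = select_solution(
        cands, nu_bin, autosomal, window=window, profile=profile, counts_vec=y_valid
    )
    sol.fit = fit
    sol.profile = profile
    return sol


def refit_with_window(
    counts: CellCounts,
    grid: BinGrid,
    new_window: tuple,
    seed: int = 0,
    profile: SegmentedProfile | None = None,
    **kwargs,
) -> PloidySolution:
    """Re-apply steps 1-3 with a cell-specific ploidy window.

    Used after the read-density check flags a cell as having an elevated
    density (G2/WGD/multiplet): the window is typically centred on twice the
    initial ploidy, e.g. (2 p0 - 0.5, 2 p0 + 0.5).
    """
    lo, hi = new_window
    if not (0 < lo < hi):
        raise ValueError("invalid ploidy window")
    sol = fit_cell_ploidy(
        counts, grid, window=new_window, seed=seed, profile=profile, **kwargs
    )
    sol.refit = True
    return sol


def doubled_window(ploidy: float, half_width: float = 0.5) -> tuple:
    """Ploidy window centred on twice the given ploidy."""
    return (2.0 * ploidy - half_width, 2.0 * ploidy + half_width)
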