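"""Synthetic single-cell WGS data with known ground truth.

Generates everything the inference modules consume: a bin grid with smooth
GC/mappability/replication-time tracks, integer copy-number profiles on a
chosen background ploidy, negative-binomial bin counts scaled by rho with
multiplicative GC/mappability bias and S-phase replication inflation, and
paired-end fragments placed on physical genome copies so that fragments from
one copy never overlap (the copy-limit the read-density method exploits).

Counts are parameterised so that ``rho`` is the expected reads per *nominal*
copy c_j per bin regardless of genome multiplicity: a doubled (G2-like) cell
has the same count profile as its G1 counterpart and differs only in how its
fragments are distributed over physical copies -- reproducing the
unidentifiability by construction.

When both counts and fragments are generated for a cell they share the same
per-bin latent gamma rate, so the fragment-start tallies are the cell's
counts and the NB overdispersion carries through to the fragment level.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .density import FragmentSet
from .grid import BinGrid, CellCounts

#: human-like relative chromosome sizes (22 autosomes, decreasing)
_CHROM_WEIGHTS = np.linspace(1.7, 0.35, 22)


@dataclass(frozen=True)
class SimSpec:
    """Study conditions for one simulated cell.

    Defaults mirror the ploidy-recovery benchmark conditions: ~5000 valid
    500 kb bins, rho = 100 reads per copy per bin, NB overdispersion 0.05,
    ten gain/loss events per cell.  Bias amplitudes default to zero (bias is
    switched on where a test exercises it).  ``s_inflation`` is the count
    multiplier for replicated bins of an S-phase cell (2.0 = fully doubled
    early-replicating DNA); ``s_fraction`` is the cell's replication
    progression (fraction of the genome already replicated, by replication
    time order).  ``multiplicity`` is the number of physical genome copies
    relative to the nominal profile (1 = G1, 2 = doubled/G2-like,
    k = k-fold multiplet).
    """

    n_bins: int = 5000
    bin_width: int = 500_000
    n_chroms: int = 22
    background_ploidy: int = 2
    n_cna_events: int = 20
    event_length_mean: float = 20.0  # mean length (bins) of focal events
    arm_event_prob: float = 0.4  # fraction of events that are arm-level
    arm_length_range: tuple = (50, 250)  # arm-level event lengths (bins)
    p_double_step: float = 0.2  # probability an event is +/-2 instead of +/-1
    rho: float = 100.0
    alpha: float = 0.05
    gc_bias_amp: float = 0.0
    map_bias_amp: float = 0.0
    s_phase: bool = False
    s_fraction: float = 0.5
    s_inflation: float = 2.0
    multiplicity: int = 1
    frag_len: int = 300
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.s_fraction <= 1.0:
            raise ValueError("s_fraction must lie in [0, 1]")
        if min(self.n_bins, self.bin_width, self.background_ploidy + 1, self.rho,
               self.multiplicity, self.frag_len) <= 0:
            raise ValueError("spec fields must be positive")


def _smooth_field(rng: np.random.Generator, n: int, autocorr: float = 20.0) -> np.ndarray:
    """Standardised smooth random field (unit variance, zero mean)."""
    x = gaussian_filter1d(rng.standard_normal(n + 200), autocorr)[100:-100]
    sd = x.std()
    return (x - x.mean()) / (sd if sd > 0 else 1.0)


def make_grid(
    n_bins: int = 5000,
    bin_width: int = 500_000,
    n_chroms: int = 22,
    seed: int = 0,
    autocorr: float = 20.0,
    rt_autocorr: float = 3.0,
) -> BinGrid:
    """Synthetic bin grid with smooth gc/mappability/reptime tracks.

    GC and mappability vary on a scale of ``autocorr`` bins (isochore-like);
    replication time varies on the much shorter ``rt_autocorr`` scale,
    matching the size of replication-timing domains (a couple of Mb) at
    500 kb bins.
    """
    rng = np.random.default_rng(seed)
    w = _CHROM_WEIGHTS[:n_chroms]
    sizes = np.maximum(np.round(n_bins * w / w.sum()).astype(int), 2)
    # adjust largest chromosome so the total is exact
    sizes[0] += n_bins - sizes.sum()
    chroms = np.concatenate([[f"chr{i + 1}"] * s for i, s in enumerate(sizes)])
    starts = np.concatenate([np.arange(s) * bin_width for s in sizes])
    gc = np.clip(0.42 + 0.05 * _smooth_field(rng, n_bins, autocorr), 0.25, 0.65)
    mp = np.clip(92.0 + 6.0 * _smooth_field(rng, n_bins, autocorr), 70.0, 100.0)
    rt = _smooth_field(rng, n_bins, rt_autocorr)
    df = pd.DataFrame(
        {
            "chrom": chroms,
            "start": starts,
            "end": starts + bin_width,
            "gc": gc,
            "mappability": mp,
            "reptime": rt,
            "valid": True,
        }
    )
    return BinGrid(df, width=bin_width)


def simulate_cn_profile(spec: SimSpec, grid: BinGrid, rng: np.random.Generator | None = None) -> np.ndarray:
    """Integer copy numbers: background ploidy plus random gain/loss events.

    Events are contiguous runs within one chromosome; a fraction
    ``arm_event_prob`` are arm-level (length uniform over
    ``arm_length_range`` bins), the rest focal with geometric lengths of
    mean ``event_length_mean``.  Steps are +/-1 (or +/-2 with probability
    ``p_double_step``), applied sequentially and clipped at zero — later
    events may nest inside or overlap earlier ones, as in clonal evolution.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    c = np.full(grid.n_bins, spec.background_ploidy, dtype=np.int64)
    codes = grid.chrom_codes
    for _ in range(spec.n_cna_events):
        start = int(rng.integers(0, grid.n_bins))
        if rng.random() < spec.arm_event_prob:
            length = int(rng.uniform(*spec.arm_length_range))
        else:
            length = 1 + int(rng.geometric(1.0 / spec.event_length_mean))
        end = min(start + length, grid.n_bins)
        # confine the event to the chromosome of its start bin
        end = min(end, int(np.searchsorted(codes, codes[start], side="right")))
        step = 2 if rng.random() < spec.p_double_step else 1
        sign = 1 if rng.random() < 0.5 else -1
        c[start:end] = np.maximum(c[start:end] + sign * step, 0)
    return c


def _replication_factor(spec: SimSpec, grid: BinGrid) -> np.ndarray:
    """Per-bin count multiplier: early-replicating bins are inflated for
    S-phase cells once the cell's progression has passed them.

    Replication-timing tracks follow the Repli-chip convention where larger
    values mean earlier replication, so a cell at progression f has
    replicated the top-f fraction of bins by replication time.
    """
    if not spec.s_phase:
        return np.ones(grid.n_bins)
    rt = grid.reptime
    if spec.s_fraction <= 0:
        return np.ones(grid.n_bins)
    q = np.quantile(rt, 1.0 - spec.s_fraction)
    return np.where(rt > q, spec.s_inflation, 1.0)


def _bias_factor(spec: SimSpec, grid: BinGrid) -> np.ndarray:
    gc = grid.gc - grid.gc.mean()
    mp = (grid.mappability - grid.mappability.mean()) / 100.0
    return np.exp(spec.gc_bias_amp * gc + spec.map_bias_amp * mp)


def _latent_rate(
    c: np.ndarray, spec: SimSpec, grid: BinGrid, rng: np.random.Generator
) -> np.ndarray:
    """Per-bin expected count rho*c*B*R times a gamma(1/alpha, alpha) latent,
    so that Poisson sampling yields NB(mean, alpha) marginally."""
    base = spec.rho * c * _bias_factor(spec, grid) * _replication_factor(spec, grid)
    if spec.alpha > 0:
        g = rng.gamma(1.0 / spec.alpha, spec.alpha, size=len(base))
    else:
        g = np.ones(len(base))
    return base * g


def simulate_counts(
    c: np.ndarray,
    spec: SimSpec,
    grid: BinGrid,
    rng: np.random.Generator | None = None,
    cell_id: str = "sim",
) -> CellCounts:
    """NB-distributed bin counts for a copy-number profile.

    x_j ~ NB(mean = rho * c_j * B_j * R_j, alpha) with B the GC/mappability
    bias factor and R the S-phase replication inflation.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    lam = _latent_rate(np.asarray(c, float), spec, grid, rng)
    x = rng.poisson(lam)
    return CellCounts(cell_id=cell_id, counts=x, technology="synthetic", paired_end=True)


def _place_nonoverlapping(
    rng: np.random.Generator, n_frags: np.ndarray, width: int, frag_len: int
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised placement of n_frags[i] non-overlapping fragments in each
    interval of ``width`` bp; returns (group index, start offset)."""
    total = int(n_frags.sum())
    if total == 0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    group = np.repeat(np.arange(len(n_frags)), n_frags)
    free = width - n_frags[group] * frag_len  # free space in the group's interval
    u = rng.random(total) * free
    order = np.lexsort((u, group))
    u_sorted = u[order]
    rank = np.empty(total, np.int64)
    start_of_group = np.concatenate([[0], np.cumsum(n_frags)])[:-1]
    rank = np.arange(total) - start_of_group[group[order]]
    starts = (u_sorted + rank * frag_len).astype(np.int64)
    return group[order], starts


def simulate_fragments(
    c: np.ndarray,
    spec: SimSpec,
    grid: BinGrid,
    rng: np.random.Generator | None = None,
    latent: np.ndarray | None = None,
) -> FragmentSet:
    """Paired-end fragments placed on physical genome copies.

    Bin j carries ``c_j * multiplicity`` physical copies; each copy receives
    Poisson-many fragments at the per-copy rate (rho * B * R * latent) /
    multiplicity, placed without intra-copy overlap (fragments from different
    copies may overlap).  The copy-limit law -- overlap depth at any position
    never exceeding the local physical copy number -- holds by construction.
    PCR-duplicate removal (identical coordinates) is applied.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    c = np.asarray(c, np.int64)
    if latent is None:
        latent = _latent_rate(c.astype(float), spec, grid, rng)
    with np.errstate(divide="ignore", invalid="ignore"):
        per_copy = np.where(c > 0, latent / np.maximum(c, 1), 0.0) / spec.multiplicity
    n_copies = c * spec.multiplicity
    width = grid.width
    cap = max(width // spec.frag_len, 1)

    copy_bin = np.repeat(np.arange(grid.n_bins), n_copies)
    rate = per_copy[copy_bin]
    n_frags = np.minimum(rng.poisson(rate), cap)
    group, offsets = _place_nonoverlapping(rng, n_frags, width, spec.frag_len)
    bin_idx = copy_bin[group]
    start = grid.start[bin_idx] + offsets
    frags = FragmentSet(
        chrom=grid.chrom[bin_idx], start=start, end=start + spec.frag_len
    )
    return frags.dedup()


def simulate_cell(
    spec: SimSpec,
    grid: BinGrid,
    rng: np.random.Generator | None = None,
    cell_id: str = "sim",
    with_fragments: bool = False,
) -> tuple[CellCounts, np.ndarray, FragmentSet | None]:
    """One cell end to end: (counts, true copy numbers, fragments or None).

    With fragments, the counts are the per-bin fragment-start tallies so the
    two views of the cell are exactly consistent.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    c = simulate_cn_profile(spec, grid, rng)
    if not with_fragments:
        counts = simulate_counts(c, spec, grid, rng, cell_id=cell_id)
        return counts, c, None
    latent = _latent_rate(c.astype(float), spec, grid, rng)
    frags = simulate_fragments(c, spec, grid, rng, latent=latent)
    bins = grid.bin_of(frags.chrom, frags.start)
    x = np.bincount(bins[bins >= 0], minlength=grid.n_bins)
    counts = CellCounts(cell_id=cell_id, counts=x, technology="synthetic", paired_end=True)
    return counts, c, frags


def simulate_population(
    n_g1: int,
    n_s: int,
    n_doubled: int,
    spec: SimSpec,
    seed: int = 0,
    with_fragments: bool = False,
) -> dict:
    """Labelled population for end-to-end tests.

    Returns a dict with ``cells`` (list of CellCounts), ``fragments`` (list
    of FragmentSet or None), ``truth`` (DataFrame: cell, phase, multiplicity,
    true_ploidy, rho) and ``grid``.  Deterministic given ``seed``; per-cell
    streams are spawned from a single SeedSequence so outputs are independent
    of evaluation order.
    """
    if min(n_g1, n_s, n_doubled) < 0:
        raise ValueError("cell counts must be non-negative")
    grid = make_grid(spec.n_bins, spec.bin_width, spec.n_chroms, seed=seed)
    phases = ["G1"] * n_g1 + ["S"] * n_s + ["doubled"] * n_doubled
    seeds = np.random.SeedSequence(seed).spawn(len(phases))
    cells, frag_sets, rows = [], [], []
    for i, (phase, ss) in enumerate(zip(phases, seeds)):
        cell_spec = replace(
            spec,
            s_phase=(phase == "S"),
            multiplicity=2 * spec.multiplicity if phase == "doubled" else spec.multiplicity,
        )
        rng = np.random.default_rng(ss)
        if phase == "S":
            cell_spec = replace(cell_spec, s_fraction=float(rng.uniform(0.2, 0.8)))
        cell_id = f"cell_{i:04d}_{phase}"
        counts, c, frags = simulate_cell(
            cell_spec, grid, rng, cell_id=cell_id, with_fragments=with_fragments
        )
        cells.append(counts)
        frag_sets.append(frags)
        rows.append(
            {
                "cell": cell_id,
                "phase": phase,
                "multiplicity": cell_spec.multiplicity,
                "true_ploidy": float(np.mean(c[grid.autosomal])),
                "rho": spec.rho,
                "s_fraction": cell_spec.s_fraction if phase == "S" else 0.0,
            }
        )
    return {
        "cells": cells,
        "fragments": frag_sets,
        "truth": pd.DataFrame(rows),
        "grid": grid,
    }
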