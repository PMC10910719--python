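"""Orchestration of the full per-cell workflow.

Step 1 segment -> step 2 grid-mixture fit -> step 3 solution selection ->
step 4 read-density residual and optional refit with a doubled ploidy
window; replication classification runs population-wide afterwards.  Each
cell is processed independently (errors quarantine the cell, never the
batch), so batches parallelise trivially and results do not depend on worker
count or order.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .density import (
    RHO_MIN,
    Z_CUT,
    DensityModel,
    ELEVATED,
    FragmentSet,
    cell_density_at_cn2,
    classify_ploidy_state,
    compute_overlap_density,
    density_residual,
)
from .exceptions import ScploidyError, SingleEndError
from .grid import BinGrid, CellCounts
from .ploidy import (
    PLOIDY_WINDOW,
    RESTARTS,
    TRUNCATION,
    doubled_window,
    fit_cell_ploidy,
    refit_with_window,
)
from .replication import (
    ACTIVITY_SD_MULT,
    MI_IQR_MULT,
    cell_cycle_features,
    classify_s_phase,
)
from .segment import MIN_SEG_LEN, PENALTY_SCALE


@dataclass
class RunConfig:
    """Validated, serialisable run configuration."""

    bin_kb: int = 500
    ploidy_window: tuple = PLOIDY_WINDOW
    truncation: int = TRUNCATION
    restarts: int = RESTARTS
    penalty_scale: float = PENALTY_SCALE
    min_seg_len: int = MIN_SEG_LEN
    rho_min: float = RHO_MIN
    z_cut: float = Z_CUT
    s_phase_sd_mult: float = ACTIVITY_SD_MULT
    mi_iqr_mult: float = MI_IQR_MULT
    mapq_min: int = 20
    seed: int = 0
    run_density: bool = True
    run_refit: bool = True
    run_cycle: bool = True

    def __post_init__(self):
        lo, hi = self.ploidy_window
        if not (0 < lo < hi):
            raise ValueError("invalid ploidy window")
        if self.truncation < 1 or self.restarts < 1 or self.min_seg_len < 1:
            raise ValueError("invalid config")
        self.ploidy_window = (float(lo), float(hi))

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha1(payload).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "ploidy_window" in data:
            data["ploidy_window"] = tuple(data["ploidy_window"])
        return cls(**data)

    def to_yaml(self, path: str) -> None:
        import yaml

        data = self.to_dict()
        data["ploidy_window"] = list(data["ploidy_window"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh)


def bam_to_counts(
    bam_path: str,
    grid: BinGrid,
    mapq_min: int = 20,
    want_fragments: bool = True,
    cell_id: str | None = None,
) -> tuple[CellCounts, FragmentSet | None]:
    """Bin counts (and fragment intervals) from a coordinate-sorted BAM.

    Counts proper-pair, primary, non-duplicate first-mate alignments with
    MAPQ >= ``mapq_min`` into grid bins by fragment start; fragments are the
    (start of first mate, end of second mate) template intervals,
    deduplicated.
    """
    import pysam

    af = pysam.AlignmentFile(bam_path, "rb")
    if af.header.get("HD", {}).get("SO") != "coordinate":
        raise ScploidyError(f"{bam_path}: BAM must be coordinate-sorted")
    if not af.has_index():
        raise ScploidyError(f"{bam_path}: BAM index required")
    chroms, starts, ends = [], [], []
    single_end_seen = False
    for read in af.fetch():
        if (
            read.is_unmapped
            or read.is_secondary
            or read.is_supplementary
            or read.is_duplicate
            or read.mapping_quality < mapq_min
        ):
            continue
        if not read.is_paired:
            single_end_seen = True
            continue
        if not read.is_proper_pair:
            continue
        # count each template once, via the leftmost mate
        if read.template_length <= 0:
            continue
        chroms.append(read.reference_name)
        starts.append(read.reference_start)
        ends.append(read.reference_start + read.template_length)
    af.close()
    if want_fragments and single_end_seen and not chroms:
        raise SingleEndError(
            f"{bam_path}: single-end reads cannot provide fragment intervals"
        )
    counts = np.zeros(grid.n_bins, np.int64)
    frags = None
    if chroms:
        frags = FragmentSet(np.array(chroms), np.array(starts), np.array(ends)).dedup()
        bins = grid.bin_of(frags.chrom, frags.start)
        counts = np.bincount(bins[bins >= 0], minlength=grid.n_bins)
    cid = cell_id or bam_path
    return (
        CellCounts(cell_id=cid, counts=counts, technology="bam", paired_end=not single_end_seen),
        frags if want_fragments else None,
    )


def run_cell(
    counts: CellCounts,
    grid: BinGrid,
    config: RunConfig,
    fragments: FragmentSet | None = None,
    density_model: DensityModel | None = None,
) -> dict:
    """Steps 1-4 for one cell; returns a flat record plus the solution.

    The density residual is computed when fragments and a reference model are
    available and rho >= rho_min; ELEVATED cells are refitted with a doubled
    ploidy window when ``run_refit`` is enabled.
    """
    record: dict = {
        "cell": counts.cell_id,
        "config_hash": config.hash,
        "version": __version__,
        "error": "",
    }
    try:
        sol = fit_cell_ploidy(
            counts,
            grid,
            window=config.ploidy_window,
            T=config.truncation,
            seed=config.seed,
            restarts=config.restarts,
            penalty_scale=config.penalty_scale,
        )
    except ScploidyError as exc:
        record["error"] = str(exc)
        record["solution"] = None
        return record
    record.update(sol.to_record())
    record["state"] = ""
    record["solution"] = sol

    if config.run_density and fragments is not None and density_model is not None:
        if not counts.paired_end:
            raise SingleEndError("read-density step requires paired-end data")
        profile = compute_overlap_density(fragments, grid)
        cn_full = np.full(grid.n_bins, np.nan)
        cn_full[grid.valid] = sol.copy_number
        dens = cell_density_at_cn2(profile, cn_full, grid)
        res = density_residual(dens, sol.rho, density_model, rho_min=config.rho_min)
        record.update(
            {k: res[k] for k in ("density_cn2", "expected_density", "residual", "z")}
        )
        if res["classifiable"]:
            state = classify_ploidy_state(res, density_model, z_cut=config.z_cut)
            record["state"] = state
            if state == ELEVATED and config.run_refit:
                refit = refit_with_window(
                    counts,
                    grid,
                    doubled_window(sol.ploidy),
                    seed=config.seed,
                    profile=sol.profile,
                    T=config.truncation,
                    restarts=config.restarts,
                )
                record["ploidy_refit"] = refit.ploidy
                record["rho_refit"] = refit.rho
                record["flag_refit"] = True
                record["solution"] = refit
    return record


def run_population(
    cells: list[CellCounts],
    grid: BinGrid,
    config: RunConfig,
    fragments: list[FragmentSet | None] | None = None,
    density_model: DensityModel | None = None,
) -> pd.DataFrame:
    """Run all cells, then population-wide replication classification.

    One bad cell never aborts the batch: its record carries the error and is
    excluded from the population thresholds.
    """
    fragments = fragments or [None] * len(cells)
    records = []
    for counts, frags in zip(cells, fragments):
        try:
            rec = run_cell(counts, grid, config, fragments=frags, density_model=density_model)
        except ScploidyError as exc:
            rec = {"cell": counts.cell_id, "error": str(exc), "solution": None}
        records.append(rec)

    if config.run_cycle:
        feats = []
        for counts, rec in zip(cells, records):
            sol = rec.get("solution")
            if sol is None:
                feats.append(None)
                continue
            try:
                feats.append(cell_cycle_features(counts.counts, grid, sol.rho))
            except ScploidyError:
                feats.append(None)
        ok = [i for i, f in enumerate(feats) if f is not None]
        if len(ok) >= 20:
            acts = np.array([feats[i]["cycling_activity"] for i in ok])
            mis = np.array([feats[i]["mi"] for i in ok])
            calls = classify_s_phase(
                acts, mis, sd_mult=config.s_phase_sd_mult, iqr_mult=config.mi_iqr_mult
            )
            for row, i in enumerate(ok):
                records[i].update(
                    {
                        "cycling_activity": acts[row],
                        "mi": mis[row],
                        "s_phase": bool(calls["s_phase"].iloc[row]),
                        "s_phase_reason": calls["reason"].iloc[row],
                    }
                )
    for rec in records:
        rec.pop("solution", None)
    return pd.DataFrame(records)
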