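"""Fixed-width genomic bin grids.

A :class:`BinGrid` is the genomic coordinate system every other module works
on: a set of non-overlapping, sorted, (nominally) fixed-width bins, each
annotated with GC content, mappability, mean replication time and a validity
flag.  Counts, copy numbers and densities are all vectors aligned to the grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GRID_COLUMNS = ["chrom", "start", "end", "gc", "mappability", "reptime", "valid"]

#: autosome names accepted for ploidy averaging (both "1" and "chr1" style)
SEX_CHROMS = {"X", "Y", "chrX", "chrY"}


@dataclass
class BinGrid:
    """Fixed-width bin annotation.

    Parameters
    ----------
    df
        DataFrame with columns ``chrom, start, end, gc, mappability, reptime,
        valid``.  Coordinates are 0-based half-open; ``gc`` in [0, 1];
        ``mappability`` in [0, 100]; ``reptime`` a standardized (unitless)
        mean replication time; ``valid`` a boolean mask of usable bins.
    width
        Nominal bin width in bp.  Every bin except possibly the last per
        chromosome has ``end - start == width``.
    """

    df: pd.DataFrame
    width: int
    _chrom_codes: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in GRID_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"grid is missing columns: {missing}")
        self.df = self.df.reset_index(drop=True)
        self._validate()
        self._chrom_codes = pd.factorize(self.df["chrom"].to_numpy())[0]

    def _validate(self) -> None:
        df = self.df
        gc = df["gc"].to_numpy(float)
        mp = df["mappability"].to_numpy(float)
        if np.any((gc < 0) | (gc > 1)):
            raise ValueError("gc must lie in [0, 1]")
        if np.any((mp < 0) | (mp > 100)):
            raise ValueError("mappability must lie in [0, 100]")
        for _, sub in df.groupby("chrom", sort=False):
            start = sub["start"].to_numpy()
            end = sub["end"].to_numpy()
            if np.any(end <= start):
                raise ValueError("bins must have end > start")
            if np.any(start[1:] < end[:-1]):
                raise ValueError("bins overlap or are unsorted within chromosome")
            if len(start) > 1 and np.any((end[:-1] - start[:-1]) != self.width):
                raise ValueError("non-terminal bin width differs from grid width")

    # -- array views ------------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_bins(self) -> int:
        return len(self.df)

    @property
    def chrom(self) -> np.ndarray:
        return self.df["chrom"].to_numpy()

    @property
    def chrom_codes(self) -> np.ndarray:
        """Integer chromosome code per bin (order of first appearance)."""
        return self._chrom_codes

    @property
    def start(self) -> np.ndarray:
        return self.df["start"].to_numpy()

    @property
    def end(self) -> np.ndarray:
        return self.df["end"].to_numpy()

    @property
    def gc(self) -> np.ndarray:
        return self.df["gc"].to_numpy(float)

    @property
    def mappability(self) -> np.ndarray:
        return self.df["mappability"].to_numpy(float)

    @property
    def reptime(self) -> np.ndarray:
        return self.df["reptime"].to_numpy(float)

    @property
    def valid(self) -> np.ndarray:
        return self.df["valid"].to_numpy(bool)

    @valid.setter
    def valid(self, mask: np.ndarray) -> None:
        mask = np.asarray(mask, bool)
        if mask.shape != (len(self.df),):
            raise ValueError("valid mask has wrong length")
        self.df["valid"] = mask

    @property
    def autosomal(self) -> np.ndarray:
        """Boolean mask of bins on autosomes."""
        return ~self.df["chrom"].isin(SEX_CHROMS).to_numpy()

    def bin_of(self, chrom: np.ndarray, pos: np.ndarray) -> np.ndarray:
        """Map genomic positions to bin indices (-1 when outside the grid).

        Positions are assigned to the bin whose [start, end) interval contains
        them, per chromosome.
        """
        chrom = np.asarray(chrom)
        pos = np.asarray(pos)
        out = np.full(pos.shape, -1, dtype=np.int64)
        for name, sub in self.df.groupby("chrom", sort=False):
            sel = chrom == name
            if not np.any(sel):
                continue
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            idx = np.searchsorted(starts, pos[sel], side="right") - 1
            ok = (idx >= 0) & (pos[sel] < ends[np.clip(idx, 0, len(ends) - 1)])
            res = np.where(ok, sub.index.to_numpy()[np.clip(idx, 0, len(ends) - 1)], -1)
            out[sel] = res
        return out

    # -- I/O --------------------------------------------------------------
    def to_bed(self, path: str) -> None:
        """Write as BED-style TSV with header (0-based half-open intervals)."""
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_bed(cls, path: str, width: int | None = None) -> "BinGrid":
        """Read a grid written by :meth:`to_bed`.

        ``width`` is inferred from the modal bin width when not given.
        """
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        if width is None:
            widths = (df["end"] - df["start"]).to_numpy()
            width = int(np.bincount(widths).argmax()) if len(widths) else 0
        if "valid" in df.columns:
            df["valid"] = df["valid"].astype(bool)
        return cls(df, width=width)


@dataclass
class CellCounts:
    """Per-bin read counts of one cell, aligned to a :class:`BinGrid`."""

    cell_id: str
    counts: np.ndarray
    technology: str = "synthetic"
    paired_end: bool = True

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1:
            raise ValueError("counts must be a 1-D vector")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def counts_to_frame(cells: list[CellCounts]) -> pd.DataFrame:
    """Stack cells into a cells x bins DataFrame (rows indexed by cell id)."""
    return pd.DataFrame(
        np.vstack([c.counts for c in cells]), index=[c.cell_id for c in cells]
    )
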