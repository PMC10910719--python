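"""Bin grid container and reference-population quality control."""

import numpy as np
import pandas as pd
import pytest

import scploidy as sp
from scploidy.exceptions import EmptyCellError, TooFewBinsError
from scploidy.grid import BinGrid, CellCounts
from scploidy.qc import (
    aggregate_mask,
    combine_technology_masks,
    hard_filter,
    median_bin_quality,
    normalize_cell_counts,
    smooth_residual_filter,
    total_count_filter,
)


def _flat_grid(n, width=100, gc=0.4, mappability=90.0):
    df = pd.DataFrame(
        {
            "chrom": ["chr1"] * n,
            "start": np.arange(n) * width,
            "end": (np.arange(n) + 1) * width,
            "gc": gc,
            "mappability": mappability,
            "reptime": 0.0,
            "valid": True,
        }
    )
    return BinGrid(df, width=width)


class TestBinGrid:
    def test_rejects_overlapping_bins(self):
        df = pd.DataFrame(
            {
                "chrom": ["chr1", "chr1"],
                "start": [0, 50],
                "end": [100, 150],
                "gc": 0.4,
                "mappability": 90.0,
                "reptime": 0.0,
                "valid": True,
            }
        )
        with pytest.raises(ValueError):
            BinGrid(df, width=100)

    def test_bed_round_trip(self, tmp_path, tiny_grid):
        path = tmp_path / "grid.tsv"
        tiny_grid.to_bed(str(path))
        back = BinGrid.from_bed(str(path))
        pd.testing.assert_frame_equal(back.df, tiny_grid.df)
        assert back.width == tiny_grid.width

    def test_bin_of_maps_positions(self, tiny_grid):
        idx = tiny_grid.bin_of(
            np.array([tiny_grid.chrom[5]]), np.array([tiny_grid.start[5] + 1])
        )
        assert idx[0] == 5
        # a position beyond the chromosome end maps nowhere
        last = tiny_grid.df[tiny_grid.df.chrom == tiny_grid.chrom[0]].iloc[-1]
        miss = tiny_grid.bin_of(np.array([tiny_grid.chrom[0]]), np.array([last.end + 10]))
        assert miss[0] == -1


class TestNormalize:
    def test_constant_cell(self):
        grid = _flat_grid(4)
        out = normalize_cell_counts(CellCounts("c", np.array([2, 2, 2, 2])), grid)
        assert np.allclose(out, 1.0)

    def test_mean_by_construction(self):
        grid = _flat_grid(4)
        out = normalize_cell_counts(CellCounts("c", np.array([0, 4, 4, 8])), grid)
        assert np.allclose(out, [0, 1, 1, 2])

    def test_output_mean_is_one_for_random_cells(self, rng):
        grid = _flat_grid(300)
        for _ in range(100):
            y = rng.negative_binomial(10, 0.3, size=300)
            if y.sum() == 0:
                continue
            out = normalize_cell_counts(CellCounts("c", y), grid)
            assert out.mean() == pytest.approx(1.0, abs=1e-9)

    def test_empty_cell_raises(self):
        grid = _flat_grid(4)
        with pytest.raises(EmptyCellError):
            normalize_cell_counts(CellCounts("c", np.zeros(4, int)), grid)


class TestMedianQuality:
    def test_single_cell_identity(self, rng):
        v = rng.random(20)
        assert np.allclose(median_bin_quality(v), v)

    def test_median_of_three(self):
        m = np.array([[0.5], [1.0], [1.5]])
        assert median_bin_quality(m)[0] == 1.0

    def test_matches_sort_based_oracle(self, rng):
        mat = rng.random((50, 200))
        oracle = np.sort(mat, axis=0)[24:26].mean(axis=0)  # even-count median
        assert np.allclose(median_bin_quality(mat), oracle)


class TestHardFilter:
    def test_keep_normal_bin(self):
        grid = _flat_grid(1, mappability=90)
        assert not hard_filter(np.array([1.0]), grid)[0]

    @pytest.mark.parametrize(
        "median,mappability,removed",
        [(5.0, 90, True), (0.05, 90, True), (1.0, 60, True), (1.0, 70, False)],
    )
    def test_thresholds(self, median, mappability, removed):
        grid = _flat_grid(1, mappability=mappability)
        assert hard_filter(np.array([median]), grid)[0] == removed

    def test_planted_violations_counted(self, rng):
        n = 500
        grid = _flat_grid(n)
        medians = np.ones(n)
        bad = rng.choice(n, size=50, replace=False)
        medians[bad[:25]] = 6.0
        medians[bad[25:]] = 0.01
        removed = hard_filter(medians, grid)
        assert removed.sum() == 50
        assert set(np.flatnonzero(removed)) == set(bad)

    def test_monotone_in_thresholds(self, rng):
        n = 300
        grid = _flat_grid(n)
        medians = rng.lognormal(0, 0.6, size=n)
        loose = hard_filter(medians, grid, median_hi=4, median_lo=0.1)
        tight = hard_filter(medians, grid, median_hi=3, median_lo=0.2)
        assert np.all(loose <= tight)  # tightening never un-removes


class TestSmoothResidualFilter:
    def _biased_grid(self, rng, n=2000):
        df = pd.DataFrame(
            {
                "chrom": ["chr1"] * n,
                "start": np.arange(n) * 100,
                "end": (np.arange(n) + 1) * 100,
                "gc": rng.uniform(0.3, 0.6, n),
                "mappability": rng.uniform(75, 100, n),
                "reptime": 0.0,
                "valid": True,
            }
        )
        return BinGrid(df, width=100)

    def test_identical_medians_nothing_removed(self, rng):
        grid = self._biased_grid(rng)
        removed = smooth_residual_filter(np.ones(grid.n_bins), grid)
        assert removed.sum() == 0

    def test_planted_outlier_removed(self, rng):
        grid = self._biased_grid(rng)
        medians = 1.0 + 0.5 * (grid.gc - 0.45) + rng.normal(0, 0.02, grid.n_bins)
        medians[123] += 3 * 0.02 * 3  # far off the gc trend
        removed = smooth_residual_filter(medians, grid, density_quantile=1.0)
        assert removed[123]

    def test_two_sd_rule_gaussian_fraction(self, rng):
        grid = self._biased_grid(rng, n=20000)
        medians = 1.0 + rng.normal(0, 0.05, grid.n_bins)
        removed = smooth_residual_filter(medians, grid, density_quantile=1.0)
        # 2 Phi(-2) = 4.55% of Gaussian mass lies beyond 2 SD
        assert removed.mean() == pytest.approx(0.0455, abs=0.01)

    def test_unbiased_reference_removal_bounded(self, rng):
        grid = self._biased_grid(rng, n=5000)
        medians = 1.0 + rng.normal(0, 0.05, grid.n_bins)
        removed = smooth_residual_filter(medians, grid)
        assert removed.mean() <= 0.06

    def test_density_only_mode_skips_trend(self, rng):
        grid = self._biased_grid(rng)
        medians = 1.0 + rng.normal(0, 0.05, grid.n_bins)
        removed = smooth_residual_filter(medians, grid, mode="density_only")
        # only the KDE criterion applies; ~2% of mass lies outside the 99%
        # high-density region of each of the two KDEs
        assert removed.mean() < 0.04

    def test_too_few_bins_raises(self, rng):
        grid = _flat_grid(40)
        with pytest.raises(TooFewBinsError):
            smooth_residual_filter(np.ones(40), grid)


class TestCombineMasks:
    def test_single_mask_unchanged(self, rng):
        m = rng.random(30) > 0.2
        assert np.array_equal(combine_technology_masks([m]), m)

    def test_disjoint_removals_union(self):
        a = np.ones(100, bool)
        b = np.ones(100, bool)
        a[:5] = False
        b[10:17] = False
        combined = combine_technology_masks([a, b])
        assert (~combined).sum() == 12

    def test_matches_set_union_oracle(self, rng):
        masks = [rng.random(200) > 0.1 for _ in range(4)]
        combined = combine_technology_masks(masks)
        removed_oracle = set()
        for m in masks:
            removed_oracle |= set(np.flatnonzero(~m))
        assert set(np.flatnonzero(~combined)) == removed_oracle

    def test_blacklist_intersected(self):
        m = np.ones(10, bool)
        blacklist = np.zeros(10, bool)
        blacklist[3] = True
        assert not combine_technology_masks([m], blacklist=blacklist)[3]

    def test_mismatched_lengths_raise(self):
        with pytest.raises(ValueError):
            combine_technology_masks([np.ones(5, bool), np.ones(6, bool)])


class TestAggregation:
    def test_fine_to_coarse_majority_rule(self):
        fine = _flat_grid(10, width=100)
        coarse = _flat_grid(2, width=500)
        fine_valid = np.ones(10, bool)
        fine_valid[:3] = False  # 3/5 invalid in the first coarse bin
        out = aggregate_mask(fine_valid, fine, coarse, invalid_fraction=0.5)
        assert not out[0] and out[1]
        out = aggregate_mask(fine_valid, fine, coarse, invalid_fraction=0.7)
        assert out[0] and out[1]


class TestTotalCountFilter:
    def test_outlier_bins_removed(self, rng):
        totals = rng.normal(100, 5, 200)
        totals[7] = 300.0
        removed = total_count_filter(totals, sd_mult=3)
        assert removed[7]
        assert removed.mean() < 0.05


def test_reference_qc_pipeline_runs(rng):
    grid = sp.make_grid(600, n_chroms=4, seed=3)
    spec = sp.SimSpec(n_bins=600, rho=50.0, n_cna_events=0, gc_bias_amp=0.5)
    cells = []
    for i in range(8):
        r = np.random.default_rng(i)
        c = np.full(600, 2)
        cells.append(sp.simulate_counts(c, spec, grid, r, cell_id=f"c{i}"))
    mask = sp.reference_qc_mask(cells, grid)
    assert mask.dtype == bool and mask.mean() > 0.8
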