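"""Fragment overlap density and WGD/G2 resolution."""

import numpy as np
import pytest
from dataclasses import replace

import scploidy as sp
from scploidy.density import (
    CONSISTENT,
    ELEVATED,
    DensityModel,
    FragmentSet,
    cell_density_at_cn2,
    classify_ploidy_state,
    compute_overlap_density,
    density_residual,
    fit_reference_model,
    fragment_overlap_counts,
    max_overlap_depth,
)
from scploidy.exceptions import DensityError


def _brute_force_overlaps(frags):
    out = np.zeros(len(frags), int)
    for i in range(len(frags)):
        for j in range(len(frags)):
            if i == j or frags.chrom[i] != frags.chrom[j]:
                continue
            if frags.start[j] < frags.end[i] and frags.end[j] > frags.start[i]:
                out[i] += 1
    return out


class TestOverlapCounts:
    def test_disjoint_fragments_zero(self):
        f = FragmentSet(np.array(["chr1"] * 3), np.array([0, 100, 200]), np.array([50, 150, 250]))
        assert np.all(fragment_overlap_counts(f) == 0)

    def test_stacked_fragments_k_minus_one(self):
        k = 5
        f = FragmentSet(np.array(["chr1"] * k), np.arange(k) * 0 + 10, np.full(k, 60))
        # identical coordinates would deduplicate; stagger starts by 1 bp
        f = FragmentSet(np.array(["chr1"] * k), 10 + np.arange(k), np.full(k, 300))
        assert np.all(fragment_overlap_counts(f) == k - 1)

    def test_matches_brute_force_oracle(self, rng):
        n = 300
        starts = rng.integers(0, 5000, n)
        f = FragmentSet(
            np.array(["chr1"] * (n // 2) + ["chr2"] * (n - n // 2)),
            starts,
            starts + rng.integers(50, 400, n),
        ).dedup()
        assert np.array_equal(fragment_overlap_counts(f), _brute_force_overlaps(f))

    def test_uniform_rate_mean_density(self, rng):
        # Poisson fragments at rate lam per bp, length L: each fragment is
        # overlapped by ~2 lam L others (starts within (start-L, end))
        lam, L, span = 0.002, 200, 2_000_000
        n = rng.poisson(lam * span)
        starts = np.sort(rng.integers(0, span, n))
        f = FragmentSet(np.array(["chr1"] * n), starts, starts + L).dedup()
        ov = fragment_overlap_counts(f)
        assert ov.mean() == pytest.approx(2 * lam * L, rel=0.05)


class TestMaxDepth:
    def test_single_copy_placement_depth_one(self, tiny_grid):
        spec = sp.SimSpec(n_bins=200, n_chroms=4, background_ploidy=1,
                          n_cna_events=0, rho=60.0, alpha=0.0)
        r = np.random.default_rng(0)
        c = np.ones(200, dtype=int)
        frags = sp.simulate_fragments(c, spec, tiny_grid, r)
        assert max_overlap_depth(frags) <= 1

    def test_depth_bounded_by_copies(self, tiny_grid):
        spec = sp.SimSpec(n_bins=200, n_chroms=4, background_ploidy=2,
                          n_cna_events=0, rho=150.0, alpha=0.0, multiplicity=2)
        r = np.random.default_rng(1)
        c = np.full(200, 2)
        frags = sp.simulate_fragments(c, spec, tiny_grid, r)
        assert max_overlap_depth(frags) <= 4  # c=2 times multiplicity 2


class TestDensityProfile:
    def test_empty_fragment_set(self, tiny_grid):
        prof = compute_overlap_density(
            FragmentSet(np.array([], dtype=str), np.array([], int), np.array([1], int)[:0]),
            tiny_grid,
        )
        assert np.all(np.isnan(prof.density))

    def test_bins_without_fragments_are_missing(self, tiny_grid):
        f = FragmentSet(
            np.array([tiny_grid.chrom[0]] * 2),
            np.array([10, 20]) + tiny_grid.start[0],
            np.array([310, 320]) + tiny_grid.start[0],
        )
        prof = compute_overlap_density(f, tiny_grid)
        assert prof.n_fragments[0] == 2
        assert prof.density[0] == 1.0
        assert np.isnan(prof.density[5])


class TestDensityAtCn2:
    def test_uniform_cn2_falls_back_to_median(self, tiny_grid, rng):
        d = np.full(tiny_grid.n_bins, 0.3)
        prof = sp.DensityProfile(d, np.ones(tiny_grid.n_bins, int))
        cn = np.full(tiny_grid.n_bins, 2.0)
        assert cell_density_at_cn2(prof, cn, tiny_grid) == pytest.approx(0.3)

    def test_exact_line_predicts_cn2(self, tiny_grid, rng):
        cn = rng.choice([1.0, 3.0], size=tiny_grid.n_bins)
        d = 0.1 * cn
        prof = sp.DensityProfile(d, np.ones(tiny_grid.n_bins, int))
        assert cell_density_at_cn2(prof, cn, tiny_grid) == pytest.approx(0.2, abs=1e-6)

    def test_robust_to_planted_outliers(self, small_grid, rng):
        cn = rng.choice([1.0, 2.0, 3.0], size=small_grid.n_bins)
        d = 0.1 * cn + rng.normal(0, 0.004, small_grid.n_bins)
        clean = cell_density_at_cn2(
            sp.DensityProfile(d.copy(), np.ones(small_grid.n_bins, int)), cn, small_grid
        )
        out = rng.choice(small_grid.n_bins, size=small_grid.n_bins // 100, replace=False)
        d[out] *= 10
        dirty = cell_density_at_cn2(
            sp.DensityProfile(d, np.ones(small_grid.n_bins, int)), cn, small_grid
        )
        assert abs(dirty - clean) / clean < 0.05

    def test_no_fragments_raises(self, tiny_grid):
        prof = sp.DensityProfile(np.full(tiny_grid.n_bins, np.nan), np.zeros(tiny_grid.n_bins, int))
        with pytest.raises(DensityError):
            cell_density_at_cn2(prof, np.full(tiny_grid.n_bins, 2.0), tiny_grid)


class TestReferenceModel:
    def test_quadratic_recovery(self, rng):
        a, b, c = 2e-6, 1.1e-3, 0.02
        rho = rng.uniform(75, 300, 200)
        dens = a * rho**2 + b * rho + c + rng.normal(0, 0.003, 200)
        model = fit_reference_model(rho, dens)
        assert model.coef[0] == pytest.approx(a, abs=3e-7)
        assert model.coef[1] == pytest.approx(b, abs=2e-4)
        assert model.resid_sd == pytest.approx(0.003, rel=0.25)

    def test_constant_density(self):
        rho = np.linspace(80, 200, 50)
        model = fit_reference_model(rho, np.full(50, 0.25))
        assert model.coef[0] == pytest.approx(0.0, abs=1e-12)
        assert model.coef[1] == pytest.approx(0.0, abs=1e-9)
        assert model.predict(100.0) == pytest.approx(0.25)

    def test_in_sample_mean_residual_zero(self, rng):
        rho = rng.uniform(75, 250, 80)
        dens = 0.001 * rho + rng.normal(0, 0.01, 80)
        model = fit_reference_model(rho, dens)
        resid = dens - np.polyval(model.coef, rho)
        assert resid.mean() == pytest.approx(0.0, abs=1e-9)

    def test_degenerate_range_raises(self):
        with pytest.raises(DensityError):
            fit_reference_model(np.full(30, 100.0), np.linspace(0, 1, 30))


class TestResidualClassification:
    def _model(self):
        return DensityModel(coef=np.array([0.0, 0.001, 0.0]), resid_sd=0.01, rho_range=(75, 250))

    def test_zero_residual_consistent(self):
        assert classify_ploidy_state(0.0, self._model()) == CONSISTENT

    def test_five_sd_elevated(self):
        assert classify_ploidy_state(5 * 0.01, self._model()) == ELEVATED

    def test_training_point_matches_formula(self):
        m = self._model()
        r = density_residual(0.15, 150.0, m)
        assert r["expected_density"] == pytest.approx(0.15)
        assert r["residual"] == pytest.approx(0.0)
        assert not r["extrapolated"]

    def test_low_rho_refused(self):
        m = self._model()
        r = density_residual(0.10, 50.0, m)
        assert not r["classifiable"]
        assert np.isfinite(r["residual"])  # still reported
        with pytest.raises(DensityError):
            classify_ploidy_state(r, m)


class TestMultiplicityMonotonicity:
    def test_density_increases_with_genome_multiplicity(self, rng):
        """At fixed fitted rho, expected overlap density at CN2 rises with
        the number of physical genome copies (1x, 2x, 3x)."""
        grid = sp.make_grid(400, n_chroms=4, seed=21)
        densities = []
        for g in (1, 2, 3):
            spec = sp.SimSpec(n_bins=400, n_chroms=4, rho=150.0, alpha=0.0,
                              n_cna_events=0, multiplicity=g, seed=30 + g)
            r = np.random.default_rng(30 + g)
            c = np.full(400, 2)
            frags = sp.simulate_fragments(c, spec, grid, r)
            prof = compute_overlap_density(frags, grid)
            densities.append(cell_density_at_cn2(prof, c.astype(float), grid))
        assert densities[0] < densities[1] < densities[2]

    def test_downsampling_moves_along_the_curve(self, rng):
        """Halving the fragments of a G1 cell halves rho and moves the cell
        along the reference curve, not off it."""
        grid = sp.make_grid(400, n_chroms=4, seed=22)
        rhos, dens = [], []
        for i, r0 in enumerate(np.linspace(60, 260, 25)):
            spec = sp.SimSpec(n_bins=400, n_chroms=4, rho=float(r0), alpha=0.0,
                              n_cna_events=0, seed=50 + i)
            r = np.random.default_rng(50 + i)
            c = np.full(400, 2)
            frags = sp.simulate_fragments(c, spec, grid, r)
            prof = compute_overlap_density(frags, grid)
            rhos.append(r0)
            dens.append(cell_density_at_cn2(prof, c.astype(float), grid))
        model = fit_reference_model(np.array(rhos), np.array(dens))

        spec = sp.SimSpec(n_bins=400, n_chroms=4, rho=200.0, alpha=0.0,
                          n_cna_events=0, seed=99)
        r = np.random.default_rng(99)
        c = np.full(400, 2)
        frags = sp.simulate_fragments(c, spec, grid, r)
        keep = np.random.default_rng(100).random(len(frags)) < 0.5
        half = FragmentSet(frags.chrom[keep], frags.start[keep], frags.end[keep])
        prof = compute_overlap_density(half, grid)
        d_half = cell_density_at_cn2(prof, c.astype(float), grid)
        z = (d_half - model.predict(100.0)) / model.resid_sd
        assert abs(z) < 3.0
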