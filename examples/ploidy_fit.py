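"""Estimate absolute ploidy and reads-per-copy for simulated single cells.

Builds two cells with known ground truth -- one diploid, one tetraploid with
the same *relative* profile shape -- and runs the initial ploidy estimation
(segmentation, constrained grid-mixture fit, solution selection).
"""

import numpy as np

import scploidy as sp

grid = sp.make_grid(n_bins=3000, seed=1)

for background in (2, 4):
    spec = sp.SimSpec(n_bins=3000, background_ploidy=background, rho=100.0,
                      alpha=0.05, seed=background)
    rng = np.random.default_rng(background)
    cn_truth = sp.simulate_cn_profile(spec, grid, rng)
    cell = sp.simulate_counts(cn_truth, spec, grid, rng)

    solution = sp.fit_cell_ploidy(cell, grid)
    true_ploidy = cn_truth[grid.autosomal].mean()

    print(f"background {background}N:")
    print(f"  true ploidy {true_ploidy:.3f}  estimated {solution.ploidy:.3f}")
    print(f"  reads per copy per bin (rho): {solution.rho:.1f} (simulated 100.0)")
    print(f"  integer-grid RMSE {solution.rmse:.3f} over "
          f"{len(solution.candidates)} candidate solutions")

# The estimated rho is the spacing between neighbouring copy-number states in
# the count marginal; ploidy is the mean rounded copy number over autosomal
# bins.  The tetraploid cell is recognised from its odd copy-number states --
# without them the two cells would be indistinguishable (see wgd_detection.py).
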