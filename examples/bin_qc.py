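"""Reference-population bin quality control.

Bins where counts do not scale linearly with copy number (poor mappability,
extreme GC, collapsed repeats) are identified on diploid reference cells:
per-cell normalisation, per-bin median across cells, hard thresholds
(median > 4, < 0.10, mappability < 70), then smooth GC/mappability trend
residual and kernel-density filters, intersected across technologies.
"""

import numpy as np

import scploidy as sp

grid = sp.make_grid(n_bins=2000, seed=3)
spec = sp.SimSpec(n_bins=2000, rho=50.0, n_cna_events=0, gc_bias_amp=0.6,
                  map_bias_amp=0.4)

cells = []
for i in range(12):
    rng = np.random.default_rng(i)
    cn = np.full(2000, 2)
    cells.append(sp.simulate_counts(cn, spec, grid, rng, cell_id=f"ref{i:02d}"))

mask = sp.reference_qc_mask(cells, grid)
print(f"{int(mask.sum())}/{grid.n_bins} bins pass QC "
      f"({100 * (1 - mask.mean()):.1f}% removed)")

# apply the mask and it travels with the grid into every later analysis
grid.valid = grid.valid & mask
print(f"analysis grid now has {int(grid.valid.sum())} valid bins")
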