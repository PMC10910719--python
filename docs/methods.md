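# Methods

## Model

Per cell, read counts over M fixed-width genomic bins are modelled as
negative binomial,

    x_j ~ NB(mean = ρ · c_j · B_j · R_j,  overdispersion α),
    Var(x) = m + α m²,

with `c_j` the integer copy number of bin *j*, ρ the reads per copy per bin,
`B_j` a multiplicative GC/mappability bias and `R_j` a replication-status
inflation (1 for non-replicating DNA).  The quantity reported as ploidy is
`p = mean_j c_j` over valid autosomal bins — proportional to DNA content,
not chromosome count.  Everything the package infers (ρ, p, c, the WGD flag,
the S-phase call) is a function of this generative picture.

## Segmentation

Chromosomes are segmented independently by optimal partitioning with the
segment cost `C(y) = −Σ log NB(y_i | m̂, α̂)`, where `m̂` is the segment mean
and `α̂ = max(0, (s² − m̄)/m̄²)` the method-of-moments overdispersion (the
Poisson limit is used below α = 1e-8).  The optimiser is PELT with a
conservative pruning margin (30 cost units): the plug-in α̂ makes the cost
only approximately subadditive, and the margin keeps pruning exact in
practice — the test suite verifies equality with the exhaustive O(n²)
recursion to 1e-9 on instances up to n = 200.  The per-segment penalty is
`1.0 · log(n)` per chromosome, calibrated so a simulated diploid cell at
ρ = 100 incurs ≈0.5 spurious breakpoints per chromosome while ±1 events of
a few tens of bins on a tetraploid background remain detectable.  Minimum
segment length is 3 bins (the overdispersion estimate needs at least two
points).

Two deliberate additions sit behind the same contract:

* **Split repair.**  After PELT, every segment is recursively split at its
  best internal changepoint whenever that improves the NB cost by more than
  4.0 — far below the penalty.  Rationale: a missed weak boundary leaves a
  *mixed* segment whose level lies between copy-number states and corrupts
  the ploidy-grid evidence, whereas a spurious split of a homogeneous
  segment is harmless there.  The candidate split is located with a
  normal-approximation scan (O(n) with prefix sums) and validated with the
  exact NB cost.
* **Two segmentations per cell.**  The ploidy stage uses the low-penalty,
  repaired segmentation.  The replication trend test uses a conservative one
  (penalty scale 2.5, no repair): replication inflation is a sub-copy-step
  transient that must remain *inside* segments for the within-segment trend
  to be visible; the aggressive segmentation would chase the few-bin
  replication domains and erase the signal.

Each segment stores its mean, its MoM overdispersion and its level ν (the
median of raw counts, as used by the replication module).  For ploidy-scale
inference the median is corrected for the NB mean−median offset,
approximately `(1 + 2αm)/6`: without the correction, levels of different
copy-number states are not integer multiples of one spacing (the offset
grows with the state), which measurably bends the grid.

## Ploidy estimation

The marginal of segment levels (weighted by segment length) is fitted with a
constrained Dirichlet-process Gaussian mixture: component means pinned to
`μ_k = k·ξ` for k = 1..T (T = 16), free per-component σ_k, stick-breaking
weights.  The optimiser is a MAP EM — E-step responsibilities; M-step
updates ξ by precision-weighted regression of levels on component index, the
σ_k from weighted residuals clipped to [0.01 ξ, 0.5 ξ] (the floor prevents
collapse on noiseless data, the cap keeps neighbouring grid components
distinguishable), and the weights from their Beta posterior means — run from
10 log-spaced initial spacings over [min(ν)/8, max(ν)] plus a
median-gap-based initialisation.  Restarts are compared on the likelihood
*plus the stick-breaking ordering term* `Σ_k n_k log E[π_k | GEM(γ)]` with
γ = 1: a point-estimate EM otherwise loses the complexity cost of occupying
high-index components, and subdividing the grid (ξ → ξ/m) can win on
likelihood alone.  With the ordering term the best-scoring fit is the
*coarsest* grid consistent with the data, which is exactly what the divisor
enumeration needs.

Candidate solutions are the divisors ρ = ξ̂/m whose implied ploidy
`p(ρ) = mean_j round(ν_j/ρ)` lies in the ploidy window (default 1.1–8.0;
multiples ξ̂·m are available behind a flag).  Each candidate records the
bin-weighted RMSE of ν_j/ρ to the nearest integers.

**Selection.**  Selection starts at the lowest-ploidy candidate and climbs a
ladder: the grid is refined to the candidate at double (or triple) the
current ploidy only when the *phase vote* finds sufficient evidence, with
ties inherently resolved toward the lowest ploidy — the same preference the
window-based approach expresses.  The phase vote works on segments precise
enough to matter (level SE ≤ 0.10 of the current spacing, ≥ 10 bins): each
casts its phase `frac(level/ρ)`.  Genuine states of a half-spacing solution
sit at phase 1/2 (third-spacing at 1/3).  Three artifact classes are
excluded:

* noise-carved segments — adaptive segmentation places boundaries where the
  noise cooperates, so segment levels deviate from their state by a few SE;
  for eligible segments this cannot reach the half-phase band, which lies
  ≥ 4 SE away;
* mixtures of adjacent grid states — recognised, when the raw counts are at
  hand, by their internal structure: the two halves at the segment's best
  internal split sit at different grid states (> 0.5 ρ apart), whereas a
  genuine intermediate state is internally homogeneous;
* a single supporting segment must be phase-consistent with exactly 1/2
  within 1.5 of its own SE.

The first refinement requires ≥ 30 bins of supporting mass; each further
refinement requires 5× more, because a genuinely doubled solution places a
macroscopic fraction of the genome on the finer grid's odd states, while
mixture artifacts contribute tens of bins — and successive doublings are a
priori increasingly implausible (a truly doubled genome is resolved by the
read-density step, not by count evidence alone).  The third-phase band
competes directly with mixture phases and is additionally held to a control
band of arbitrary phases.  An advance is vetoed if it inflates the plain
RMSE by more than 1.4×: subdividing k-fold multiplies the pure-noise RMSE by
about k, and a genuine refinement is offset by the off-grid states it
resolves.  A plain min-RMSE rule with exact ties broken toward the lowest
ploidy is retained for bare candidate lists without segment information; it
is also what the reported per-candidate RMSEs express.

The design rationale: the plain bin-weighted RMSE has a scale artifact — its
noise floor is `Σ_l Var(level_l)/ρ²`, so halving the ploidy (doubling ρ)
quarters the noise floor, which on realistic data can outweigh the misfit of
several percent of odd-state genome.  The phase ladder replaces that global
contest with a targeted question (is there real mass *between* the current
grid's states?) whose failure modes are individually characterisable.  By
construction a doubled genome with *no* distinguishing states is assigned
the lower-ploidy solution — that unidentifiability is physical, and
resolving it is the read-density module's job.

After selection, ρ is polished at fixed integer assignment: weighted least
squares on the reads scale, then a local scan minimising the copy-scale
RMSE (whose optimum sits at slightly larger ρ than the reads-scale one).
Sex chromosomes are excluded from the ploidy average; their copy numbers are
still reported.  Re-fitting with a cell-specific window (e.g. centred on
twice the first-pass ploidy for a density-flagged cell) re-runs the same
steps.

## Read-overlap density

For deduplicated paired-end fragments, the number of *other* fragments
overlapping a fragment by ≥ 1 bp is counted by sorted search
(`#{start < end_i} − #{end ≤ start_i} − 1` per chromosome); fragments are
assigned to the bin containing their start, and the bin's density is the
mean overlap count of its fragments.  Because an amplification-free library
draws each fragment from one physical genome copy and same-copy fragments
cannot overlap, the expected overlap count at copy number c and genome
multiplicity g is proportional to `(gc − 1)/g` times the per-bin read rate:
at fixed fitted ρ a doubled cell (g = 2) shows ~1.5× the G1 density at
CN 2.  The per-cell summary is the prediction at CN = 2 of a Huber robust
regression of bin density on bin copy number, fitted per chromosome and
combined weighted by bin count; CN-uniform cells fall back to the median
density.  A least-squares quadratic of density versus ρ over known-G1
reference cells gives the expected value and a residual SD; cells whose
residual exceeds `z_cut` (default 3) SDs are flagged ELEVATED
(G2/WGD/multiplet candidates).  Classification requires ρ ≥ 75 (at 500 kb,
paired-end); the residual is reported regardless.  Single-end data are
refused.

## Replication status

A per-cell NB generalised additive model
`log μ_j = β₀ + β₁ ν_j + s(gc_j, map_j)` is fitted with a tensor-product
cubic B-spline surface (4 basis functions per margin) and a light ridge
penalty (0.01) on the smooth block — penalised regression splines; an
additive basis is the fallback.  The centered ŝ_j is the bias covariate.
Within each segment of the conservative segmentation (≥ 10 bins), the
partial Spearman correlation between counts and replication time given ŝ is
computed with midranks; cycling activity is the segment-length-weighted
(lower) median of these statistics.  The population threshold is
`median + 1.5 · SD_left`, where SD_left is the RMS deviation from the median
over the cells at or below it (the reflected left half).  For
classification the cutoff is recomputed once on the cells below the first
cutoff: with a large replicating fraction even the median is dragged into
the S tail, and one refinement restores it, while on a symmetric population
it moves the cutoff only ~10% (the unrefined rule is the default of
`dynamic_threshold` itself).  A conditional mutual information between
counts and replication time given copy-number state (plug-in entropies;
replication time in quartiles and counts in deciles within each state
holding ≥ 50 bins; states combined weighted by bin fraction) catches
individual outliers past the boxplot fence Q3 + 1.5 IQR.  A cell is called
S phase if either rule fires.  No training data enter anywhere.  The four
features used by supervised classifiers elsewhere (ρ, overdispersion,
activity, MI) are exposed by `cell_cycle_features`; training such a
classifier is out of scope.

## Synthetic data

The generator emulates the generative model above plus the physical
fragment-level structure:

* **Grid.**  22 chromosomes with human-like decreasing sizes; GC and
  mappability are smooth random fields (autocorrelation 20 bins — isochore
  scale), replication time a much rougher field (3 bins, matching the Mb
  scale of replication-timing domains; block-like inflation aligned with
  long replication-time runs would be absorbed by the segmentation and
  erase the trend the test statistic relies on).  Replication-time values
  follow the Repli-chip convention: larger = earlier.
* **Copy numbers.**  Background ploidy plus 20 sequential gain/loss events:
  40% arm-level (uniform 50–250 bins), the rest focal (geometric, mean 20
  bins); steps ±1 (80%) or ±2, clipped at zero, events free to nest and
  overlap as in clonal evolution.  These defaults produce heavily aberrant
  profiles with five or more distinct copy-number states in most cells —
  the regime the benchmarked tree-derived simulations occupy, and the
  stated condition of the recovery claims.  Purely-focal, low-aberration
  genomes carry less identifying information and show correspondingly more
  lowest-ploidy assignments.
* **Counts.**  `x_j ~ NB(ρ c_j B_j R_j, α)` via a shared per-bin gamma
  latent; for an S-phase cell at progression f, the earliest-replicating
  fraction f of bins is inflated by `s_inflation` (default 2 — fully
  replicated DNA).
* **Fragments.**  Each bin carries `c_j × multiplicity` physical copies;
  each copy receives Poisson-many fragments of fixed length at the per-copy
  rate (sharing the count latent, so fragment-start tallies *are* the
  cell's counts), placed uniformly without intra-copy overlap.  The
  copy-limit law — overlap depth never exceeding local physical copies —
  holds exactly.  ρ is defined per *nominal* copy, so a doubled cell has
  the same count profile as its G1 counterpart and differs only in fragment
  structure: the unidentifiability is reproduced by construction.
* Deterministic given a seed (per-cell streams spawned from one
  SeedSequence).

What passing tests on this generator do **not** show: robustness to
amplification artifacts, mappability structure beyond smooth fields,
sequencing-error or alignment effects, replication stochasticity beyond the
threshold model, or cell-to-cell contamination.  The procedure-level claims
(exactness of the optimiser, the distributional identities, the threshold
rules) are generator-independent.

## Problem sizes and numerics

The ploidy-recovery check uses 200 cells per background at ~5000 bins; the
density separation 50 cells plus 25 reference cells at 1000 bins with
ρ = 150; the replication classifier 100 + 100 cells at 1500 bins — sizes
chosen so the full suite re-runs in minutes on one core while keeping
Monte-Carlo error well inside the asserted margins.  Degenerate inputs are
handled explicitly: all-zero segments cost zero (point mass at zero),
all-zero cells raise, chromosomes shorter than the minimum segment length
become single segments, empty fragment sets give missing (not zero)
densities, and zero-variance trend inputs return a zero statistic with the
tie-handling of midranks.

## Known limitations

* G2 cells and recently-doubled G1 cells are indistinguishable by
  construction; the density step flags both, and telling them apart needs
  outside information (staining, population G1/G2 frequencies).
* The phase-vote ladder reaches ploidies at products of 2 and 3 of the
  starting candidate; a pentaploid cell whose mixture locks onto the
  whole-genome spacing would need the window or a refit to be reached.
* Ploidy states are clamped to the mixture truncation (T = 16) times the
  spacing; copy numbers above that follow the rounding rule only.
* The density model is trained per protocol; applying it across library
  preparations with different fragment-length distributions shifts the
  reference curve.
* At ρ below ~75 (500 kb bins) overlap evidence is too sparse for the WGD
  call, mirroring the stated applicability bound of the approach.
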