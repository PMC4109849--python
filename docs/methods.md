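# Methods

This note documents the statistical model behind `tagen`, the choices made
where the design was genuinely open, and what the synthetic-data generator
does and does not establish.

## The two-state expression model

A locus toggles between an active chromatin state (mean expression `mu_on`,
arbitrary fluorescence units) and a silent state (`mu_off < mu_on`) at rates
`k_on`, `k_off` per generation.  Single-time-point populations are sampled
from the stationary state distribution, active fraction
`p = k_on / (k_on + k_off)`, rather than by integrating a time course: for
the statistics implemented here only the stationary mixture matters, and
stationary sampling keeps the generator exact and fast.

Per-cell expression is `X = E * S * I + M`:

* `E` — extrinsic factor, lognormal with mean 1 and log-scale sd
  `sigma_extrinsic`; shared by all alleles of a cell.  Default 0.1–0.2,
  the 10–20% cell-to-cell global variation typical of size/machinery effects
  in budding yeast.
* `S` — the state mean (`mu_on` or `mu_off`).  Defaults 100 and 5 AU give the
  ~20-fold active/silent expression contrast typical of telomeric silencing;
  only the ratio matters for CV-type statistics.
* `I` — intrinsic factor per allele, lognormal with mean 1 and CV
  `cv_intrinsic`.  Lognormal (rather than gamma or normal) keeps intensities
  positive and matches the multiplicative noise seen in fluorescence data;
  the distribution family is a modelling choice, not a measured fact.
* `M` — additive measurement noise, Gaussian with sd `cv_measurement` times
  the population mean expression, truncated at zero (the clipped fraction is
  logged; for all default regimes it is negligible, so closed-form moments
  ignore truncation).

`lock_mode` freezes every cell in one state (`locked_on` / `locked_off`),
emulating growth under selection for constant expression or constant
silencing of a subtelomere-adjacent marker.  A pure two-state mixture cannot
be locked to *either* state while keeping the population mean unchanged; the
generator makes no attempt to preserve the mean under locking, and
state-conditional means remain independently configurable.  Whether real
loci compensate their mean under selection is left to the data.

Closed-form moments (`telegraph_moments`) for the two-allele mode, with
`v_e = exp(sigma_e^2) - 1`, `v_i = cv_i^2`, `s2 = E[S^2]/E[S]^2`:

    eta_ext2 = (1 + v_e) * s2 - 1
    eta_int2 = (1 + v_e) * s2 * v_i + cv_m^2
    CV^2     = eta_ext2 + eta_int2

State toggling enters the *extrinsic* component because both alleles share
the cell's chromatin state.  These formulas are the parameter-recovery oracle
for the decomposition tests.

## Colony, pedigree and replicate structure

Colonies and mother/daughter populations grow as synchronous binary division
trees; each daughter flips its epigenetic state with probability
`p_switch_per_division` (colonies/pedigrees use a symmetric flip; default
0.02 per division makes state memory persist over the ~10 divisions of an
overnight colony, the regime in which founder effects are visible; 0.5
destroys memory within one generation — the fast-switching analog of losing
the Sir2 deacetylase).  Cells are sampled evenly across the ordered leaves;
`region_id` partitions the leaf order into contiguous blocks as a proxy for
spatially distinct colony sectors.  This is deliberately not a spatial model:
no diffusion, no nutrient gradients, no cell-cycle asynchrony.

For RNA-Seq-like expression matrices each (gene, condition, replicate) value
is the mean expression of an independently grown 64-cell population
(tree-grown with per-division switch probabilities `k_on`, `k_off`), so the
replicate-to-replicate CV increases as switching slows — the property that
lets positional scans recover a configured rank–noise gradient.  Condition
effects are lognormal mean shifts (log-sd 0.25) shared by a condition's
replicates; they widen cross-condition spread without inflating
within-condition CV.  Defaults: 11 conditions, 2 replicates, 8 chromosome
arms with genes laid out round-robin (rank r appears once per arm).

## Statistics

* **CV** uses the n−1 sample standard deviation (the estimator denominator is
  a convention; it cancels in all ratio comparisons).  Non-positive means
  raise instead of emitting infinities.  Per-gene mean CV averages conditions
  with ≥2 non-missing replicates, unweighted; conditions are not imputed.
* **Robust CV** = `100 * 0.5 * (P84.13 - P15.87) / median` with percentiles by
  linear interpolation at `p*(n-1)` (numpy's default).  Computed on
  linear-scale intensities; whether vendor software log-amplifies first is
  instrument-specific, so the input scale is the caller's choice.
* **Gating** keeps events with FSC and SSC strictly > 0 ("measurable");
  thresholds are configurable.
* **Dual-reporter decomposition** scales each channel to unit mean first so
  unequal fluorophore brightness cannot masquerade as intrinsic noise.
  Negative extrinsic estimates are reported raw with a warning — clamping at
  zero would bias the paired intrinsic-vs-extrinsic t-test.
* **Resampling tests** all use the add-one empirical p,
  `(1 + #extreme) / (n + 1)`, which can never be 0.  Gene-set nulls draw sets
  without replacement within a set, independently across sets.  The pedigree
  statistic aggregates per-population means of per-cell ln intensity (the
  per-cell alternative is exposed via `intensity_column`/aggregation
  options); permutations are full random relabelings, identity allowed.
  Orientation is explicit: gene-set and CV-ratio tests are upper-tailed
  (more variable), the pedigree test lower-tailed (more similar).
  Ties between the observed statistic and null draws are recognised up to
  1e-12 relative round-off, since summation order differs between the two
  code paths.
* **Positional scan**: arms split at the centromere midpoint when supplied,
  else at half the chromosome length; distance to the telomere is measured
  from the gene edge nearest it (0-based half-open coordinates); rank ties
  break lexicographically by gene id.  The rank-k group is the first
  `group_size` genes ordered by (rank ≥ k, distance), pooling a rank across
  arms before dipping into the next rank.  Distance trends are offered
  against both the telomere- and centromere-anchored coordinate, since the
  two orientations answer slightly different questions.
* **Image quantification**: z-projection is a *sum* (lossless int64/float64
  accumulator), not max or mean.  Background is the pooled mean of the three
  background boxes (region-paired subtraction is available; the two coincide
  for flat backgrounds).  Negative signals are retained.

## The renderer and what a green test establishes

`render_nuclei_stack` draws nuclei as 2-D Gaussian spots (σ = 2.5 px) on a
grid, splits each spot's signal across 8 focal planes with a Gaussian axial
profile, and adds configurable uniform background, linear gradient, Gaussian
read noise and optional Poisson counting noise.  Each cell's ground-truth
`expected_signal` is defined as exactly what `nuclear_intensity` computes on
the noiseless projection, so zero-noise recovery is exact by construction and
recovery error under noise measures noise propagation only.  The renderer
does not emulate defocus blur across planes, chromatic effects, overlapping
cells, or segmentation error — a green recovery test validates the
measurement arithmetic, not a full microscopy pipeline.

Synthetic data generally: the generator reproduces the *statistical
structure* the analyses assume (shared extrinsic factors, state mixtures,
founder inheritance, rank-graded switching).  Green tests establish that the
estimators recover what the generator put in at the stated sample sizes; they
do not establish that real loci follow lognormal noise or synchronous binary
growth.

## Numerical and degenerate-input choices

* All generators are bit-deterministic given an integer seed; scenario runs
  derive named substreams from one master `SeedSequence`.
* Bootstrap/permutation loops are vectorised in chunks (~4·10⁷ doubles) so
  memory stays flat at any `n_boot`.
* Degenerate inputs raise typed errors (`InsufficientDataError`,
  `UndefinedStatisticError`, `DegenerateTestError`, ...) rather than emitting
  NaN/inf: zero-mean CV, zero-median Robust CV, zero-variance F-test
  denominators, empty gates, out-of-bounds boxes.
* A perfectly separated paired t-test (zero spread, non-zero mean difference)
  reports `t = ±inf, p = 0` explicitly instead of relying on the t
  distribution at a degenerate scale.

## Known limitations

* No burst-size kinetics: the telegraph mixture has no within-state transcript
  dynamics, so fast-switching regimes reduce noise only through state
  averaging.
* `ColonyModel` requires `cells_per_colony ≤ 2^generations` (sampling real
  leaves of the division tree).
* Flow input is CSV; FCS containers should be exported to CSV upstream.
* No multiple-testing correction across positional ranks or gene sets — the
  scans report per-rank empirical p-values as-is.
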