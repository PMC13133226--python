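# Methods

## The composite-sequencing model

A dataset is a set of measured sections; each section is an ordered grid of
levels (heights strictly increasing upward, i.e. toward younger strata) with
taxon occurrences at levels. A taxon observed in a section contributes two
local datums: its FAD at the lowest occupied level and its LAD at the
highest. The modelling premise is *containment*: observed local ranges may
be truncated, never inflated, so any global reconstruction is allowed to
extend a local range (FAD down, LAD up) but not contract it.

A candidate solution is a composite sequence: a permutation of all 2T events
(T taxa), index 0 oldest. Two hard rules define feasibility:

1. every taxon's FAD precedes its own LAD;
2. for every section and ordered taxon pair (A, B) observed in it with
   local FAD level of A ≤ local LAD level of B, FAD_A precedes LAD_B.

Rule 2 subsumes "observed coexistences must survive" and is chosen over a
literal coexistence-only reading because it guarantees, constructively, that
an extension-only monotone placement exists in every section (fuzz-tested
over 10⁴ random feasible composites). Every constraint runs from a FAD to a
LAD, so the constraint digraph is bipartite and always satisfiable: the
feasible set is never empty. Whether the original CONOP programs treat the
superpositional pairs as hard constraints or as penalties is not documented;
hard constraints were chosen because they shrink the search space and keep
the penalty a pure economy-of-fit measure.

### Penalty

The misfit of a composite against one section is the minimum of
Σ |placed − observed| · weight over placements of the section's events at
non-decreasing heights along the composite order, with FADs only moved down
and LADs only up. An optimal placement always exists on the section's own
level grid, so the minimum is found by dynamic programming over
(event, level) states with a running prefix-minimum; ties in the placement
witness break toward smaller heights, which never affects the value. Penalty
is measured in height units ("interval" style); sections enter with
multiplicative weights (the virtual marker section defaults to weight 10 —
the multiplier is not documented in the method's sources, so it is a
configurable default). Events of taxa not observed in a section contribute
nothing to that section (no implied-coexistence surcharge).

Incremental evaluation (`delta_penalty`) recomputes only the sections whose
*restricted* event order a move can change: for an adjacent swap, sections
containing both taxa; for a block move, sections containing the moved
event's taxon plus at least one taxon from the shifted block; for a window
reorder, sections with two or more taxa in the window. Exactness against
full recomputation is asserted for 1000 accepted moves in the test suite.

## The evolutionary search

The optimiser is a steady-state evolutionary algorithm with an annealing
acceptance rule:

* **Initialisation** — sections are ranked by shared faunal content (a
  section's score sums, over its taxa shared with other sections, the
  taxon's dataset-wide occurrence total; the per-pair alternative is
  configurable since the classical description is ambiguous). Composites are
  built by greedy insertion: the top-ranked section's taxa first, in
  observed level order, then the remaining taxa in a per-member shuffled
  order, each taxon's FAD and LAD inserted at the feasible positions that
  greedily minimise the penalty over the sections hosting that taxon.
  Insertion respects the constraint windows, so every member is feasible
  even when sections contradict one another (a literal copy of the top
  section's succession need not be). Duplicate members are nudged apart with
  zero-cost swaps. Populations can instead be seeded from prior composites
  (`init_from_sequences`), which is also how seed-parallel restarts merge —
  the package's single-process replacement for per-core population mapping.
* **Moves** — small mutation: swap one uniformly chosen adjacent pair; large
  mutation: move one event to another position, shifting the block between
  by one; recombination: order-based window crossover (a contiguous window
  of parent 1 is reordered to the relative order those events have in parent
  2 — literal segment substitution would not preserve the event multiset);
  memory replay: a FIFO buffer (1024 entries) of previously improving
  (move type, event pair) records is re-targeted at the current sequence,
  skipped when inapplicable. Infeasible offspring are rejected outright.
* **Acceptance and selection** — proposals are evaluated against a
  rank-biased parent (linear bias, best member twice the sampling weight of
  the worst). An offspring is accepted if better, or with probability
  exp(−Δ/T) when T > 0; at T = 0 only strict improvements pass. Temperature
  decays linearly from `start_temperature` to exactly zero across `steps`
  equal stages of `trials/steps` proposals — endpoints and stage count are
  standard for the method family; the linear shape is this package's choice.
  An accepted offspring replaces the worst member whenever it beats it;
  otherwise it continues its parent's annealing chain in place. This
  reconciles the two classical descriptions (a population composed of the
  best individuals; uphill acceptance to escape local optima): elitist
  replacement preserves the best sequences while each chain can still walk
  uphill at temperature.
* **Defaults** — population 24, start temperature 500, 700 steps, 40 000
  trials mirror the method family's published settings for large
  compilations; the test fixtures use smaller budgets (e.g. 8 members /
  12–15 k trials for 20-taxon worlds) because desk-scale instances converge
  orders of magnitude faster.
* **Baseline** — `compare_runs` pits the full EA against a pure-annealing
  baseline (population 2, no recombination, no memory) at equal trial
  budgets. The classical multi-core annealing baseline cannot be cloned
  exactly (its communication interval is unspecified), so pure annealing is
  the documented stand-in. At desk scale the EA's advantage appears when the
  temperature is high enough that an un-elitist chain wanders (the
  comparison fixture uses start temperature 30 on a 30-taxon, 35%-sampled
  world); near-converged instances show no difference.

Reproducibility: all randomness flows from one `numpy` generator per run;
identical seeds give bit-identical histories.

## Levels and age calibration

Adjacent events merge into one temporal level when swapping them is feasible
and changes the total penalty by exactly zero, closed transitively along
runs of such pairs (the alternative — one level per event — is a flag).
Levels are the unit of the imputed resolution, `span_myr × 1000 / n_levels`
Kyr per level.

Ages are fitted as a cubic smoothing spline of marker age against level
rank. The spline solve is the Green–Silverman natural-spline form: fitted
values f minimise Σ wᵢ(yᵢ − fᵢ)² + λ ∫ f″², computed densely as
(W + λK)⁻¹Wy — the same objective as `scipy.interpolate.make_smoothing_spline`
(agreement to ~1e-7 is a test), solved in-house because the hat diagonal is
needed for exact leave-one-out errors, which scipy does not expose.
Predictions between knots use the natural cubic interpolant; beyond the
first/last marker, extrapolation is linear from the boundary slope and
flagged in the output.

* **Smoothing selection** — λ is chosen by exact LOO cross-validation on a
  span-scaled grid (λ = ρ·(rank span)³, ρ log-spaced 10⁻⁸…10², from
  near-interpolation to the straight-line limit; an absolute grid cannot
  serve all span scales). Selection uses the one-standard-error rule
  (largest λ within one SE of the CV minimum): plain argmin is noisy at
  marker-set sizes and that noise measurably degrades bootstrap coverage.
  LOO rather than k-fold: the deterministic choice at small n.
* **Monotonicity** — fitted ages are projected to non-increasing-with-rank
  by isotonic regression; markers violating monotone order beyond tolerance
  are reported, not rejected.
* **Uncertainty** — markers are resampled with replacement; duplicates enter
  the refit as least-squares weights (collapsing them would silently turn
  the pairs bootstrap into subsetting), and each replicate re-runs the λ
  selection so the envelope carries smoothing-selection uncertainty.
  Degenerate draws (< 4 distinct levels) are redrawn and counted. The
  2.5th/97.5th percentile envelope is widened, when necessary, to bracket
  the point estimate; event ages are reported as midpoint ± half-width.
  Calibration of the envelope is itself tested: ~95% pointwise coverage
  (±3%) of a known linear age-rank law over 200 simulated marker sets
  (25 markers, σ = 0.1 Myr). Marker resampling — not taxon resampling — is
  the default uncertainty source throughout the downstream envelopes, since
  the confidence statements attach to the age model; taxon resampling can be
  layered on separately.
* **Small samples** — the model fits from 4 distinct marker levels upward
  (the dense solve needs 3 support points, so LOO at the minimum legal set
  still works; below 3, a least-squares line is the fallback).

Chron-boundary markers are carried as pseudo-taxa pinned to one level of the
weighted virtual marker section, so they occupy composite levels like any
datum and can anchor the spline.

## Diversity estimation

* **Unbinned richness** — richness at level k is the count of taxa whose
  composite range spans k, computed as a running sum (FADs at ≤ k minus LADs
  at < k) and cross-checked against direct counting. Genus richness
  collapses congeners to (earliest FAD, latest LAD); taxa without a genus
  are excluded from the genus series with a logged count.
* **Proportional rates** — per bin of width Δt (default 0.2 Myr):
  origination O/(D·Δt) and extinction E/(D·Δt) in per-lineage-per-Myr units,
  where D counts every taxon whose age range intersects the bin
  (range-through denominator; a boundary-crosser denominator is a config
  option since the classical phrase "proportional" fixes no formula).
  Turnover is their sum, net diversification their difference; D = 0 bins
  are emitted as missing. A taxon's age range runs from its FAD-level age to
  its LAD-level age inclusive; singletons occupy one bin.
* **Rarefaction** — occurrences pooled per analysis bin (default = the rate
  bin width; occurrence ages interpolate each occurrence's level between the
  taxon's composite FAD/LAD ages); n occurrences drawn without replacement,
  1000 iterations, mean and 2.5/97.5 percentiles; n larger than the pool is
  a missing value with a warning. The Monte-Carlo mean is tested against the
  exact hypergeometric expectation E[Sₙ] = Σᵢ (1 − C(N−Nᵢ, n)/C(N, n)).
* **Envelopes** — richness is a fixed step function of levels, so age-model
  bootstrap replicates simply re-date it; rate envelopes refit the binning
  per replicate and align bins by midpoint interpolation.

## Association with proxies

Series are linearly interpolated onto a shared 0.2-Myr grid over their age
overlap (matching the rate bin; the classical correlation grid is
unstated). Spearman's ρ uses mid-ranks for ties, a two-tailed t-approximate
p (floored at 2.2 × 10⁻³⁰⁸ and flagged rather than printed as zero), and a
percentile bootstrap CI from resampling index pairs i.i.d. (10 000
iterations by default; a block bootstrap for autocorrelated series is
available but off by default, matching the plain-percentile description of
the published intervals). CI calibration is tested at ~95% ± 3% coverage on
bivariate normal draws at n = 140. Linear detrending removes the
least-squares line against age; VIF screening regresses each proxy on the
rest and flags VIF = 1/(1−R²) > 10, with perfect collinearity reported as
infinite.

## The synthetic world

The generator emulates the structure the method assumes, with every truth
retained for closed-loop scoring:

* true ranges: origination ages uniform over the study span (the
  constant-rate process conditioned on n), durations exponential with mean
  1/ext_rate Myr, clipped at the young edge (defaults: 48–20 Ma span,
  ext_rate 0.25 /Myr, i.e. 4-Myr mean lifetime);
* sections: random time windows (length uniform between 35% and 100% of the
  span), a fixed number of stratified-uniform level ages per window, and
  Bernoulli(p) preservation per extant (taxon, level) — so local ranges are
  contained in true ranges by construction and section-internal order always
  honours true age order; heights are Myr below the window top;
* markers: the k most-occurring taxa carry their true FAD/LAD ages,
  mimicking index-species selection;
* proxy: coupling × min-max-normalised true richness + stationary AR(1)
  noise on a regular age grid.

What it does *not* emulate: facies control, geographic endemism, taphonomic
gradients, age-model error in the markers themselves, or reworking. Passing
recovery tests therefore demonstrate correctness of the inference machinery
under honest incomplete sampling, not robustness to violated assumptions.

One structural fact the generator exposed: even with 100% per-level sampling,
the *true* event order carries positive penalty, because discrete level
grids truncate local ranges inward and the truncation differs between
sections. "Zero-conflict" test datasets are therefore constructed directly
(sections sharing one global succession), not sampled.

## Problem sizes and test design

Test fixtures are sized for interactive runs: the standard recovery fixture
is 20 taxa × 8 sections at 50% sampling (12 000 trials recovers the true
event order at rank correlation ≥ 0.9); the search-comparison fixture is 30
taxa × 10 sections at 35% sampling over 10 seeds; the end-to-end world is 20
taxa × 12 sections at 95% sampling with 6 marker taxa, where the recovered
richness curve tracks truth within one species of mean absolute error.
Statistical calibration suites use 500 correlation simulations and 200
age-model simulations with 250-replicate bootstraps. All fixture parameters
were fixed from pilot runs before the corresponding assertions were frozen.

## Known limitations

* The penalty considers range extension only — no teaser/negative-evidence
  terms and none of the alternative CONOP objectives (eventive, spatial).
* Greedy insertion during initialisation is order-dependent; it seeds the
  search, it does not claim optimality.
* Bootstrap envelopes inherit percentile-bootstrap small-sample behaviour:
  with very few markers (< ~10 distinct levels) coverage runs below nominal.
* The composite cannot see taxa absent from every section; closed-loop
  richness error therefore grows with the fraction of never-sampled taxa.
* Rarefaction dates occurrences by within-range interpolation, a crude
  monotone dating adequate for pooling but not for event-level inference.
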