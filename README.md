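# stratseq

Composite sequencing of stratigraphic events, with downstream chronology and
palaeodiversity estimation.

## The problem

Fossil occurrences are recorded section by section: each measured section
gives, for every taxon observed in it, a local first appearance datum (FAD)
at its lowest occupied level and a local last appearance datum (LAD) at its
highest. Local ranges are truncated by incomplete sampling and by the time
window each section happens to capture — but they can never be *longer* than
the taxon's true range. Constrained-optimization correlation (the CONOP
family of methods) exploits this asymmetry: it searches for a single total
ordering of all taxa's FAD and LAD events — a *composite sequence* — that can
be reconciled with every section by only *extending* observed ranges (moving
FADs down-section, LADs up-section), and scores a candidate ordering by the
minimum total extension it forces, summed over sections:

```
penalty(s) = Σ_sections  w_sec · min Σ_events |placed − observed|
             subject to: placements non-decreasing along s,
                         FAD placed ≤ observed, LAD placed ≥ observed
```

The inner minimum is solved exactly by dynamic programming over each
section's level grid. Two hard constraints restrict the search space: a
taxon's LAD must come after its own FAD, and observed coexistences must
survive (implemented as the superpositional rule: FAD_A precedes LAD_B
whenever section data show A appearing at or below B's top).

`stratseq` searches this permutation space with an evolutionary algorithm: a
population of feasible composites evolves by constrained mutation (adjacent
swaps and block moves), order-based recombination between parents, replay of
previously improving moves, and steady-state selection, under a simulated
annealing acceptance rule whose temperature decays linearly to zero. Every
trial is scored incrementally — only sections whose restricted event order a
move can change are re-evaluated — which is what makes large searches
affordable.

The optimised composite is then turned into a chronology and diversity
history:

* **Levels** — adjacent events whose swap is free (feasible, zero penalty
  change) merge into discrete temporal levels; the imputed resolution is
  `span / n_levels`.
* **Ages** — a cubic smoothing spline maps level rank to age (Ma) through
  marker datums (index-species events, magnetochron boundaries), with
  leave-one-out cross-validated smoothing, isotonic projection to monotone
  ages, and a marker-resampling bootstrap envelope.
* **Diversity** — unbinned standing richness per level (species and genus),
  proportional origination/extinction/turnover/net rates per 0.2-Myr bin
  (events per lineage-Myr), individual-based rarefaction, and bootstrap
  envelopes propagated from the age model.
* **Association** — Spearman rank correlation between richness and
  environmental proxy series on a common age grid, with percentile bootstrap
  CIs, optional linear detrending, and VIF screening for collinear proxies.

A synthetic-world generator (`stratseq.synthesize`) produces taxa with known
true ranges, sections with honest incomplete sampling, true-age markers and a
richness-coupled proxy, giving every stage a closed-loop test target.

## Worked example

```python
import stratseq as ss
from stratseq import calibrate as C, diversity as D

world = ss.simulate_world(n_taxa=20, ext_rate=0.12, n_sections=12,
                          levels_per_section=25, sampling_prob=0.95,
                          n_markers=6, seed=5)
ds = ss.workbench.marker_virtual_section(world.markers, world.dataset, weight=10.0)
problem = ss.compile_problem(ds)

cfg = ss.EAConfig(population_size=8, start_temperature=5.0,
                  steps=60, trials=15000, seed=5)
best, history = ss.evolve_run(problem, cfg)
levels = C.cluster_levels(best, problem)
model = C.bootstrap_age_model(levels, world.markers, problem, n_boot=200, seed=5)
rich = D.unbinned_richness(levels, problem, age_model=model)

print(f"final penalty     {best.cached_penalty:.2f}")
print(f"temporal levels   {len(levels)}")
print(f"resolution (Kyr)  {ss.imputed_resolution(model.span_myr, len(levels)):.1f}")
```

prints

```
final penalty     16.26
temporal levels   28
resolution (Kyr)  994.2
```

i.e. the search reconciled all twelve sections at a total range extension of
16.26 height units, the composite's 32 events collapse into 28 temporal
levels, and those levels span the calibrated interval at roughly 0.99 Myr per
level (desk-scale worlds resolve far fewer levels than a global compilation
would). Comparing `rich["richness"]` against `world.true_richness(...)` at
the same ages gives a mean absolute error of 0.57 species.

The same pipeline is scriptable from the shell:

```bash
stratseq simulate --n-taxa 20 --seed 5 --out-dir demo
stratseq optimize --sections demo/sections.csv --out composite.csv
stratseq calibrate --sections demo/sections.csv --composite composite.csv \
                   --markers demo/markers.csv
```

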