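# clonalarch

Clonal architecture analysis for grid-sampled microsatellite genotypes of
clonal plants: clone discrimination, clonal diversity indices, spatial genet
structure, group statistics, and a spatially explicit clonal-population
simulator with known ground truth.

The pipeline mirrors the standard workflow for field surveys in which ramets
(stems) are sampled one-per-grid-cell-per-life-stage inside quadrats and
genotyped at codominant microsatellite loci:

1. **`clonalarch.io`** — data model and flat-CSV interchange format
   (`sample_id, quadrat_id, row, col, stage, <locus>_1, <locus>_2, …`, one
   row per ramet, missing genotypes encoded as `0`), quadrat layouts in a
   YAML/JSON sidecar, strict missing-data dropping.
2. **`clonalarch.clones`** — multilocus genotypes (MLGs) by exact match;
   genotype accumulation curves; round-robin allele frequencies; P_gen
   (Parks & Werth, product of genotype frequencies × 2^h) and P_sex
   (binomial upper tail); allele-mismatch distances with optimal within-locus
   pairing; data-driven distance cutoff (largest gap among the first
   candidate distances); agglomerative clustering of MLGs into multilocus
   lineages (MLLs = genets) under farthest- or nearest-neighbour linkage.
3. **`clonalarch.diversity`** — per-quadrat census, clonal richness
   R = (G−1)/(N−1), Simpson index with range-standardised evenness V, Pareto
   index β (negative log-log slope of the reverse cumulative clone-size
   distribution, ≥3 distinct sizes required), clonal-ramet percentage, and
   mean ± sample-SD group summaries.
4. **`clonalarch.spatial`** — genet convex hulls (cell-centre positions) and
   areas, hull-overlap counts with leave-one-genet-out jackknife 95% CIs,
   clonal identity as a function of pair distance, stem density from random
   1 m² sub-quadrat counts.
5. **`clonalarch.stats`** — rank-sum test (exact for small tie-free samples),
   Fisher's exact test with odds ratio and Woolf CI, Tukey HSD all-pairs
   comparison with compact letter display.
6. **`clonalarch.simulate`** — founders with Hardy–Weinberg genotypes from
   Dirichlet population frequencies, branching stolon random walks,
   stepwise somatic mutation and genotyping-error noise, and the
   one-ramet-per-cell-per-stage sampling protocol.  Presets `young`
   (2–5 founders, ~10 stems/m², large clones) and `old_growth`
   (14–30 founders, ~145 stems/m², intermingled clones).
7. **`clonalarch.pipeline` / `clonalarch.cli`** — end-to-end orchestration
   with CSV/JSON outputs and a hashed run manifest.

## CLI

```bash
# simulate a quadrat and keep the ground truth
clonalarch simulate --preset young --seed 42 --out sim.csv --truth sim_truth.json

# clone discrimination (MLG -> genet assignments)
clonalarch clones --input sim.csv --linkage farthest --clonal-fraction 0.5 --out clones.csv

# diversity indices / spatial architecture
clonalarch diversity --input sim.csv --out diversity.csv
clonalarch spatial --input sim.csv --bin-width 1.0 --out geometry.csv

# full pipeline with report bundle + manifest
clonalarch all --input sim.csv --out-dir results/ --layout-config layouts.yaml

# recompute the bundled reference-survey arithmetic (exit 1 on mismatch)
clonalarch check-tables
```

## Tests

```bash
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria: exact arithmetic
reproduction of the bundled reference tables, Pareto-fit behaviour, oracle
equivalence (rasterised overlap counting, exhaustive test enumeration,
Monte-Carlo tail probabilities), and seeded parameter-recovery runs on the
simulator.  One integration test is skipped unless `CLONALARCH_FIELD_DATA`
points to a real field genotype CSV.

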