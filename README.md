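# gsbreed

Genomic selection (GS) versus phenotypic selection (PS) for mass selection of
allogamous crops, end to end in silico:

- **`gsbreed.simulate`** — forward-in-time simulator of a self-incompatible
  diploid population: genetic map, phased haplotypes, Haldane recombination,
  random mating with pedigree, bottlenecks, a pleiotropic multi-trait
  architecture with a target genetic-correlation matrix, and marker
  observation (codominant dosage or dominant presence/absence, optional
  missingness).
- **`gsbreed.index`** — selection-index construction by principal component
  regression (component count by leave-one-out RMSE), index evaluation, and a
  Mantel permutation test for correlation-matrix similarity.
- **`gsbreed.gblup`** — per-trait G-BLUP (REML via spectral decomposition)
  with an equivalent ridge/marker-effect representation, expected/predicted
  selection indices, LOOCV accuracy, and frozen-model accuracy decay.
- **`gsbreed.scheme`** — the breeding programs: GS with two cycles per year
  (cycle 1: genotype + phenotype + train + select *after* pollination;
  cycle 2: genotype only + select *before* pollination, mating among the
  selected), PS once per year (female-side selection on the observed index),
  annual model updating, marker-panel attrition, and a mortality contingency.
- **`gsbreed.ld`** — pairwise r² including two-locus EM for dominant
  markers, LD-decay summaries, and LD-based effective population size from a
  drift-expectation curve.
- **`gsbreed.evaluation`** — population summaries, Welch's t-tests with
  Bonferroni correction, percent gains, gain trajectories, compact letter
  displays.
- **`gsbreed.presets`** — the published reference inputs (selection-index
  coefficients, trait correlation matrices, 2014 evaluation summaries,
  marker counts) so everything runs offline.

Default sizes mirror the experimental scheme: 192 plants in cycle 1, 48 in
cycle 2, 12 selected, a 40-plant bottleneck to create the initial population.
Per-trait heritabilities default to 0.5 (an assumption — the source
experiment does not report them) and the dominant-marker fraction defaults to
0.5; both are configurable.

## CLI

```sh
gsbreed simulate --seed 1 --out runs/inputs          # synthetic map/genotypes/phenotypes
gsbreed run --seed 1 --scheme both --years 3 --out runs/full
gsbreed analyze --run-dir runs/full                  # summaries, accuracy, LD/Ne reports
gsbreed report --run-dir runs/full
```

Configuration is YAML (see `gsbreed.cli.DEFAULT_CONFIG` for the fields);
every run writes a JSON manifest with the config snapshot, master seed and
file checksums. Tables are plain CSV with `NA` for missing values.

## Notes on conventions

- LOOCV accuracy holds the variance ratio and the intercept at their
  full-data estimates by default (`mean_policy="full"`); refitting the
  intercept per fold (`mean_policy="per_fold"`) biases null accuracies
  toward −1. Fast closed-form paths match the literal refit paths to
  machine precision in both modes.
- PCR predictors are mean-centered but not scaled by default (`scale=True`
  switches), matching the magnitude pattern of the published coefficients.
- The Hill–Weir drift expectation (with finite-sample term) is the default
  expected-r² curve; a simpler `1/(2+C) + 1/n` variant is selectable.
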