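# ecomethyl

A tested, reusable pipeline for two-ecotype seed methylome comparison on
synthetic data. It covers:

- **`simulate`** — a complete synthetic two-ecotype (Col/Cvi), three-stage
  (FH/AR/GS) dataset: per-cytosine CX-dialect reports, gene/TE annotations
  (GFF3 + BED), SNP/SV/HOT tracks, 24-nt small-RNA cluster intervals with a
  replicated count matrix, and a machine-readable truth table of every
  planted effect (eDMR windows, Cvi coverage-dropout loci, cluster classes).
- **`windows`** — fractional methylation over non-overlapping fixed windows
  (default 50 bp, ≥3 sites with ≥10 reads per context) and over annotated
  features (≥5 sites), plus a 5-kb chromosomal-view variant (≥10 sites).
  Site fractions are averaged unweighted; low-depth sites are excluded.
- **`partition`** — classify every window into common region (CR: valid in
  all six samples), Col-specific (COL_SR: valid only in Col), CVI_SR,
  MIXED, or NONE; merge labelled windows (`-d 1` semantics) and combine
  per-context region sets at base-pair level (union / intersection).
- **`edmr`** — per-stage Col−Cvi deltas over CR windows, eDMR calling by the
  strict mean ± k·SD rule (population SD, per context and stage),
  stage-consistent ("maintained") eDMRs, Gene / Gene&TE / TE / IGR feature
  breakdown, and gene-body methylation sectioning.
- **`srna-classify`** — RPM length/5′-nt profiles, CPM/CP10M normalization,
  a two-group negative-binomial exact test (median-of-ratios size factors,
  tagwise-moderated dispersions, BH correction) as a documented stand-in
  for a GLM workflow, and e24sRC classification (FDR < 0.05, |FC| ≥ 2 in
  all three stages, direction-consistent).
- **`permtest`** — regioneR-style randomization test: lengths preserved,
  per-chromosome, non-overlapping placements, count-once overlaps, inputs
  merged (`-d 1`), empirical p = (1 + k)/(n_perm + 1).
- **`variant-summary`** — SNP-per-window accounting, methylation by
  SNP-count strata, substitution-type z-scores ((x − m)/σ per region
  class), SV-category methylation summaries, and HOT-region coverage.

Coordinates are 0-based half-open internally and in BED outputs; CX reports
and SNP tables use 1-based positions.

## CLI

Run the whole pipeline from one config:

```sh
ecomethyl run --config config.yaml --outdir out/
```

A minimal config needs only a seed (everything else has desk-scale
defaults — a 2 × 500 kb genome with central pericentromeres):

```yaml
seed: 1
simulation:
  edmr_delta: 0.4
  cluster_fold_change: 8
permutation:
  n_perm: 1000
```

The run writes the synthetic dataset under `out/data/`, one artifact set
per stage (window tables, region labels and merged BEDs, eDMR calls and
thresholds, e24sRC classes, permutation JSON, variant summaries), and a
`manifest.json` recording seed, config hash and every output path. Each
stage is also exposed as a subcommand (`ecomethyl simulate`, `windows`,
`partition`, `edmr`, `srna-classify`, `permtest`, `variant-summary`); see
`ecomethyl COMMAND --help`.

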