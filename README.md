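# coreniche

Core-microbiome inference for amplicon (ASV-level) count tables:

- **Occupancy/consistency ranking** of taxa under a pooled occupancy model
  or a site-specific one (per province, gender, or any categorical
  covariate), combining per-group detection proportions with replicate
  consistency.
- **Bray-Curtis contribution curves** measuring the share of
  beta-diversity structure explained by each ranked prefix, with two
  stopping rules for picking the core set: a last->=2%-relative-gain rule
  and an elbow rule on segment slopes.
- **Sloan neutral community model** fitting (migration rate by least
  squares on the abundance-occupancy cloud) and partitioning of taxa into
  host-selected (above the envelope), neutral, and dispersal-limited
  (below) classes.
- **Supporting statistics**: Shannon entropy, rarefied richness
  (hypergeometric expectation), Bray-Curtis distance matrices, PCoA,
  single-factor PERMANOVA with seeded permutations, chi-square independence
  tests with Pearson-residual attraction maps, and Poisson log-linear
  incidence-rate ratios for questionnaire covariates.
- **Pre-processing**: lineage-based exclusion (e.g. Mitochondria,
  Chloroplast, fully unassigned ASVs), prevalence-based contaminant
  identification from negative controls (one-sided hypergeometric test),
  and a low-yield sample filter (< 2000 reads by default; a sample at
  exactly the threshold is retained).
- **Synthetic data generator** producing multi-site (province x gender)
  communities from a log-normal metacommunity via the stationary Sloan law,
  with planted host-selected, dispersal-limited, patchy-generalist and
  contaminant taxa plus questionnaire metadata with a planted
  health-status association — every pipeline stage is testable against
  known ground truth without external data.

## CLI

```sh
# generate a synthetic dataset with ground truth
coreniche simulate --seed 1 --out-dir fixtures/

# filtering: lineage exclusions, contaminants from negative controls, depth
coreniche filter --table table.tsv --metadata meta.tsv --taxonomy tax.tsv \
    --min-reads 2000 --exclude Family=Mitochondria --exclude Order=Chloroplast \
    --drop-unassigned --out filtered.tsv

# occupancy ranking + core selection (pooled or site-specific)
coreniche core --table filtered.tsv --metadata meta.tsv \
    --occupancy-by province_of_residence --criterion last2pct --out core.tsv

# neutral-model fit and partition
coreniche neutral --table filtered.tsv --out neutral.tsv --summary fit.json

# alpha diversity + per-covariate PERMANOVA
coreniche diversity --table filtered.tsv --metadata meta.tsv \
    --covariates gender,province_of_residence --permutations 999 --seed 42 \
    --out diversity

# full pipeline from one YAML config (see PipelineConfig fields)
coreniche run --config pipeline.yaml
```

Tables are TSV (samples as rows) or BIOM 2.x HDF5 (`.biom` extension);
metadata is TSV with a header row and one sample per line; taxonomy is TSV
with `taxon_id` plus a semicolon-delimited lineage (SILVA-style `p__`
prefixes tolerated).

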