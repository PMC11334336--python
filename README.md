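# trophograd

Gradient analysis of microbial communities and putative trophic
associations: from multi-kingdom ASV count tables and site covariates to
random-matrix-thresholded bipartite predator-prey networks, per-site
association metrics, normalized stochasticity ratios (NST),
moving-window hierarchical variance partitioning, Procrustes ordination
congruence, and AIC-selected gradient trend models.  A synthetic-data
module generates survey-like and microcosm-like datasets with planted
gradients and planted predator-prey links so the whole pipeline is
testable end to end without external downloads.

## Layout

| Module | Role |
| --- | --- |
| `trophograd.core_data` | `AsvTable` / `SiteMetadata` / `DistanceMatrix` types, TSV I/O, rarefaction, prevalence filtering, relative abundance |
| `trophograd.synthetic_data` | survey and microcosm generators with planted richness shapes, covariate gradients and trophic links |
| `trophograd.diversity` | Bray-Curtis/Jaccard distances (optional Hellinger), NMDS, ANOSIM, Mantel, haversine distances, distance-decay regressions |
| `trophograd.trophic_networks` | Spearman correlation blocks, random-matrix (NNSD) threshold scan, binary bipartite meta-networks, per-site subnetwork metrics (E, N, C = E/N²) |
| `trophograd.assembly_stochasticity` | occupancy-proportional richness-preserving null model and NST on Jaccard distances; determinism = 1 − NST |
| `trophograd.gradient_partitioning` | VIF pruning, dbRDA with permutation tests, all-subsets hierarchical partitioning, 3-way variation partitioning, moving-window scan |
| `trophograd.congruence` | symmetric Procrustes, PROTEST permutation test, residual-versus-gradient trends |
| `trophograd.trend_models` | linear-vs-quadratic AIC-selected trend fits, standardized best-subset OLS |
| `trophograd.pipeline` / `trophograd.cli` | end-to-end survey and microcosm orchestration, `trophograd` console script |

## CLI

```bash
# synthetic survey dataset (TSV tables + metadata + true-link registry)
trophograd simulate --seed 1 --outdir data/survey

# full survey pipeline on the default synthetic dataset
trophograd run-survey --seed 1 --outdir runs/survey

# microcosm arm (5 temperature levels x 8 replicates)
trophograd run-microcosm --seed 1 --arm temperature --outdir runs/microcosm

# individual stages
trophograd network --prey data/survey/asv_bacteria.tsv \
    --predator data/survey/asv_protist.tsv --outdir runs/net
trophograd nst --table data/survey/asv_bacteria.tsv --out runs/nst.tsv
trophograd procrustes --table-a data/survey/asv_bacteria.tsv \
    --table-b data/survey/asv_protist.tsv --out runs/procrustes.json
```

Every subcommand takes `--seed`; all stochastic stages derive
deterministic child seeds from it, so reruns are byte-identical.
Pipeline and simulation settings can also be provided as YAML via
`--config` (the schema mirrors `PipelineConfig` / `SimulationConfig`).

## Conventions worth knowing

- Count tables are samples x ASVs; `--transpose` accepts the transposed
  dialect.  Rarefaction is without replacement
  (multivariate-hypergeometric), and samples under the requested depth
  are dropped with a warning.
- The prevalence filter keeps ASVs detected in strictly more than the
  threshold fraction of samples.
- Network edges use |rho| >= threshold by default (both signs);
  `--positive-only` restricts to positive associations.  Connectance is
  E/N² with isolated nodes excluded from N.
- The NST definition is fixed and documented in
  `trophograd.assembly_stochasticity`; bit-compatibility with any
  external package is not claimed.
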