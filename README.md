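# grassdiv

Taxonomic, phylogenetic and functional diversity of semi-natural grassland
plant communities under contrasting land use — three grazing pressures
(intensive, intermediate, extensive) and two ages of abandonment (recent,
< 10 y; past, > 10 y). The package implements the complete analysis chain
used in community-ecology surveys of this kind, plus a synthetic-community
generator so every stage can be exercised and validated without field data.

## Who it is for

Plant and community ecologists comparing diversity components across
management categories from three standard inputs: a plot × species
abundance matrix, a species × trait table, and a dated phylogeny that may
be missing some of the surveyed species (but contains congeners).

## What it computes

For each plot with relative abundances $p_i$:

- **Taxonomic diversity** — Gini–Simpson index $D = 1 - \sum_i p_i^2$.
- **Phylogenetic (raoD) and functional (raoQ) diversity** — Rao's
  quadratic entropy $Q = \sum_i \sum_j p_i p_j d_{ij}$, with $d_{ij}$ the
  time since the most recent common ancestor (patristic distance / 2) for
  raoD, and the Gower dissimilarity of log-transformed traits (SLA, LDMC,
  LNC, LA, SM, PH) for raoQ.
- **Community-weighted means** — $\mathrm{CWM}_t = \sum_i p_i x_{it}$ per
  trait.
- **Tree completion** — species missing from the phylogeny are grafted at
  random positions within their genus clade; the procedure is repeated to
  yield a set of alternative topologies over which raoD and its null model
  are averaged.
- **Standardized effect sizes** — permutation null models (tip shuffling
  for raoD; joint trait-row permutation for raoQ and CWMs) give
  $\mathrm{SES} = (\mathrm{obs} - \bar{Q}_{\mathrm{null}})/\mathrm{SD}_{\mathrm{null}}$:
  negative values indicate convergence (habitat filtering), positive
  values divergence (limiting similarity).
- **Phylogenetic signal** — Blomberg's
  $K = (\mathrm{MSE}_0/\mathrm{MSE}) \,/\, E_{BM}[\mathrm{MSE}_0/\mathrm{MSE}]$
  with a tip-permutation test; $K \approx 1$ under Brownian motion,
  $K \approx 0$ without signal.
- **Dimensionality of biodiversity** — per category, a PCA on the
  correlation matrix of (D, raoD, raoQ) yields the evenness of eigenvalues
  (EE, Camargo's index: high = complementary metrics), per-metric
  importance values $IV_m \propto \sum_k (\lambda_k/\sum\lambda)\, r_{mk}^2$
  (normalized to sum to 1), and the Camargo evenness of the IVs with a
  plot-bootstrap 95% CI.
- **Group comparisons** — Kruskal–Wallis across categories with pairwise
  Wilcoxon rank-sum post hoc tests (Holm-adjusted) and a compact letter
  display, plus one-sample *t*-tests of SES against zero.

## Worked example

Simulate a small study (60-species pool, 5 categories × 6 plots, the
default assembly regimes: filtering of decreasing strength in grazed
categories, neutral at recent abandonment) and run the chain:

```sh
grassdiv simulate --seed 7 --n-species 60 --n-plots-per-category 6 --out demo
grassdiv run --community demo/community.csv --traits demo/traits.csv \
    --tree demo/tree.nwk --design demo/design.csv --out demo_out \
    --n-topologies 5 --n-rand 199 --n-boot 99 --seed 7
```

`demo_out/ses_summary.csv` then contains (excerpt):

```
          category   metric  n  mean_ses      t     p
         intensive raoQ_ses  6    -1.921 -8.430 0.000
      intermediate raoQ_ses  6    -1.389 -3.722 0.014
         extensive raoQ_ses  6    -0.463 -1.135 0.308
recent_abandonment raoQ_ses  6     0.241  0.858 0.430
  past_abandonment raoQ_ses  6    -1.312 -3.487 0.018
```

The functional SES recovers the simulated regimes: strongly negative
(trait convergence) under intensive grazing, fading to non-significant
under extensive grazing, and near zero under neutral recent abandonment.
`demo_out/dimensionality.csv` reports per-category EE, IVs and IV
evenness with bootstrap CIs, e.g. intensive grazing: EE = 0.700,
IV = (0.361, 0.328, 0.312) for (D, raoD, raoQ), IV evenness = 0.967
(95% CI 0.877–0.984).

The same chain runs on real data by pointing `grassdiv run` at your own
four files (`--log-traits` if the trait table holds raw values).

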