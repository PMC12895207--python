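# Methods

This note records the statistical model behind each stage of the
analysis chain, the defaults and why they were chosen, what the
synthetic-data generator does and does not emulate, and the numerical
conventions adopted where more than one was defensible.

## Data model and assumptions

All metrics treat a plot as a multinomial community: relative abundances
`p_i` are cover values normalized within the plot. Intraspecific trait
variability is ignored (within-species dissimilarity is zero), the
standard comparative-ecology assumption that between-species differences
dominate. Traits are analysed on the natural-log scale with conventional
units (SLA mm²/mg, LDMC mg/g, LNC mg/g, LA mm², SM mg, PH cm); the
natural log makes back-transformed community-weighted means land on
biologically plausible raw values (e.g. a log-LDMC CWM of 5.7 ≈ 300 mg/g,
log-PH 3.2 ≈ 25 cm).

## Diversity metrics

- **Simpson diversity** is the Gini–Simpson form `D = 1 − Σp²`
  (probability two random individuals differ in species). The
  inverse-Simpson form is available (`variant="inverse"`) but Gini–Simpson
  is the default: it is the common "simpson" of ecological software and
  yields values in the 0.7–0.9 range typical of species-rich grassland
  relevés.
- **Rao quadratic entropy** `Q = Σᵢⱼ pᵢ pⱼ dᵢⱼ` is used for both the
  phylogenetic and the functional axis. With the 0/1 species-identity
  "distance" it reduces exactly to Gini–Simpson — this identity is a
  standing cross-check in the test suite.
- **Phylogenetic divergence** defaults to half the patristic distance,
  i.e. the time since the most recent common ancestor on an ultrametric
  tree. On a ~100-Myr-deep phylogeny this puts raoD on the familiar
  ~70–100 "mean divergence time" scale. The raw-patristic convention is
  one configuration switch away (`convention="patristic"`), since
  published implementations differ silently on this factor of two.
- **Functional distance** defaults to the Gower dissimilarity of the log
  traits (per-trait range-normalized L1, averaged), which bounds raoQ by
  1. Zero-range traits are excluded with a warning. Euclidean distance on
  the log traits (`euclidean_log`) or on z-scores (`euclidean_z`) is
  provided because surveys computed with other toolchains often report
  raoQ magnitudes of 3–5, which are impossible under Gower scaling and
  indicate an unscaled Euclidean convention; when comparing against such
  numbers use `euclidean_log`.

## Tree completion by random grafting

Surveyed species absent from the megaphylogeny are attached within their
genus: the attachment point is drawn uniformly along the branches of the
smallest clade spanning the genus' tips, including that clade's stem, and
the new tip is extended to the tree's tip depth so ultrametricity is
preserved. Uniform-along-branch placement is the least-informative choice
consistent with "random placement within the genus". Species with no
congener fall back to their family clade when a taxonomy is supplied and
are otherwise dropped with a warning — they then also leave the abundance
analysis, since no phylogenetic position can be defended for them. The
procedure is repeated (default 1000 topologies) and raoD, its null model
and SES are computed per topology and averaged; the across-topology SD is
reported alongside.

## Blomberg's K

K is the observed ratio MSE₀/MSE divided by its Brownian-motion
expectation `(tr(C) − n/Σ(C⁻¹)) / (n − 1)`, where C is the shared
branch-length covariance, MSE₀ the mean squared deviation of tip values
from the GLS ancestral mean, and MSE the GLS mean squared error. On a
star phylogeny the ratio equals its expectation and K = 1 identically; K
is invariant to affine transformation of the trait. Significance is a
one-tailed tip-permutation test on MSE (lower = stronger signal) with the
observed arrangement included in numerator and denominator, 999
permutations by default. A constant trait or singular C raises an error
rather than returning a value.

## Null models and SES

The species pool for every null is the set of species in the community
matrix (not the full megaphylogeny): plot-level SES against the study
pool is the standard reading of "shuffling tips". The phylogenetic null
permutes tip labels — implemented as a joint row/column permutation of
the divergence matrix, which is mathematically identical and avoids
re-traversing the tree 999 times. The functional null permutes whole
trait rows; because Gower ranges are pool-level constants, this too
reduces to a label permutation of the distance matrix. The CWM null
permutes all traits jointly by species row, preserving the pool's trait
covariance and each trait's pool mean and variance exactly in every
randomization (permuting traits independently would break covariance and
test a different hypothesis; the joint null was chosen and is flagged
here). Plots whose null SD is zero (fewer than two species, or an
all-identical pool) report SES as undefined rather than ±∞ so category
summaries are not poisoned.

## Dimensionality

Per category, the 3×3 Pearson correlation matrix of (D, raoD, raoQ) over
plots is eigendecomposed. Loadings are scaled to metric–component
correlations (`Σ_m r²_mk = λ_k`); eigenvector signs are fixed by making
each component's largest-magnitude loading positive (IVs are invariant to
sign under the r² weighting, asserted in tests). Evenness of eigenvalues
(EE) and IV evenness both use Camargo's index
`1 − Σ_{i<j}|q_i − q_j|/S`, which is 1 for perfect evenness and 1/S for a
single dominant value. Importance values use squared correlations,
`raw_m = Σ_k (λ_k/Σλ) r²_mk`, normalized to sum to 1 — r² makes `raw_m`
the metric's communality-weighted variance share and matches the
observation that published IV rows sum to ≈ 1; the |r| weighting is
available as `iv_variant="abs_r"`. Uncertainty on IV evenness is a
percentile bootstrap (resample plots with replacement within category,
recompute the whole chain, 2.5/97.5 percentiles); percentile rather than
BCa because the statistic is bounded and the sample sizes (24 plots)
small. Degenerate resamples (a zero-variance metric) are redrawn and
counted.

## Group comparisons

Kruskal–Wallis (tie-corrected, χ² approximation) for overall effects;
pairwise Mann–Whitney rank-sum post hoc tests, exact when both groups
have ≤ 10 tie-free observations and normal-approximate with continuity
correction otherwise. Pairwise p-values are Holm-adjusted by default
(none and Benjamini–Hochberg available); the compact letter display is
built from the adjusted p-values at α = 0.05 with the insert–absorb
algorithm, so categories share a letter iff their adjusted pairwise test
is non-significant.

## Synthetic-data generator

The generator emulates the structure of the survey design: a 292-species
pool on a Yule (pure-birth) ultrametric tree rescaled to root depth 100
time units, six log-scale traits, and 120 plots in five land-use
categories of 24. Tips are labeled `G###_sp###` with genera assigned to
contiguous blocks of the leaf order so congeners are clustered (they need
not be strictly monophyletic, as in real genera). Traits are
`s·z_BM + (1−s)·z_noise` with both components unit-standardized and the
noise orthogonalized against the BM realization, so the mixture variance
is exactly `s² + (1−s)²`; the default signal s = 0.2 reproduces the weak
phylogenetic signal (K ≈ 0.05–0.1) typical of continuous functional
traits. Plot assembly draws `richness = 25` species (a realistic richness
for 4-m² alpine relevés) under one of three regimes — neutral (uniform),
habitat filtering (weights `exp(−strength·(tᵢ − optimum)²)` on one trait
axis, optimum drawn per plot from the pool distribution), or limiting
similarity (greedy max–min functional spacing, each step greedy with
probability `1 − e^{−strength}`) — and assigns lognormal(0, 1)
abundances, mimicking right-skewed cover data. Default per-category
regimes: filtering with strength 4/2/1 for intensive/intermediate/
extensive grazing, neutral for recent abandonment, strength-2 filtering
for past abandonment, so the expected SES sign pattern (convergence in
grazed and late-successional plots, randomness early after abandonment)
is built into the study conditions.

What the generator does **not** emulate: spatial structure and
autocorrelation among plots, intraspecific trait variation, realistic
species-abundance-distribution shape beyond lognormality, non-ultrametric
or imperfectly dated trees, and correlated trait evolution. Passing the
recovery tests therefore demonstrates that the chain detects the assembly
signal it is pointed at under clean conditions, not that any given field
pattern will be as clean.

## Numerical and reproducibility choices

Default replication matches survey practice: 1000 grafted topologies,
999 randomizations, 999 bootstrap resamples; all counts are configurable
downward, and the test-suite and acceptance runs use reduced sizes
(10–25 topologies, 199 randomizations/permutations, 199 bootstraps, 50
replicate studies for calibration) at which the reported averages are
stable. One global seed derives every stage seed via a blake2b hash of
`"<seed>:<stage>"`, so identical configurations produce byte-identical
outputs and any stage can be rerun in isolation. Divergence matrices are
computed by a single postorder MRCA-depth sweep (O(n²)); the
path-counting patristic matrix of an independent tree library is used as
the oracle in tests, never as the implementation. Ties in the greedy
max–min selection are broken uniformly at random. The Yule simulator is
run one exponential waiting time past the final speciation so no pair of
tips has zero divergence (which would make the BM covariance singular).

## Known limitations

- Grafting resolves taxonomy from binomial tip labels; synonyms or
  misspellings silently become "no congener" drops.
- The permutation null fixes richness and abundances, testing only
  species-identity arrangement; richness-constrained or swap-based nulls
  are out of scope.
- The dimensionality analysis assumes ≥ 4 plots and non-degenerate metric
  variance per category; it is generic in the number of metrics but is
  exercised and interpreted for the three-metric (D, raoD, raoQ) case.
- With strongly non-ultrametric input trees the "time since MRCA"
  interpretation of raoD degrades to half the patristic distance.
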