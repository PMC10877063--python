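# Methods

This note documents the statistical procedures the package implements, the
model behind the synthetic-data generator, the tunable parameters and their
defaults, the numerical conventions, and the known limitations.

## Preprocessing chain

Raw per-domain count tables pass through, in order: control removal and
replicate de-duplication, singleton removal, organelle/contaminant removal,
and the rare-ASV filter; each domain is then converted to relative
abundances and the two domains are merged over their shared samples.

- **Singletons** are ASVs with total count < 2 across the whole dataset.
- **Organelles/contaminants**: an ASV is dropped if any deny-list term
  (default `Chloroplast`, `Mitochondria`) occurs as a substring of its
  semicolon-joined lineage, or if it is explicitly flagged. The deny list is
  pluggable because contaminant identification conventions vary between
  labs.
- **Controls**: blank and mock samples are dropped; within a replicate
  group only the member with the largest library size is kept. Ties are
  resolved toward the lexicographically smallest sample id — an arbitrary
  but deterministic rule, and the event is logged.
- **Rare-ASV filter** (per domain, before merging): keep an ASV only if its
  maximum per-sample relative abundance exceeds 0.1 %, its total count
  exceeds 5 reads, and it occurs in more than 3 samples — all strict
  inequalities. "Relative abundance > 0.1 %" is interpreted as the maximum
  across samples (an ASV qualifies by exceeding the threshold in at least
  one sample); mean or pooled abundance would be stricter alternatives.

### Cumulative-sum scaling

CSS replaces library-size normalization with a quantile-bounded sum: each
sample's scaling factor is the sum of its counts at or below its own
l-th quantile of positive counts, and cells are rescaled by
`scale_constant / factor` (default constant 1000). The level l is chosen
data-adaptively: per-sample quantiles of positive counts are computed on the
grid 1/n … 1 (type-7 linear interpolation); at each level the median
absolute deviation of the per-sample quantiles from their across-sample
median measures instability, and the smallest level at which this
instability's relative increase between consecutive levels reaches 0.1 is
chosen (0.5 if the criterion never fires). CSS output is invariant to
per-sample multiplicative depth, which the tests fuzz.

## Environmental conditioning and collinearity

Concentration-like variables (conductivity, TOC, TN, TP, nitrate, ammonium,
dry weight, elevation) are natural-log transformed, phosphate square-root
transformed, pH left untransformed; all are then centered and scaled.
Variables containing zeros use log(x + half the smallest positive observed
value), logged. Skewness and kurtosis are recorded before and after as
transform diagnostics. Collinearity is screened two ways: the Pearson
correlation matrix (|r| < 0.8 expected) and stepwise VIF removal —
VIF(v) = 1/(1 − R²) of v regressed on the other retained variables; while
any VIF ≥ 10 the worst variable is removed (perfect collinearity gives
VIF = ∞ and is removed first).

## Spatial structure (PCNM)

Sample coordinates give a haversine great-circle distance matrix (sphere of
radius 6 371 000 m). PCNM truncates this matrix at the longest edge of its
minimum spanning tree — the smallest threshold that keeps all samples
connected — replacing larger entries by 4× the threshold (the canonical
replacement constant), double-centers −½D², and keeps eigenvectors with
eigenvalue > 1e-10 × the largest. Axes are ordered by descending eigenvalue,
so PCNM1 carries the broadest spatial scale. Axes correlated with any
environmental variable at p < 0.05 (Pearson) are retained, and an AICc
bidirectional stepwise OLS (starting from the intercept) links each retained
axis to environment plus bedrock dummies. AICc is the small-sample-corrected
operationalization of "most parsimonious"; it is not a consistent selector,
so the recovery test screens first and tolerates its known behavior.

## Ordination

PCoA eigen-decomposes the double-centered −½D² matrix; scores are
eigenvectors scaled by √eigenvalue, negative eigenvalues are reported as a
mass but excluded (no Lingoes/Cailliez correction by default). Community
distances for constrained ordination are Euclidean on log2(css + 1)
abundances — the standard companion transform of CSS; the log2 step is
configurable off.

db-RDA regresses the positive principal coordinates on centered predictors;
R² is the fitted sum of squares over total inertia, adjusted by Ezekiel's
formula 1 − (1 − R²)(n − 1)/(n − m − 1) with m the effective predictor rank
(one-hot bedrock dummies keep all four categories; the rank-tolerant
least-squares fit absorbs the redundancy so every substrate can be
selected). Significance uses a permutation pseudo-F with the add-one
convention p = (#{F_perm ≥ F_obs} + 1)/(n_perm + 1).

Forward selection adds, at each step, the candidate with the largest
adjusted-R² gain, subject to (i) a marginal permutation test at level alpha
(Freedman–Lane style: the candidate's rows are permuted with the selected
terms held fixed) and (ii) the cumulative adjusted R² not exceeding the
full-model adjusted R². Rule (ii) is the standard double-stopping scope; it
is conservative when the remaining candidates are uninformative, because
the submodel's and full model's adjusted R² then estimate the same
population quantity and the comparison is a near coin flip at the last
informative step. `adjr2_scope=False` disables it, leaving the permutation
test as the only stopping rule; the tests document both behaviors.

## Co-occurrence network and modules

Edges join ASV pairs with tie-corrected Spearman ρ > 0.7 across samples,
positive correlations only; zero-variance ASVs are excluded and logged, and
isolated nodes are dropped. At n = 85 samples, the permutation-null
two-sided p < 0.001 critical value of |ρ| is ≈ 0.355 (Monte-Carlo, 10⁶
permutations; Student-t approximation t/√(n−2+t²) ≈ 0.351), so the 0.7
threshold operates far inside the significant region and no separate
p-value filter is needed.

Module detection runs Louvain (10 seeded restarts, best-Q partition kept),
with asynchronous label propagation and igraph's walktrap (4-step walks,
dendrogram cut at maximum modularity) as convergence checks; agreement is
reported as pairwise adjusted Rand index, and the Louvain partition is the
one used downstream. Modularity is weighted Newman–Girvan
Q = Σ_c (w_c/W − (s_c/2W)²).

Node metrics: degree, Brandes betweenness over **unweighted** shortest
paths (pair counts, not normalized; a 1/ρ-cost weighted variant is behind a
flag), and the local clustering coefficient. Keystone candidates per module
are the union of the top-k (default 1) nodes by betweenness and by degree,
using competition ("min") ranking so top ties all qualify; the global
maximum-betweenness node is flagged.

## Module–environment consensus

A module's abundance profile is the per-sample mean of its member ASVs'
z-scored relative abundances (ddof = 1); standardization removes any scale
difference between the merged domains, and zero-variance members are
excluded with a log message. Profiles are tested across substrates with
Kruskal–Wallis, and against each environmental variable with Pearson and
Spearman correlations; p-values are Holm-corrected within each correlation
family across **all** module × variable pairs (the conservative reading of
"all p values"; per-module families are configurable). The random-forest
ranking fits a regression forest per module (500 trees, mtry = ⌈p/3⌉,
minimum leaf 5) and scores variables by mean out-of-bag permutation increase
in squared error. A variable is a **consensus predictor** when both
Holm-corrected correlation p-values fall below alpha (default 0.01) and the
variable is in the top-3 RF ranks; the top consensus variable (best RF
rank, ties by |r|) is the module's **major explanatory variable**, reported
with its sign. Pairs where |ρ_Spearman| − |r_Pearson| > 0.2 are annotated
"possibly nonlinear" — an automated stand-in for manual scatterplot
inspection, which cannot be part of a tested pipeline. The top-3 RF cut is a
declared simplification of multi-phase RF variable selection.

## Synthetic data model

The generator emulates the structure this analysis assumes, at the scale of
the reference study conditions: 8 sites (two per bedrock type) × 12 samples
= 96 samples, plus 2 blanks, 1 mock and 1 replicate when controls are
enabled; a bacterial table (~366 ASVs) and a eukaryotic table (~120 ASVs).

- **Environment**: each variable is drawn per sample around its substrate
  mean (realistic Antarctic mineral-soil magnitudes; e.g. pH 6.8 ± 0.5,
  conductivity 120 ± 30 µS/cm). Module m's driver variable is shifted by
  1.2 s.d. in m's preferred substrate with the planted sign, so environment
  and bedrock are correlated as in real surveys; dry weight and elevation
  carry additional mild substrate signatures as confound decoys.
- **Module activity**: ln a(m, j) = ln affinity(m, substrate_j) +
  β·z(driver_m, j) + δ(m, j), with affinity 6.0 in the preferred substrate
  vs 0.5 elsewhere, β = 1.1 (sign alternating by module), and module noise
  δ ~ N(0, 0.8²).
- **ASV abundances**: member i multiplies a baseline (log-normal, σ = 0.8)
  by a(m, j) and by exp(ε) with per-ASV idiosyncratic noise σ_i drawn
  uniformly from 0.9–2.0. The hub of each module uses σ = 0.15 and a 3×
  baseline: an abundant taxon tightly coupled to its module's activity. The
  heterogeneous member noise is deliberate — it makes hubs emerge through
  the same Spearman estimator the pipeline uses (the hub correlates with
  every member more strongly than any member pair does, and the noisiest
  members are reachable only from the hub), and it spreads member–member
  correlations smoothly around the 0.7 edge threshold instead of piling
  them on one side of the cliff.
- **Counts**: per cell a gamma intensity with shape `dispersion` (default
  8) around the expected abundance, then a multinomial draw of the sample's
  library size (uniform in 20 000–60 000) over the intensities — a
  negative-binomial-type overdispersed model whose emitted library sizes
  are exactly within the configured depth range; as dispersion → ∞ the
  counts become Poisson/multinomial. Background ASVs (160) have no module
  signal; 6 decoy ASVs carry Chloroplast/Mitochondria lineages so organelle
  filtering is exercised end-to-end.

All default effect sizes were frozen after pilot simulations, before the
recovery thresholds were asserted: over 20 seeded runs the pipeline recovers
the planted partition at ARI ≥ 0.99, planted hubs appear among their
module's keystone candidates in ~97 % of (run, hub) cases, and the planted
driver is recovered as the module's major explanatory variable in ~98 % of
(run, module) cases.

What the generator does **not** emulate: compositional coupling beyond the
multinomial draw, taxonomic mis-assignment, chimeras, phylogenetic
correlation among ASVs, spatially autocorrelated environments within sites,
negative (exclusion) associations, and uneven site sampling. Passing
recovery tests therefore demonstrate that the pipeline's estimators recover
the structure they assume — not that real soil communities satisfy those
assumptions.

## Numerical conventions and scale choices

- Permutation p-values always use the add-one convention (never zero).
- Eigenvalue positivity tolerances: 1e-10 × largest (PCNM), 1e-9 relative
  (PCoA); eigenvector signs are fixed by making the largest-magnitude
  loading positive, so results are stable across BLAS builds.
- Kruskal–Wallis uses the chi-square reference with tie correction; its
  calibration test uses groups of 50, where the asymptotic approximation
  is accurate (at very small groups the approximation error itself is
  detectable by a 1000-replicate KS test).
- Deterministic seeds thread through every stochastic step (Louvain
  restarts, permutation tests, random forests, the generator); the same
  seed gives byte-identical simulated datasets.
- Test problem sizes (24-sample small studies, ≤ 15-node oracle graphs,
  199–999 permutations, 20 recovery runs) were chosen so the full suite
  exercises every stage at statistically meaningful scale while remaining
  quick to run on a single CPU.

## Limitations

- Spearman co-occurrence on relative abundances carries compositional bias;
  the package deliberately follows the simple-correlation design (with a
  strict threshold) rather than compositionally corrected estimators.
- The forward-selection entry test is selection-biased (the best candidate
  is tested at level alpha), so under a global null the family-wise
  spurious-selection rate exceeds alpha; the double-stopping scope rule
  partly compensates, at the cost of the conservativeness described above.
- The RF consensus uses a fixed top-3 rank cut rather than a
  null-calibrated importance threshold.
- PCoA negative eigenvalues are reported but uncorrected by default, so
  percent-explained values for strongly non-Euclidean dissimilarities
  should be read with care.
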