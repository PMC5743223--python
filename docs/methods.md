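# Methods

This note records the models, conventions and numerical choices behind
`clonepotency`, in the order data flows through the pipeline.

## Observation model

The atomic observation is a *clone*: the progeny of one sorted
progenitor cultured in one well, summarized by non-negative integer
terminal cell counts over the six core lineages in the fixed canonical
order (G, M, L, DC1, DC2, pDC).  Counts are flow-cytometry events, so
fractional values are rejected rather than rounded.  The JD culture arm
adds Er and Mk columns after the core six.  One canonical lineage order
is used in every matrix, file and statistic; input files with permuted
columns are re-canonicalized on read, which makes all downstream results
invariant to the input column order.

## Positivity and bias statistics

A lineage is detected when its count reaches the subset's threshold —
7 events, lowered to 2 for CDPs, whose clones are small.  A clone with
no detected lineage is unproductive and excluded (this is the only data
exclusion anywhere in the pipeline).  For productive clones:

* commitment degree `c_k = x_k / Σ x_j` (sums to 1 exactly up to float
  rounding; all bias statistics are invariant under per-clone scalar
  rescaling);
* equipotency ratio = smallest / largest yield **among detected
  lineages** of a non-unipotent clone.  Computing it over all six
  lineages would pin the ratio at 0 for every clone short of six
  detected lineages and destroy the distribution's shape; a switch
  (`equipotency_over_positive=False`) restores the all-six convention
  for sensitivity analysis;
* bias ratio = second-largest / largest of the six raw yields, again
  only for non-unipotent clones;
* predominant lineage = argmax yield, ties broken deterministically by
  canonical lineage order (ties are logged).

"Non-unipotent" means ≥2 detected lineages after positivity calling.
When exactly two lineages are detected and no sub-threshold counts
intrude, the two ratios coincide; in general neither bounds the other.

## Normalization

Donor factors assume a progenitor phenotype behaves similarly across
cord-blood donors: within each subset, a donor's factor is the geometric
mean of its productive clones' total yields divided by the geometric
mean of all donors' per-donor geometric means.  Lineage factors equalize
the geometric means of the six count columns (the culture under-produces
pDCs).  Both use the zeros-excluded geometric mean: it keeps factors
finite, makes them exactly equivariant under rescaling, and makes the
equalization postcondition exact; a pseudocount alternative is provided
for matrices whose columns are nearly all zero, at the cost of making
both properties approximate.  Factors are multiplicative; normalization
divides by them, and re-deriving factors from normalized data returns 1
(idempotence).  Per-clone scalar factors cannot change any within-clone
ratio, so the bias statistics are computed on raw counts and are
unaffected by donor normalization.

The embedding input is the lineage-equalized matrix of productive clones
after `log10(x + 1)`; donor normalization is applied first by default
and both steps are individually switchable.

## Affinities and embedding

Similarity between clones i and j is the Gaussian conditional
probability P(j|i) over squared Euclidean distance in log-yield space,
with P(i|i) = 0.  Each bandwidth σ_i is calibrated by bisection (with
doubling until the bracket closes, ≤200 iterations) until the row's
perplexity 2^H matches the target (default 20) to 1e-5 in log2; a row
that cannot be calibrated — e.g. a point all of whose neighbors coincide
with it — is reported by index.  Conditionals are symmetrized to
P(i,j) = (P(j|i)+P(i|j))/2N, which has total mass exactly 1 and reads as
a one-step diffusion transition kernel over clones.

The 2-D map minimizes KL(P‖Q) with the Student-t kernel Q by exact
O(N²) gradient descent — at a few thousand clones the Barnes-Hut tree
approximation buys nothing and costs exactness.  Schedule: early
exaggeration 12 for the first 250 iterations (clamped to half the run
for short runs), momentum 0.5 → 0.8, per-coordinate adaptive gains
(×0.8 / +0.2, floored at 0.01), and learning rate
max(N / early_exaggeration, 50) by default — a fixed large rate
(e.g. 200) diverges for some seeds at small N, flinging points apart;
the size-scaled rate is stable across the range used here.  Runs are
bit-reproducible per seed.  Repeated runs with different seeds produce
different coordinates but consistent cluster structure, which is why
downstream track assignment recomputes backbones per embedding rather
than caching them.

PCA operates on centered, unit-scaled columns (correlation PCA) via SVD;
constant columns are dropped with a warning.  Lineage co-ancestry is
d = 1 − ρ with Spearman's ρ (average ranks) between lineage columns
across productive clones — lineages frequently co-produced by the same
clones are close.  Classical MDS double-centers −½·J·D²·J and
eigendecomposes; since 1 − ρ need not be Euclidean, negative eigenvalues
are possible and are returned for inspection, with axes beyond the
positive spectrum zero-filled.

## Tracks

A lineage's backbone is the set of embedded clones with commitment
degree ≥ 0.7 to it ("70% commitment" read as at-least, boundary
inclusive).  Any threshold above 0.5 makes backbones disjoint; 0.5 or
below is rejected.  A clone's distance to a track is the Euclidean
distance to the nearest backbone member in the 2-D map (a switch allows
the 6-D yield space instead), and the clone is assigned to the nearest
track, ties broken canonically.  Empty backbones (no sufficiently
committed clone) contribute +∞ and are reported.

## Clustering and leaf ordering

Clones are clustered by complete-linkage agglomeration on Euclidean
distances of the log-scaled matrix (scipy linkage; merge heights are
monotone by construction).  Leaf ordering maximizes the summed
similarity of adjacent leaves over all 2^(N−1) subtree flips with an
exact dynamic program over subtree endpoint pairs: for each internal
node the table M[u, w] (best cost of arranging its leaves starting at u
and ending at w, endpoints necessarily in different children) is a
min-plus product of the children's tables with the inter-leaf cost
matrix, vectorized and chunked; a traceback over stored argmins
reconstructs the permutation.  The similarity defaults to negative
Euclidean distance (overridable).  The mirrored ordering has equal
objective and either may be returned.  scipy's own
`optimal_leaf_ordering` was found to return sub-optimal orderings on
roughly half of small random instances when checked against exhaustive
flip enumeration, so it is deliberately not used.  The potency-class cut
takes the dendrogram to exactly k clusters (default k = 4).

## Heritability

A granddaughter family holds the 2–4 individually cultured
second-generation descendants of one traced ancestor; families with
fewer than two viable granddaughters are excluded.  The ancestor's
potency is inferred as the elementwise sum of granddaughter yields.  A
granddaughter inherits when its predominant lineage equals the ancestral
bias and switches otherwise; inherited + switched = classified, always.

For real data the ancestral bias must be the predominant lineage of the
inferred sum.  For synthetic families the generator's true ancestral
archetype is stored on the family and used by default: the sum-inferred
plurality always matches at least one granddaughter, so the inferred-
ancestor estimator cannot reach 0% and overstates inheritance when
transmission is weak (expectation ≈0.65 at a true rate of 0.5 with
two-granddaughter families) — an estimator property worth knowing when
interpreting real tracing data, and the reason parameter-recovery tests
classify against ground truth.  Both paths are exposed
(`use_known_ancestor`).

The commitment fold-change of a granddaughter is its commitment to its
own predominant lineage divided by the ancestor's commitment to that
same lineage (for switched progeny, the new lineage).  Note a structural
asymmetry of this convention: a switched granddaughter's new lineage is
typically rare in the family sum, so its denominator is small and its
fold-change large; meaningful comparisons between inherited and switched
progeny should therefore use the commitment degree itself alongside the
fold-change, and the simulation tests assert exactly the two robust
properties: inherited fold-change > 1 on average, and inherited
commitment degree above switched commitment degree.

## Dosage correlation

Inputs are two per-subset percentage tables with shared row order: the
share of cells in each of the six IRF8/PU.1 gates, and the share of
productive clones biased to each lineage (rows may sum to under 100; an
ungated remainder is allowed).  The gate × lineage matrix holds Pearson
r across subsets; constant vectors give NaN and are reported.
Significance defaults to the classical t-test on r,
t = r·√((n−2)/(1−r²)) with n−2 df, which is exact under the null — its
measured type-I error at n = 9 over 10,000 null replicates is 0.047 at
α = 0.05.  The Fisher z variant (atanh r · √(n−3) against the standard
normal, measured 0.053) is available as `method="fisher"`.  |r| = 1 is
capped at 1 − 1e-12 before transforming.  For heat-map-style reporting
the r matrix rows and columns are ordered by the clustering module.

## Synthetic generator

The generator reproduces the statistical structure the analysis assumes,
not the biology that produced it:

* **Scale.** Defaults: ~5,000 seeded clones over 9 subsets and 17
  donors, with per-subset unproductive fractions around 0.5–0.65 (0.52
  for HSC/MPP) giving roughly 45% overall clonal efficiency.
* **Composition.** Each productive clone draws an archetype from a
  subset-specific mixture over six lineage-biased archetypes plus an
  equipotent one, then a Dirichlet composition (precision 30) around the
  archetype mean, then a multinomial allocation of the clone total.  The
  archetype mean puts weight e^c on the dominant lineage against a
  background of 5 (c = `bias_concentration`, default 3 → dominant share
  0.80), so raising c lowers the typical bias ratio monotonically.  The
  default mixtures follow the known subset propensities: myeloid-path
  subsets (CMP/GMDP/MDP) weight G and M, lymphoid-path subsets
  (LMPP/MLP/BNKP) weight L, DC1 and pDC, CDP is DC-dominated, and the
  stem compartments (HSC/MPP) carry the largest equipotent weight.  An
  optional cross-priming matrix biases each archetype's background
  composition toward chosen partner lineages, creating co-ancestral
  lineage pairs by construction (used to test the co-ancestry map).
* **Yields.** Clone totals are log-normal (log10 sd 0.8; means 2.5 for
  biased and 3.5 for equipotent archetypes, spanning the observed
  orders-of-magnitude spread), shifted up by
  `bias_yield_coupling × (1 − bias ratio)` (default 0.8 decades at full
  bias) so biased clones out-yield equipotent ones, plus a per-donor
  log-normal effect (sd 0.15) that gives the donor size factors
  something to remove.  Optional division tracking decays expected
  yield by 0.35 decades per CFSE division across generations {0, 3, 6}.
* **Families.** Each family draws a biased ancestral archetype and a
  latent family composition; granddaughters inherit with probability
  `inheritance_probability` (default 0.8, matching observed ~80%
  transmission) and sharpen the family composition (elementwise power
  2, renormalized — inherited progeny amplify the bias), or switch to a
  kernel-chosen other lineage (uniform by default) with the dominant
  and target shares exchanged and expected yield reduced by 0.5 decades.
* **Dosage tables.** Gate percentages are a noisy image (Gaussian,
  default sd 3 percentage points, renormalized to 100) of the expected
  bias composition under a recorded gate ↔ lineage correspondence.
* **Streams.** All randomness derives from one seed through fixed
  substream keys, so enlarging the clone table never perturbs family or
  dosage draws.

What the generator does *not* emulate: division kinetics or TF dynamics,
inter-donor differences in composition (only in scale), correlations
between a clone's bias and its donor, plate/batch effects, and the
exact shapes of real yield distributions.  Passing tests therefore
demonstrate that the algorithms recover known structure under the
assumed statistical model — not that real data satisfy that model.

## Problem sizes and tolerances

Unit and acceptance tests run on scaled-down tables (tens of clones per
subset; 200-clone affinity checks; 500 families; 10,000 null replicates
for test calibration), sizes chosen so the full suite completes in well
under a minute of compute while keeping every estimator in its
asymptotic regime.  The acceptance script uses a ~2,000-clone table.
Key tolerances: perplexity calibration 1e-5 (log2) per row; affinity
mass/symmetry 1e-10; size-factor postconditions 1e-9 relative; MDS
planar recovery 1e-8; statistical recoveries within 3 standard errors.

## Known limitations

* Exact t-SNE is O(N²) per iteration and the leaf-ordering DP is O(N³)
  worst case; both are comfortable to a few thousand clones but not
  beyond.
* The four-cluster cut uses a fixed k; no model selection is attempted.
* Equipotency/bias ratios are undefined for unipotent clones by
  construction; summaries over "non-unipotent clones" depend on the
  positivity thresholds, which should be reported alongside any such
  percentage.
* The inferred-ancestor inheritance estimator is upward-biased at low
  transmission rates (see Heritability) — a measurement-design
  property, not an implementation artifact.
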