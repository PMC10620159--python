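# Methods

This note documents the models and procedures implemented in `fritniche`,
the conventions chosen where the field leaves them open, what the
synthetic-data generators do and do not emulate, and the package's known
limitations.

## Occurrence preparation

**Thinning.** Duplicate pruning keeps one record per species per
20 km × 20 km cell. The grid lives in an equirectangular projection about a
reference latitude (1° latitude = 111.195 km; 1° longitude =
111.195 · cos(ref) km), with the reference defaulting to the records' mean
latitude. This matches the "20 km" intent at mid-latitudes without
projection machinery; the first record per cell in input order is kept, so
thinning is stable and reproducible. Thinning is exactly idempotent when
the reference latitude is held fixed; re-deriving it from an
already-thinned set can shift the longitude scale by a fraction of a
percent, which is why `thin_occurrences` exposes `ref_lat` explicitly.

**Variable pre-filter.** For every variable pair with |Spearman ρ| > 0.8
the lower-contribution variable is dropped, greedily in ascending
contribution order (ties broken by variable name, logged). Contribution
scores default to each variable's univariate rank AUC against the
presence/pseudo-absence labels, folded about 0.5 so direction does not
matter — a model-free score available before any multivariate fit exists.
A single ascending pass suffices: removing a low-contribution variable
never creates a new correlated pair, so the retained set provably contains
no pair above the threshold.

## Ensemble SDM

**Members.** Two members are implemented from their definitions and always
available:

- *SRE* — the surface range envelope, a per-variable empirical quantile
  box over presence rows at quantiles [q, 1 − q], q = 0.025 by default
  (q = 0 gives the min/max box; a constant variable yields a point
  interval). Prediction is 1 iff every variable lies inside its interval,
  boundaries inclusive.
- *GLM* — a logistic model fitted by iteratively reweighted least squares
  on standardized variables, iteration cap 500 (reaching the cap or
  runaway coefficients flags possible perfect separation; predictions are
  still returned). The ensemble member uses degree-2 features
  (z and z²): a purely linear logit is monotone in each variable and
  cannot place a response-curve optimum in the interior of a variable's
  range, which the suitable-range analysis requires. Quadratic logits are
  also the common default of ensemble-SDM GLM implementations.

Additional learners (random forest, classification tree, gradient
boosting, neural network, discriminant analysis) plug in behind the same
fit/predict contract via scikit-learn; their internals are not this
package's contribution.

**Pseudo-absences.** Sampled uniformly without replacement among cells the
presence-fitted SRE rejects, excluding cells holding a presence record,
one pseudo-absence per presence by default. This mirrors the
envelope-based background strategy of presence-only ensemble modelling;
note it makes evaluation scores optimistic relative to true absences (the
background is by construction environmentally distinct), which is why the
package validates recovery on virtual species rather than reading the
scores as field performance.

**Evaluation.** Per run: a stratified random train/test split (train
fraction 0.85, 0.80 or 0.75 conventionally; any fraction accepted),
15 runs per algorithm by default. AUC is the Mann–Whitney rank statistic
with ties counting one half. TSS and Cohen's κ are computed at the lowest
threshold on the grid 0.00–1.00 (step 0.01) that maximizes TSS on the test
scores — a deterministic convention, stated because single published TSS/κ
values rarely specify their threshold rule. An optional bootstrap mode
(fit on a resample, score out-of-bag) yields score confidence intervals.

**Ensemble.** Members with mean test AUC strictly above the cutoff (0.9)
are combined as an AUC-weighted mean of member probabilities (weights
normalized to sum to 1), making the ensemble a convex combination —
cellwise bounded by the member predictions. Committee averaging is the
main alternative convention; weighted mean was chosen for continuity of
the projected surfaces.

**Response curves and suitable ranges.** A variable is swept over its
observed range (101 points) with all other variables fixed at their
presence means. The suitable range is the threshold-0.5 interval around
the curve's global maximum: contiguous crossings linearly interpolated
between grid points, clipped at the observed range; the optimum is the
argmax, reported even when the curve never reaches the threshold.

**Habitat grades and areas.** Grades partition [0, 1] as not [0, 0.25),
low [0.25, 0.5), moderate [0.5, 0.75), high [0.75, 1] — lower-inclusive
bins, top bin closed. Cell areas are spherical:
R² · Δλ · Δφ · cos(lat), R = 6371.0088 km, so grade areas sum exactly to
the domain area.

**Variable importance.** Permutation mode: 1 − corr(prediction,
prediction with the variable permuted), averaged over shuffles and
normalized to 100 %. Jackknife mode: the AUC drop on a held-out split when
the variable is excluded from refit members, clipped at zero and
normalized. Both are provided because published importance figures rarely
state which convention produced them; zero total importance falls back to
uniform percentages with a warning.

## Niche statistics

Overlap indices operate on suitability normalized over the cell set valid
in **both** maps (cells missing in either are excluded from both):
Schoener's D = 1 − ½ Σ|p_A − p_B| and the Hellinger-based
I = 1 − ½ Σ(√p_A − √p_B)²; both are symmetric, in [0, 1], equal 1 iff the
distributions coincide and 0 iff their supports are disjoint, with I ≥ D.
Levins breadth uses B1 = ((Σp²)⁻¹ − 1)/(n − 1) and
B2 = −Σ p ln p / ln n (natural log, 0·ln 0 = 0), both standardized to
[0, 1] and maximal only for the uniform distribution. The overlap region
is where both species grade moderate or better; the overlapping degree is
the fraction of the two species' records falling in that region —
symmetric in the species and monotone in the mask. Species-specific
habitat is where the focal species grades moderate-or-better and no other
species does.

## Chemical clustering

Fingerprints are 881-bit binary vectors consumed as data (fingerprint
computation from structures is out of scope). Tanimoto similarity is
|a∧b|/|a∨b| with the all-zero pair defined as 0; the network links pairs
with similarity **strictly** greater than 0.85. Metabolite-groups default
to connected components; the IPCA-style mode mines dense subgraphs by
seeding at the highest-degree unassigned node and extending while the
subgraph density stays ≥ 0.5 (the density threshold is configurable —
published IPCA uses give no parameters). Isolated metabolites are retained
as singleton groups. Plants are compared through the binary plant × group
matrix with Jaccard (|A∩B|/|A∪B|) or Simpson (|A∩B|/min(|A|,|B|))
similarity; trees are agglomerative (UPGMA default — the published trees
do not state their linkage) and bootstrap support resamples the group
columns with replacement, scoring each internal node by the percent of
replicate trees containing the same leaf cluster.

## TN93 distances

The closed-form Tamura–Nei distance uses pooled empirical base frequencies
over both sequences, the observed purine-transition (P1),
pyrimidine-transition (P2) and transversion (Q) proportions, and pairwise
deletion of gapped/ambiguous sites (complete deletion optional). When a
logarithm argument is non-positive the pair is saturated: the distance is
undefined and reported as NaN with a warning rather than clamped. A zero
pooled frequency for a base class actually observed to substitute is an
error.

## Correlation

Pearson r with R² = r² and a two-sided P from t = r√((n−2)/(1−r²)) on
n − 2 degrees of freedom; |r| = 1 returns P = 0 exactly. For n = 3 pairs
(one degree of freedom) the t tail is the standard Cauchy,
P = 2(½ − arctan|t|/π), and the implementation matches this closed form to
machine precision. Reports always carry n and a low-power flag below five
pairs — with three species pairs the test is honest but fragile, and the
trend line (OLS) is descriptive. Dissimilarity (1 − similarity) or
distance is always the y variable; R² is reported sign-free.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the *statistical shape* of the study inputs, with
explicit seeds and bit-reproducible output:

- **Environmental layers**: Gaussian white noise smoothed at a
  correlation length (default 4–5 cells) and affinely rescaled so sample
  mean/sd equal the request exactly. Real bioclim layers additionally have
  cross-variable covariance, anisotropy, elevational structure and
  fragmented coastlines; none of that is modelled, so passing tests show
  the machinery is correct, not that any real species' map is.
- **Virtual species**: product-Gaussian suitability with per-variable
  weights; presences drawn with probability proportional to suitability,
  jittered within their source cell. A configurable fraction of records
  are near-duplicates (~0.1 m from their source, hence provably inside the
  same 20-km thinning cell), giving exact thinning ground truth; the
  default 20 % mirrors the raw-to-thinned ratio typical of herbarium
  compilations.
- **Fingerprint clusters**: random centres at ~10 % bit density (~88
  on-bits) kept below 0.5 pairwise Tanimoto, members flipped in
  `flip_bits` random positions. The expected within-cluster similarity is
  roughly (m − f)/(m + f); `flip_bits` is validated against the 0.85
  network threshold and defaults to 4 (≈ 0.91). Real PubChem fingerprints
  have correlated bits and uneven density.
- **Alignments**: site-independent TN93 evolution with transition
  probabilities from the matrix exponential of the rate matrix normalized
  to one expected substitution per site per unit branch length — exact at
  any divergence. No rate heterogeneity across sites, no indels.

Default problem sizes — 100 × 100 rasters, 200 presences, 15 evaluation
runs, 10⁴ alignment sites, 5 000 pipeline sites, 200 tree bootstraps — are
chosen so every recovery check is comfortably inside its sampling noise
while the full suite runs in well under a minute of compute per stage.

## Pipeline conventions

One master seed fans out to per-stage seeds by stable hashing
(blake2b) of stage names, so stages are reproducible independently of
execution order; all seeds are written to `seeds.json`. Future/scenario
stacks are handled generically as labelled layer-shifted stacks projected
through the fitted ensemble — no calendar or emissions logic. Any stage
failure halts the run with the stage name.

## Known limitations

- The SRE/background circularity noted above: evaluation against
  envelope-derived pseudo-absences overstates discrimination relative to
  true absences.
- Published overlap statistics computed by other toolchains can differ in
  their normalization domain (the shared-cell convention here) and in the
  B2 logarithm base; both conventions are stated above precisely so
  differences are attributable.
- Maximum-likelihood tree inference, niche equivalency randomization
  tests, and fingerprint generation from structures are out of scope.
- With three species pairs the correlation analysis cannot support strong
  claims; the report says so rather than hiding it.
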