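# Methods

## Model family

All models are discrete Bayesian-network classifiers over a response node
C and covariate nodes X₁…X_k. In the naive form C is the sole parent of
every covariate. In the tree-augmented (TAN) form the covariates are
additionally joined by the maximum-weight spanning tree under empirical
class-conditional mutual information

    I(Xi; Xj | C) = Σ_{xi,xj,c} P(xi, xj, c) · log₂ [ P(xi, xj | c) / (P(xi | c) · P(xj | c)) ]

(bits; 0·log terms are zero; each pair's CMI is computed over the cases
complete in Xi, Xj and C). The tree is oriented outward from a root
covariate (default: first in catalog order), so every covariate has at
most two parents — C plus at most one covariate — and a k-covariate TAN
has exactly 2k − 1 links for k ≥ 2. Kruskal's algorithm runs on edges
sorted by (−weight, name, name), so equal-weight structures are
reproducible.

CPT learning is frequency counting with a symmetric pseudo-count `alpha`
per cell: row = (count + alpha)/(total + alpha·|states|). `alpha = 1`
(the default) approximates an uninformative prior and keeps rows proper
when a parent configuration is sparse; `alpha = 0` yields exactly the
empirical conditional frequencies, which the tests exploit as an oracle.
Counts for each node use the cases complete in that node and its parents
(available-case analysis); there is no EM. Never-observed parent
configurations with `alpha = 0` get a uniform row.

Inference is exact. Observed covariates contribute likelihood factors;
unobserved covariates are summed out along the covariate tree by upward
message passing (each node's message to its tree parent sums its CPT over
its allowed states times its children's messages). A vectorized
product-of-factors path handles the fully-observed rows of a case table;
the property tests check both paths against brute-force enumeration of
the full joint on random ≤ 5-node models.

## Error conventions and scores

Predictions are the dominant posterior state, ties to the earlier-listed
state. Given a focal state (RERA):

* overall error — multiclass misclassification fraction;
* Type I (false presence) — false focal predictions / all focal
  predictions;
* Type II (false nonpresence) — missed focal cases / all non-focal
  predictions.

The predicted-class denominators are deliberate: they answer "when the
model asserts presence (absence), how often is it wrong?", the question a
manager acts on. For the nine-state response only Type I/II binarize on
the focal state; overall error stays multiclass. An empty denominator is
reported as 0 with an explicit `undefined` flag — a model that never
predicts presence genuinely has no false-presence rate, and the flag
prevents mistaking that for perfection.

Spherical payoff is the mean over cases of p(true state)/‖p‖₂ of the
posterior vector: 1 for certain-and-correct, 1/√2 for a flat binary
posterior, 0 for certain-and-wrong.

Cross-validation is stratified k-fold (default k = 4, seed 42; folds via
scikit-learn's StratifiedKFold, sizes within one case and per-class
balance within one case of proportional). Structure *and* CPTs are
re-learned on each training split; confusions are summed before the error
partition, payoff is case-weighted.

Sensitivity is entropy reduction: I(C; Xi) under the model's own joint,
obtained by exact enumeration (for each state of Xi, the class likelihood
of that single observation). It is bounded by H(C) and is zero exactly
when the covariate's CPT does not depend on the class.

## Discretization

Continuous covariates are cut into at most 5 ordered states with at least
20 training cases per state. States are seeded at equal-frequency
quantiles; cut points snap to midpoints between adjacent distinct data
values ([low, high) convention, terminal states clamp). When any bin
falls below the support floor the bin count is reduced by one and the
quantiles recomputed — a re-seeding rule rather than pairwise bin
merging, chosen because it keeps the final states balanced (e.g. 60
distinct values at floor 20 give three states of 20, where greedy merging
would give 24 + 36) and makes state count monotone in the support floor.
Equal-frequency seeding rather than equal-width: the support floor is a
frequency criterion, and equal-width bins on the strongly skewed distance
covariates would starve the tails. Categorical covariates pass through
with native labels, capped at 5 states by pooling the infrequent labels
into `other`.

## Covariate screening and species comparison

Screening computes all C(k,2) pairwise Pearson correlations (pairwise
deletion of missing values) over the 13 continuous
elevation/distance/patch covariates; vegetation covariates are excluded
as too sparse. A pair flags when p < 0.05 and |r| > 0.75. Elimination is
greedy: remove the covariate in the most flagged pairs (ties: larger mean
|r| over its flagged pairs, then the later-listed covariate, so the
first-listed, more primary variable survives), repeat until no flagged
pair remains among the retained set. On the default synthetic conditions
this removes MHHW, Elev_MHHW and Dist_Ag, a 13 → 10 reduction.

The species comparison uses unpaired Welch t tests (unequal variances —
the safer default; the companion two-sided F test on the larger/smaller
variance ratio lets users check the equal-variance assumption) per
covariate over the trap nights where each species was captured, with a
Bonferroni multiplier equal to the number of covariates in the table
(16). The higher-mean species is reported only below the adjusted
threshold, else `nd`.

## The model suite

Seven covariate sets define the variants: C1 trap design (site, year,
session, layout, trap position), C2 latitude–longitude, C3 dominant-plant
vegetation (4 covariates), C4 top-three-plants vegetation (12, a superset
of C3), C5 elevation/tidal datums after screening (Marsh_Elev, MHW,
Elev_MHW, Elev_MHHW), C6 distances after screening (levee, water, bay,
road), C7 patch sizes (2). Nineteen set combinations × two responses give
38 models. Variants 6/25 use the single-covariate distance set
(`C6solo = [Dist_Road]`): the published two-node form of that variant is
only consistent with a one-covariate distance model, while the combined
variants need the four-covariate C6 — set membership is therefore
config-driven with these defaults.

Ranking is a Pareto frontier minimizing Type I error, overall error and
probability count and maximizing spherical payoff; model a dominates b
when no objective is worse and at least one fractional metric is better
by more than ε = 0.01 (or the probability count is strictly smaller).
The ε keeps trivially different payoffs from knocking simple models off
the frontier. The `selected` list (minimal Type I, then overall error,
then probabilities within the frontier) is advisory output only — best-BN
selection is acknowledged to be partly subjective, and the frontier is
the objective product.

Complexity counts: nodes; directed links; probability values = every CPT
cell including the prior, Σ_nodes |states| · Π_parents |states|. Binary
response with one 5-state covariate: 2 + 2·5 = 12. Binary TAN with two
5-state covariates: 2 + 2·5 + 2·5·5 = 62. Nine-state response, same
structure: 9 + 45 + 225 = 279. Twenty-two covariates: 2·22 − 1 = 43
links.

## Synthetic study conditions

The generator emulates the survey's statistical structure, not its
geography. Defaults: 5 sites × 827 traps × 3 nights = 12,405 trap nights
(equal effort per site, chosen so the default total equals the study
scale under the sites × traps × nights parameterization); P(empty) =
0.731 per trap night; capture outcomes from the nine-species composition
with RERA = 669/3,339 = 20% of captures. Continuous covariates are drawn
per *trap* (constant across that trap's nights) through a latent-Gaussian
copula: correlation targets are imposed on the latent normals and each
margin is transformed to its configured normal/lognormal/uniform shape
(clipping percent covers to [0, 100] and distances to ≥ 0). Default
correlation blocks plant the near-duplicate tidal datums (MHW–MHHW 0.99,
Elev_MHW–Elev_MHHW 0.97), the urban/agriculture trade-off (−0.85) and
mildly related patch metrics (0.60). An infeasible (non-positive-definite)
correlation matrix is rejected.

RERA presence is driven by planted effects — log-odds coefficients per SD
of covariate, default Patch_Size 1.0, Dist_Road 0.8, longitude 0.6
(larger patches, further from roads, more easterly) — applied as an odds
tilt to the RERA component of the capture mix, other species rescaled
proportionally. The tilt intercept is re-calibrated per simulation
(Brent root-finding on the realized linear predictor) so the planted
effects redistribute *which* trap nights are RERA without moving the
marginal 20% share. Missingness is missing-completely-at-random per
continuous covariate (default 2%).

What the generator does not emulate: spatial autocorrelation and marsh
geometry, tidal dynamics, season/year trends, detection heterogeneity
across trap layouts, and the vegetation sparsity pattern of real plots.
Passing tests therefore demonstrate correctness of the estimators and
the recoverability of planted structure, not field-data conclusions.

## Numerical and edge-case choices

* Log base 2 throughout (bits).
* Posterior normalization falls back to uniform when the evidence has
  zero likelihood under every class (possible only with `alpha = 0`).
* Degenerate discretization inputs collapse to a single all-covering
  state; constant series are handled, empty series rejected.
* Problem sizes in tests and the acceptance script follow the default
  study conditions (12,405 trap nights, ~3,350 capture cases); the full
  38-model suite fits and evaluates in a few seconds.

## Known limitations

* No general DAG search, no continuous-node inference, no EM for missing
  data — the naive/TAN family with available-case counting is the scope.
* Netica-style auto-discretization is unspecified upstream; exact bin
  edges of the original analysis are unrecoverable, so complexity counts
  (not bin edges) are the comparable quantities.
* The nine-state response includes the genus-level `RE` record as its own
  state; with 3 such cases its CPT rows lean heavily on the prior.
* Bonferroni is the only multiplicity correction offered, by design.
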