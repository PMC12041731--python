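# Methods

## Model

`twinnet` estimates and compares Gaussian graphical models (GGMs).  For
p variables with joint covariance Σ, the GGM is the undirected network
whose edge weights are partial correlations

    w_ij = -θ_ij / sqrt(θ_ii θ_jj),     Θ = Σ⁻¹,

so w_ij = 0 exactly when variables i and j are conditionally independent
given all others.  Sparse estimation maximizes the ℓ1-penalized
log-likelihood

    log det Θ − tr(S Θ) − λ Σ_{i≠j} |θ_ij|

over positive-definite Θ (graphical lasso), with S the sample
correlation matrix of the preprocessed data and the diagonal left
unpenalized.  The solver is a blockwise coordinate-descent of the
Friedman type: each column's subproblem is a lasso solved by coordinate
descent with an incrementally maintained residual cache and active-set
sweeps, with convergence declared when no working-covariance entry moves
more than 1e-8 between sweeps.  Solutions satisfy the stationarity (KKT)
conditions to machine precision; the test suite certifies them against an
independent ADMM solver of the same objective.

### Penalty selection

A log-spaced grid of `n_lambdas = 100` penalties runs from λ_max (the
smallest penalty that empties the graph, i.e. the largest absolute
off-diagonal correlation) down to `lambda_min_ratio = 0.01` times λ_max,
fitted with warm starts.  The selected model minimizes the Extended
Bayesian Information Criterion

    EBIC(λ) = −2 ll(λ) + E(λ) log n + 4 γ E(λ) log p,

with ll = (n/2)(log det Θ − tr(S Θ)) (the additive normal constant is
irrelevant to selection), E the number of nonzero upper-triangle entries
(hard-thresholded at 1e-10 to remove numerical dust), and γ = 0.5 by
default, the conservative setting that suppresses spurious edges.  Exact
EBIC ties break toward the larger penalty (sparser model).

### Edge thresholding

Because EBIC is evaluated on the *penalized* likelihood, large samples
push selection toward small penalties, where a few spurious edges of tiny
magnitude (|w| ≈ 0.01–0.02 at n = 2000) survive.  As the final-model
cleanup the package therefore zeroes edges with

    |w_ij| < log(p(p−1)/2) / sqrt(n),

the consistency bound behind qgraph's `threshold` option.  This is on by
default (`edge_threshold=True`) for network estimation and the bootstrap
diagnostics; with it, chain-graph recovery at n = 2000 achieves perfect
sensitivity with essentially zero false edges.  Raw path fits are kept
un-thresholded so their KKT conditions remain checkable.  The network
comparison test is the exception: it compares *un-thresholded* networks
(see below), because thresholding makes the max-difference statistic
jumpy — an edge near the bound lands at either 0 or ~0.17 — which
measurably distorts the mid-range of its permutation p-value
distribution.

## Preprocessing

GGMs assume roughly normal margins.  To alter the data as little as
possible, only columns whose unadjusted Fisher–Pearson skewness
g1 = m3/m2^{3/2} exceeds 1.0 in absolute value are transformed; the rest
are merely standardized.  The transform is the Winsorized-ECDF
nonparanormal map: Φ⁻¹ of the empirical CDF truncated at
δ_n = 1/(4 n^{1/4} sqrt(π log n)), restandardized to mean 0 and unit
sample variance.  It depends on ranks only (monotone, idempotent, ties
share a value; the truncation ties the few most extreme ranks).  The
inverse normal CDF is computed by Acklam's rational approximation with
one Halley refinement (agrees with scipy's `ndtri` to ~1e-9 or better);
having it inside the compiled kernels lets permutation loops re-run the
full preprocessing per re-estimation.  Transformation is applied within
each analysis group whose network is being estimated, not on pooled
samples, because networks are estimated per group.  Missing data are
handled by complete-case deletion by default; a pairwise-complete mode
(`missing="pairwise"`) transforms each column on its observed entries
and feeds pairwise-complete correlations to estimation with the median
pairwise n in the EBIC, logged loudly since such a matrix need not be
positive semidefinite.  Constant columns are an error; n < p produces a
warning but estimation proceeds thanks to regularization.

## Centrality and stability

Node strength is Σ_j |w_ij|; one-step expected influence is the signed
sum Σ_j w_ij; global strength is Σ_{i<j} |w_ij|.  z-scores standardize
centralities across the nodes of one network using the sample SD (n−1).

The case-dropping bootstrap re-estimates the network on subsamples with a
proportion q of cases removed, q ∈ {0.05, …, 0.75}, and correlates
subsample with full-sample centralities (Pearson, on the chosen
centrality).  The CS coefficient is the largest q at which at least 95%
of subsample correlations stay ≥ 0.7; 0.75 is the grid cap, which is why
saturated analyses report exactly 0.75.  Values above 0.25 are
conventionally read as stable, above 0.5 as preferable.  Subsample
networks with constant centrality vectors (e.g. empty graphs) count as
correlation 0.  Edge accuracy uses the nonparametric case-resampling
bootstrap with percentile intervals; bootstrapped difference tests call a
pair of edges (or nodes) different when the percentile interval of their
bootstrap difference excludes 0.  Every resample re-runs the full
pipeline including EBIC selection.  `B = 1000` by default; the test suite
runs B = 100–200.

## Network comparison test

Two groups are compared through S (absolute difference of global
strengths) and M (maximum absolute edge difference), computed on
un-thresholded EBIC networks (the canonical convention; with
thresholding, the M test's null p-values are anticonservative in the
mid-range even though its 5% rejection rate stays near nominal).  The
null distribution reassigns the pooled individuals at random to groups
of the original sizes and re-estimates both networks from scratch —
preprocessing included — for every permutation (1000 by default).
P-values use the add-one convention (b+1)/(K+1), so they are never 0 and
ties count against rejection.  Per-edge invariance tests reuse the same
permutation draws; both raw and Holm-corrected p-values are reported.
Pooled rows are sorted lexicographically before permuting, which makes
results invariant to the order in which the two groups are supplied.
Permutations whose re-estimation fails are dropped (counted, capped at
5%).

When the two groups contain both members of twin pairs, individual-level
permutation breaks the within-pair dependence and is mildly
anticonservative; the `pair_ids` argument switches to pair-blocked
permutations that reassign whole pairs.  The standalone `nct()` defaults
to individual permutation (the canonical test); the study orchestration
defaults to pair-blocked at levels 2–3, where pooled co-twin samples make
it the statistically safer choice.

A caveat worth knowing: when the two groups have *different* within-pair
correlations (MZ vs DZ), their effective sample sizes differ, so the two
estimated networks carry different shrinkage bias, and no permutation
scheme can equalize that.  At a few hundred individuals per group this
inflates the per-test rejection rate to roughly 6–12%; the inflation
shrinks as samples grow.  This motivates the family-wise gating below.

## Three-level twin design

Level 1 compares co-twins within each gender × zygosity stratum.  Because
"twin 1 / twin 2" labels are arbitrary, the stratum is reassigned
`n_reassignments = 1000` times: each iteration splits every pair by a
fair coin into datasets A and B, runs the NCT between them, and
accumulates both estimated networks into elementwise running means (the
averaged co-twin networks, zeros included).  The p-value distributions
are summarized by their minimum, 5th percentile, and the fraction below
α; a stratum is flagged when that fraction exceeds
α + 2·sqrt(α(1−α)/R).  Note that the per-iteration tests are
conservative whenever co-twins are correlated — the two datasets
partition the same pairs, so they differ less than the permutation null
assumes — and that iterations share the dataset, so the fraction is more
variable across datasets than a binomial would suggest; the flag is a
screening device, not an exact test.

Level 2 pools both co-twins and compares MZ with DZ individuals within
each gender; level 3 pools zygosity and compares women with men, with
per-edge tests optionally restricted to edges incident to chosen nodes
(e.g. the depressive symptoms).  Each pooling gate is one decision
informed by several index tests (2 genders × {S, M} at level 2; {S, M}
at level 3), so the gates control the family-wise error at α by
Bonferroni: level 2 is "no zygosity difference" when all four p-values
are ≥ α/4, level 3 is "significant" when min(p_S, p_M) < α/2.  Gates are
advisory: all levels always run, and violated gates are flagged in the
report rather than stopping the pipeline.  A single seed drives separate
substreams per stage, so a full study is byte-reproducible.

## Synthetic twin cohorts

The generator draws each pair from a 2p-dimensional Gaussian with
within-twin covariance Σ_g = Θ_g⁻¹ (gender-specific ground-truth
precision) and cross-twin covariance ρ_z Σ_g, the equicorrelated
ACE-style simplification with ρ_MZ = h² + c² and ρ_DZ = h²/2 + c²
(defaults h² = 0.6, c² = 0.2, hence ρ_MZ = 0.8, ρ_DZ = 0.5).  Chain-graph
precisions (unit diagonal, constant off-diagonal on the first band)
provide a known sparse truth whose edge partial correlations equal the
chosen weight; a boost factor strengthens every edge uniformly, giving
the "denser women's network" condition (default boost 1.8, i.e. 0.45 vs
0.25).  Designated columns pass through the monotone map
x ↦ exp(x/(1.5·sd(x))), restandardized by exact lognormal moments, which
yields marginal skewness ≈ 2.7 — safely beyond the screening threshold —
while staying invertible by the rank-based transform.  Default stratum
sizes mirror a realistic like-sex middle-aged twin cohort at quarter
scale (115/140/91/123 pairs for MZ-F/DZ-F/MZ-M/DZ-M).  The 39-variable
default registry covers 9 depressive symptoms, 6 cognitive scores, 8
intellectual, 6 physical, and 8 social activity frequencies plus age and
alcohol consumption as covariate nodes; ordinal frequency items are
emulated as continuous (a quantile-binning utility exists as a stress
test), covariates enter as nodes (residualization is not performed).

What the generator does *not* emulate: real item distributions (bounded
ordinal scales, floor effects), missingness, response biases, per-variable
heritabilities, or assortative mating.  Passing tests therefore show that
the estimators and tests behave correctly under a controlled
Gaussian-copula twin structure, not that any substantive conclusion about
real cohorts follows.

## Simulation sizes used by the test suite

The statistical tests run at desk scale: solver equivalence on 20 random
instances (p ≤ 6); selection consistency on 100 replicates of a 10-node
chain at n = 2000; NCT calibration on 500 null replicates (p = 8, 400 per
group, 200 permutations) and power on 200 boosted replicates (500 per
group); CS behavior at n up to 10,000 with B = 100–200; reassignment
validity at R = 100 with 100 inner permutations over 3 independent
strata; and the full three-level decision pattern over 50 replicates of a
half-scale cohort (10 nodes, strata 230/280/182/246 pairs, women's boost
1.4 — edge differences of ~0.1, matching the between-group edge contrasts
the design is meant to detect — with 12 reassignments × 25 inner
permutations and 100 permutations at levels 2–3).  `scripts/acceptance.py`
runs one such study at R = 50, inner K = 50, K = 200, B = 200.

## Known limitations

* GGMs are undirected and cross-sectional; no causal or longitudinal
  claims follow from an estimated network.
* The NCT's validity degrades when groups differ in within-pair
  dependence (see above); interpret level-2 p-values near α with care.
* The equicorrelated cross-twin structure shares one ρ across variables;
  per-variable heritabilities would need a structured cross-covariance.
* The CS coefficient is capped at 0.75 by its drop grid.
* Pair-blocked permutation requires complete pairs and even group sizes.
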