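# Methods

This note documents the statistical procedures implemented in
`symptomnet`, the choices made where the design was genuinely open, and
what the synthetic-data experiments do and do not demonstrate.

## Data model and inclusion rule

A dataset is a subjects × items integer matrix bound to an item schema
(scale membership, level range, sex-specificity). The bundled schema
describes three instruments: 32 PRISE-M side-effect items on 0–2, 10
MADRS depression items on 0–6, and 11 YMRS mania items (seven on 0–4;
irritability, speech, thought content and disruptive–aggressive behavior
on 0–8). Restricting to one sex drops the inapplicable sex-specific
PRISE-M item (irregular periods for males, erectile dysfunction for
females), leaving the 52-item analysis frame with 52·51/2 = 1326
possible edges.

Euthymia is operationalized by inclusive caps on the scale totals,
MADRS ≤ 10 and YMRS ≤ 12 by default; both thresholds are arguments so
more conservative sensitivity cutoffs can be run. Subjects with any
missing item in the analysis set are excluded listwise. Missing cells in
CSV input are empty strings or `NA`.

Scale descriptives: totals are plain row sums; correlations between
totals use Spearman rank correlation with average ranks for ties (the
natural convention for heavily tied ordinal scores; a zero-variance
total yields an undefined (NaN) entry rather than 0). Internal
consistency is McDonald's ω-total, \((\Sigma\lambda)^2 /
((\Sigma\lambda)^2 + \Sigma\psi)\), with loadings and uniquenesses from a
one-factor maximum-likelihood fit of the Pearson covariance. The ML fit
profiles the likelihood over uniquenesses (for fixed ψ the optimal
loading direction is the leading eigenvector of ψ^{-1/2} S ψ^{-1/2}) and
minimizes the remaining-eigenvalue discrepancy over log ψ with bounded
L-BFGS; bounds act as a Heywood-case guard. The ω estimator variant is
not uniquely dictated by common usage; ω-total with a single ML factor is
the default reading and is verified against the closed form on parallel
items.

## Network estimation

Each node is regressed on the remaining 51 items by an ℓ1-penalized
Poisson regression. All items are treated as counts under the log link,
including the ordinal mood items — the estimator's exponential-family
form is what makes a single node-conditional family workable across the
mixed 3/5/7/9-level ranges. Predictors are centered and scaled to unit
variance; the outcome stays on its count scale, so edge weights are
signed Poisson regression weights on standardized data.

The solver is proximal-gradient (FISTA) with backtracking line search,
momentum restarts on objective increase, and warm starts along a
50-point log-spaced λ path from λ_max (the smallest λ with an empty
model, computed in closed form from the gradient at the null fit) down to
0.01·λ_max. The path solutions were verified against R `glmnet`
(`family="poisson"`, identical path, `standardize=FALSE`) to ~3e-7.

Model selection per node uses the extended BIC with γ = 0.25,
df = number of nonzero coefficients, and p−1 candidate predictors. By
default selection is *relaxed*: each support visited by the path is
refit by unpenalized ML (damped Newton, warm-started) and the EBIC is
computed from the refit likelihood, with the refit coefficients
reported. Scoring the shrunken penalized fit itself (available via
`refit=False`) systematically favors near-empty models because shrinkage
absorbs most of a weak predictor's likelihood gain; in simulations at
the 52-node design point it cut edge-detection sensitivity roughly
threefold with no measurable specificity benefit. EBIC ties resolve
toward the larger λ (parsimony).

Nodewise fits combine symmetrically: the AND rule (default) keeps edge
(i,j) only when both directed coefficients are nonzero and weighs the
edge by their mean; the OR rule keeps an edge when either is nonzero
(mean over the nonzero ones). The AND rule is the conservative standard
for nodewise mixed-graph estimation; the combination rule and λ grid are
package choices, not uniquely determined by common practice.

Predictability is the proportion of variance of a node explained by its
selected neighbors: an unpenalized Poisson refit on the neighbor set,
R² = 1 − SS_res/SS_tot on the count scale, floored at 0, with 0 by
convention for isolated nodes; bands are high (R² > 0.5), moderate
(0.15 < R² ≤ 0.5), low otherwise. Because the network is undirected,
predictability is an upper bound on what intervening on neighbors could
achieve. Topological overlap
TO(i,j) = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j) + 1 − a_ij) on absolute
weights flags near-redundant item pairs; no consensus threshold exists,
so pairs above a configurable warning level (default 0.9) are reported,
never merged.

## Resampling diagnostics

Edge accuracy: nonparametric bootstrap over subjects (default B = 1000),
percentile 95% CIs per node pair, significance = CI excluding zero.
Replicates whose resample leaves an item constant are dropped and
logged; the effective B is reported. Percentile intervals are the
simplest defensible default; BCa is out of scope.

Centrality stability: case-dropping subset bootstrap over a 15-point
grid of drop fractions from 0.05 to 0.75. The default budget of 2500
subsamples is split evenly across the grid. At each fraction the network
is re-estimated on the retained subjects with the same configuration and
each centrality vector's Spearman correlation with the full-sample
vector is recorded; a degenerate (constant) centrality vector counts as
a failed replicate. The CS coefficient per index is the largest grid
fraction at which ≥ 95% of subsamples correlate ≥ 0.7; CS > 0.5 reads as
high stability, 0.25–0.5 moderate.

Centrality conventions: strength sums absolute incident weights;
closeness and betweenness are shortest-path indices with edge distance
1/|w| by default (the field convention) and an unweighted hop mode also
provided, since the verbal definition of closeness as "inverse number of
edges on shortest paths" is hop-based. Unreachable pairs are excluded
from the closeness sum (a node reaching nothing has closeness 0), and
the count of reachable nodes is available alongside; symptom networks
routinely contain isolated single-node clusters, so some convention is
unavoidable. Both modes are exercised against brute-force path
enumeration in the tests.

## Community detection and node roles

Clusters are found by smart local moving (SLM) on absolute weights:
local moving of single nodes to neighboring communities (plus one empty
candidate community), then splitting each community by local moving on
its own subnetwork, aggregation of the subcommunities into a reduced
network initialized by the parent communities, and recursion on the
reduced network. One outer iteration is the default — adequate for
networks under ~100 nodes — with additional iterations re-randomizing
the splits (useful on sparse graphs where a single pass can lodge in a
local optimum). The best of 20 random restarts is returned; equal-Q ties
resolve to the lexicographically smallest canonical labeling, and
cluster labels are ranked by descending size. On all tested graphs with
≤ 8 nodes the partition matches the exhaustive-search modularity
maximum; on random 20-node graphs it is never worse than networkx's
greedy agglomerative baseline.

Modularity is Q = Σ_c (e_c/m − (d_c/2m)²), with a resolution parameter
exposed (default 1). Cluster quality additionally reports per-cluster
conductance cut(c)/min(vol(c), vol(rest)) and coverage (intra-cluster
weight over total weight). The single network-level conductance figure is
the volume-weighted mean over clusters of size ≥ 2 — singleton clusters
have no internal structure and would degenerate the metric — with the
per-cluster values always reported alongside, since no unique aggregation
is standard.

A node's strength splits exactly into bridge strength (absolute weight on
inter-cluster edges) and stabilizing index (absolute weight within its
cluster); this identity is enforced by construction and tested. Bridge
nodes are the top-5 by bridge strength, extending through any ties at the
cut, and zero-bridge-strength nodes are never flagged (isolated clusters
have no bridge nodes). Each cluster's stabilizing node is the argmax of
the stabilizing index, with exact ties reported jointly and none for
singletons.

## Synthetic data

Ground-truth networks place round(density·p(p−1)/2) edges uniformly at
random with i.i.d. weights uniform on (low, high]; the default study
condition is p = 52, density 0.08 (106 edges), weights in (0, 0.3]. All
weights are nonnegative, matching the all-positive estimated networks
this model family produces on residual-symptom data.

Two samplers generate item data from a truth network:

- **Gaussian copula** (default): latent z ~ N(0, Σ) with precision
  Ω = I − cW, c = min(1, largest value keeping Ω positive definite). For
  every network in the default condition the spectral radius of W is
  well below 1, so c = 1 and the latent partial correlations *equal* the
  true weights; only denser or heavier networks are shrunk. (Requiring
  diagonal dominance instead would force c ≈ 0.7 even when I − W is
  already positive definite, silently attenuating every dependence a
  third below the stated condition.) Margins are discretized into each
  item's level range with probabilities proportional to 0.45^level — a
  right-skewed profile mimicking how rare most residual symptoms are —
  via Gaussian quantile thresholds.
- **Pairwise count model**: single-chain Gibbs sampler with node
  conditionals Poisson(exp(α_j + Σ_k w_jk x_k)) truncated to the item's
  range (default burn-in 500 sweeps, thinning 2). Intercepts α_j are
  solved so the null truncated-Poisson mean is 0.3, matching the skew of
  the copula margins; a rate cap aborts with a rescale hint if the
  positive feedback diverges.

An optional truncation mode applies the euthymia filter to sampled
batches and resamples until n subjects qualify, emulating the
restriction-of-range the inclusion rule induces.

What the generator does *not* emulate: item-specific marginal
frequencies fit to a real cohort, treatment covariates, informative
missingness, or rater effects. Passing tests therefore demonstrate that
the pipeline recovers known conditional-dependence structure from
discrete, right-skewed data of realistic size — not that any specific
clinical dataset would yield the published structures.

## Power analysis

"Power" is operationalized as edge-detection sensitivity: per replicate,
draw a truth network, sample a dataset at the candidate n, re-estimate,
and score sensitivity (true edges recovered / true edges) and
specificity. The headline figure is the across-replicate probability
that sensitivity exceeds a threshold (default 0.5); the acceptance
script reports the sensitivity level exceeded by 80% of replicates (the
20th percentile). Replicates with a zero-edge truth report sensitivity
as undefined, never 0/0-coerced. The copula sampler is the default for
power runs (no burn-in); the count-model sampler brackets the result
from the side of exact model match.

At the 52-node design point (density 0.08, weights (0, 0.3], n = 634,
γ = 0.25, AND rule) the measured 20th-percentile sensitivity is ≈ 0.42
and the probability of exceeding 0.5 is well under 0.8. The shortfall is
attributable to discretization: collapsing the latent Gaussian onto
skewed 3-level (and coarser) margins attenuates observable dependence by
roughly 30%, so the effective design point behaves like weights
uniform on ≈ (0, 0.21]. A power calculation that treats the weights as
directly observable continuous dependencies — ignoring the discreteness
of the items — arrives at > 50% sensitivity at this n, but under the
generative conditions implemented here that level is not met. The
package reports the measured value rather than adjusting margins,
thresholds, or selection constants to meet it.

Default replicate counts (10 networks × 1 dataset in the test suite, 20
in the acceptance script) keep a full run in the minutes range on one
CPU; all replicate seeds derive from the single run seed and are logged
in the result table.

## Numerical details

- FISTA: η clipped at ±30 before exponentiation; convergence when the
  max coefficient change falls below 1e-6 (relative); non-converged path
  points are flagged with a warning, never silently dropped.
- Newton refits: damped steps with a tiny (1e-9) Hessian ridge; on
  failure (separation) the penalized fit is kept for that support.
- Zero-variance predictors are dropped with a warning; a zero-variance
  *target* is an estimation error naming the offending items.
- Adjacency symmetry is enforced to 1e-12 and the diagonal forced to 0.
- Pipeline TSVs use 6 significant digits; the adjacency CSV keeps full
  precision so node statistics can be recomputed losslessly from it.
- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; bootstrap, stability, clustering restarts
  and the two samplers each consume independent draws from the run seed.

## Known limitations

- The Poisson conditional treats ordinal severity scores as counts; for
  heavily truncated items the conditional model is misspecified, which
  is precisely why recovered-weight scales are only comparable within an
  estimation configuration.
- Percentile bootstrap CIs undercover slightly for sparse-selected
  weights near zero.
- Bridge-node selection reliability is not itself resampled; consensus
  clustering across bootstrap replicates is out of scope.
- The SLM heuristic guarantees no global optimum on large graphs;
  restarts and iterations trade time for quality.
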