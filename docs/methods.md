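# Methods

## Model

The data model is a recursive linear structural-causal model over p
continuous variables: a DAG G together with, for each node X_i,

    X_i = β₀ + Σ_{X_j ∈ Pa_G(X_i)} β_j X_j + ε_i,   ε_i ~ N(0, σ_i²),

with mutually independent errors. Under this model the log-likelihood of a
node's equation, profiled over β and σ², depends on the data only through
the residual sum of squares, which yields the local score

    BIC(X_i, Pa(X_i)) = −(n/2)[ln(2π) + 1 + ln(RSS/n)] − ((k+2)/2)·ln(n).

The penalty counts k slope parameters plus the intercept and the residual
variance, hence k+2. The graph score is the sum of local scores
(decomposability), so evaluating a single-edge move requires refitting at
most two node equations — the target for an addition/removal, both
endpoints for a reversal.

Two conventions the formula leaves open are fixed as follows and recorded
in output metadata:

- **Standardization divisor**: sample standard deviation (n−1). On
  standardized data a parent-free node then has RSS = n−1 exactly.
- **RSS floor**: the score diverges as RSS → 0 (a perfectly collinear
  child). RSS is floored at 1e-10·n before the logarithm, with a logged
  warning; this keeps every score finite without affecting any
  non-degenerate fit.
- The intercept is always fitted even though it is ≈0 on standardized
  data, matching the node equation as written.

## Search

Hill climbing starts from the empty graph and at each iteration applies
the single legal move with the largest score gain, stopping when no move
improves the score by more than 1e-9 (a float-roundoff guard; "strict
improvement" is meaningless below that). Determinism is a contract:
candidate moves are enumerated in a fixed order (additions, then removals,
then reversals, each lexicographic by edge) and ties in the gain go to the
first move in that order, so identical data and config give identical
graphs edge for edge. The iteration cap defaults to 3p² accepted moves —
comfortably above the number of useful moves for a DAG on p nodes — and
hitting it returns the best-so-far graph flagged `converged=False`. Random
restarts and tabu lists are deliberately absent: the procedure validated
here is plain greedy ascent, and its failure mode (stalling in a local
optimum) is measured rather than hidden — on three-node chains the
search reaches the exhaustive-enumeration optimum in ≥90% of simulated
cohorts, and the local-optimum certificate (no legal move improves the
score) holds in 100%.

Blacklist semantics: a reversal whose resulting edge is forbidden is
itself illegal, since a reversal is a removal plus an addition and the
addition would be illegal. Edges into the exogenous score are legal by
design; in cohorts where parents transmit both genes and environment, a
behavioural-factor → child-score edge is an expected non-causal
association, and forbidding it would force the dependence into a worse
place.

## Effect quantification

Given a learned graph, each node is fit by OLS on its parents. For a
recursive system with independent errors this per-equation least squares
coincides with full-information maximum likelihood, so no covariance-
structure machinery is needed for the point estimates. Coefficient
standard errors use σ̂² = RSS/(n−k−1) and p-values the t distribution with
n−k−1 df (a large-sample z would differ negligibly at cohort n).

Total effects are computed twice and cross-checked to 1e-9: as sums over
all directed simple paths of edge-coefficient products (exact — a DAG has
finitely many; no length cutoff) and as entries of (I−B)⁻¹. Both the
per-path list and the totals are reported, since "indirect effect" is
sometimes wanted path-by-path and sometimes as the lump sum. Effects are
reported on the standardized scale only.

## Aggregation and selection

Redundant questionnaire scales are collapsed before search because
near-duplicate nodes make edge orientation unstable. Average-linkage
hierarchical clustering on distance 1−r (signed by default — the intended
inputs are positively oriented T-scores; a flag switches to 1−|r|) is cut
at distance 1−r_threshold; each multi-member cluster is replaced by scores
on the first principal component of its members' correlation matrix, with
the eigenvector sign fixed so the largest-|loading| member loads
positively. The default r_threshold of 0.7 is prominent in the config
because learned structures are known to be sensitive to it; a sweep plus
`compare` quantifies that sensitivity. Factor scores are re-standardized
before search.

Predictor selection is a two-stage cascade: cross-validated L1 regression
keeps variables with |coefficient| > 0.03; variables the penalty dropped
are re-admitted when the full multivariate OLS gives them p < 0.05 *and*
an LMG relative-importance share > 0.01 — the L1 stage alone can discard a
true cause that is highly correlated with a stronger predictor. LMG shares
(the average R² increment over all predictor entry orderings) are computed
exactly via the subset-weighting identity up to 10 predictors and by
seeded Monte-Carlo over orderings beyond; shares are nonnegative and sum
to the full-model R².

## Bootstrap and comparison

Edge stability: B (default 100) row-resamples of size n with replacement,
each re-standardized and re-fit end to end (search + path model). Per
directed edge: appearance frequency and the 2.5th/97.5th percentiles of
its coefficient across replicates. Edges with frequency ≥ 0.40 are
reported, plus every original-graph edge regardless (flagged); an original
edge is "consistent" when its full-data coefficient lies inside its
bootstrap interval. Two conventions exist for the interval when an edge is
absent from some replicates — pool only present-replicates (default) or
count absences as zero coefficients — and both are implemented, since
neither is canonical. Replicate RNG streams are spawned per replicate from
the master seed, so replicate i is unchanged when B grows. Re-standardizing
each resample keeps the score's unit-variance assumption; resampled columns
otherwise have sd ≠ 1. In full-pipeline mode the aggregation step is also
refit inside each replicate (factor definitions then vary per replicate);
the default holds factor definitions fixed, which isolates structure
uncertainty from clustering uncertainty.

Graph comparison is exact edge-set arithmetic: Jaccard overlap
|shared|/|union| over directed edges plus the two directional containment
percentages.

## Synthetic cohorts

The generator draws nodes in topological order from the linear-Gaussian
model. Noise standard deviations are solved analytically (walking the
implied covariance matrix) so every node has unit marginal variance before
standardization, keeping edge coefficients directly interpretable as
standardized effects. Collinear "raw scale" blocks are generated as
sqrt(r)·base + sqrt(1−r)·noise, giving any two members exact population
correlation r.

The cohort preset emulates the variable architecture of a parental-
behaviour / polygenic-score / child-outcome study: three substance-use
roots, two behavioural-issue nodes each a collider of two substance nodes
(the collider is what makes those directions identifiable from
observational data), an exogenous score with one weak (0.05) incoming edge
standing in for shared parental genetics — giving it the ~0.05 correlation
with behavioural predictors seen in real cohorts — and the outcome fed by
alcohol use (direct 0.30; total 0.4985), both behavioural nodes (0.25,
0.20) and the score (0.12). Two collinear blocks (r = 0.85, 0.90) ride on
the behavioural nodes. The generating truth (graph, B, (I−B)⁻¹) is
serialized with every draw so recovery tests never re-derive it.

What the generator does *not* emulate — and hence what passing tests do
not establish about real cohorts: non-Gaussian and heteroscedastic noise,
nonlinear or interactive effects, latent confounding beyond the one
genetics-proxy edge, measurement error structure beyond exchangeable
noise, missing-data mechanisms (the pipeline only does listwise deletion),
and selection effects. Structure-recovery rates on the preset are
best-case figures for a correctly specified linear model.

## Problem sizes and validation

The validation suite measures, at desk scale: score-formula agreement with
an independently coded evaluation (500–1000 random cases, ≤1e-9); delta
scoring versus full rescoring over random 6-node graphs and all their legal
moves (≤1e-9); exhaustive-search agreement over 100 three-node cohorts at
n=2000 (≥90% optimum matches, 100% certificates); effect totals versus
(I−B)⁻¹ over random 8-node models (≤1e-9); preset recovery over 20 seeds at
n=5000 (all coefficients within 3 SE; ≥90% of edges direction-correct
under blacklists); bootstrap behaviour with a planted β=0.7 edge at n=1000,
B=100 (frequency ≥0.95) and on null data at the cohort scale n=10000
(edge-free in ≥18/20 macro-seeds — note that chance correlations of order
sqrt(ln n / n) do clear the BIC penalty occasionally at any n, and when
they do they are bootstrap-stable, so a null run is not guaranteed clean);
and the aggregation closed forms ((1+r)/2 for a two-variable PC1, the p=2
LMG identity, exact share-sum to R²).

## Known limitations

- Greedy search returns one DAG from what is generally a Markov
  equivalence class; edge directions not pinned by colliders or
  blacklists are tie-break artifacts and should be read alongside the
  bootstrap reversal frequencies.
- The BIC is correct only for linear-Gaussian equations; heavy tails or
  nonlinearity bias both structure and effects.
- Bootstrap intervals are percentile intervals without bias correction.
- LMG beyond 10 predictors is a Monte-Carlo estimate (seeded, 2000
  orderings by default).
- The pipeline assumes complete rows after listwise deletion; no
  imputation is provided.
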