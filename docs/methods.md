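# Methods

This note documents the models implemented in `riskevo`, the conventions
and numerical choices behind them, what the synthetic generators do and do
not emulate, and the package's known limitations.

## State coding

IUCN categories are mapped to an ordered integer scale: EN 1, VU 2, NT 3,
LC 4. Data-deficient (DD) and unrecorded (NE) species are never coded;
they are moved to an exclusion log with a machine-readable reason, as are
species absent from the tree after underscore/space and case
normalization. No fuzzy name matching is attempted: a silently wrong
taxonomic match is worse than a logged drop.

The integer codes are used in two deliberately different ways. The
disparity analysis treats them as points on an ordered scale (differences
are meaningful); the Markov model treats them as unordered labels. This is
coherent because the equal-rates model is symmetric under any permutation
of the state alphabet, so ordering information would be ignored anyway.

## Disparity through time

Disparity of a set of tip values is the mean pairwise distance: squared
differences by default (`avg_sq`, the convention of the DTT literature),
absolute differences as an option. For a lineage with one tip the
disparity is 0.

The curve is evaluated at the relative times of the internal nodes
(root = 0, present = 1), sorted ascending. The value at time *t* is the
mean, over all lineages crossing the instant just *before* the splitting
event at *t*, of the disparity of the tips descending from each lineage,
divided by the whole-clade disparity. At the root time the only such
lineage is the clade itself, so the curve starts at exactly 1. Evaluating
just before rather than just after each split is what makes the two
standard small-tree cases come out right: on a balanced 4-tip tree with
cherry states (1,1) and (4,4) the post-root value is 0, and with states
(1,4) and (1,4) it is (9 + 9)/2 ÷ 6 = 1.5.

Two nulls are provided. `bm_sim` (default) fits a Brownian rate to the
observed states by maximum likelihood — using the standard phylogenetic
GLS estimate with the shared-depth covariance matrix and an estimated
ancestral mean — then simulates continuous tip datasets and computes each
one's DTT curve; this is the null of the comparative literature the DTT
method comes from. `tip_shuffle` permutes the observed states across tips,
holding both the tree and the state multiset fixed. Pointwise quantiles
(2.5% and 97.5% by default) form the envelope; the per-time classification
calls `conservatism` where the observed curve exceeds the upper quantile
and `overdispersion` below the lower one, following the interpretation
convention of the source analysis, and the MDI-style summary is the mean
observed-minus-null-median difference.

Note one caveat of that convention: states that are perfectly clustered
within subclades produce *low* observed disparity late in the tree, which
the above-upper rule does not flag. The rule detects departure above the
null, which for a Brownian null means the states are less tree-structured
than a drifting continuous trait — the pattern actually observed in the
motivating dataset.

## Equal-rates Markov models

The 4-state ER chain has generator off-diagonals q and closed-form
transition matrix P_ii = 1/k + (1 − 1/k)e^(−kqt), P_ij = (1 − e^(−kqt))/k.
Likelihoods use Felsenstein pruning with per-node rescaling against
underflow; polytomies are supported (the consensus step can produce
them). The root prior is uniform over the four states — identical to the
ER stationary distribution and the only self-consistent default; tips may
be declared ambiguous (all-ones partial). A zero likelihood (e.g. q = 0
with discordant tips) is reported as −inf and excluded from optimization
trajectories.

Time-dependence is implemented by exact integration of the rate
trajectory into effective branch lengths on relative time (trees are
rescaled to unit depth for fitting, so all rates are per unit relative
time):

* **null**: effective length = raw length.
* **delta**: node depths d are raised to d^δ and branch lengths
  re-derived; δ = 1 is the identity, δ > 1 concentrates apparent change
  toward the present. Total depth is preserved.
* **linear**: r(t) = q + s·t, effective length over [t0, t1] is
  (t1 − t0) + (s/q)(t1² − t0²)/2; feasibility r(t) ≥ 1e−8 on [0, 1] is
  enforced in both the spec validator and the optimizer.
* **two-rate**: rate q before breakpoint B, rate E after; branches
  spanning B are split exactly at B. E is an absolute rate by default
  (a multiplier interpretation is available as a flag).

At δ = 1, s = 0 or E = q each transform reduces to the identity, so all
three nested models reproduce the constant-rate likelihood exactly — a
property the test suite asserts to 1e−8.

### Fitting

Positive parameters are optimized on the log scale. The constant-rate
model uses bounded scalar minimization of −logL over log q on
[log 1e−6, log 1e3]. Delta and linear use Nelder-Mead from 5 seeded
starts anchored at the null-model optimum (Nelder-Mead because the
feasibility penalty makes the surface locally non-smooth). The two-rate
likelihood is only piecewise smooth in B, so B is profiled on a 101-point
grid over [0, 1] with (log q, log E) optimized at each point, warm-started
from the previous grid point, followed by bounded scalar refinement of B
between the best point's neighbours; a boundary-pinned B is flagged in
the diagnostics. If a nested model's optimum falls below the null optimum
(a numerical artifact), the null solution is returned for it, preserving
the nesting inequality.

### AIC

The default convention counts only parameters beyond the baseline rate:
AIC = −2 logL + 2 k_extra with k_extra = 0 (null), 1 (delta, linear),
2 (two-rate). This is the convention under which the published comparison
for the motivating dataset is internally consistent (the constant-rate row
satisfies AIC = −2 logL exactly). Because it is nonstandard, the
all-parameters convention (k_extra + 1) is available via
`FitOptions(aic_convention="standard")`. The model table reports ΔAIC
from the minimum and flags when the runner-up is within 2 units, in which
case the models should be treated as indistinguishable and the simpler
one preferred.

## Trees

Newick and Nexus parsing (including translate tables) is delegated to
dendropy; the in-memory representation is a small array-backed rooted
tree. Majority-rule consensus operates on rooted clades: a clade is kept
iff its frequency strictly exceeds 50% (at-or-above for higher
thresholds), which guarantees pairwise compatibility, and each kept
edge's length is the arithmetic mean of the subtending edge length over
exactly the trees containing that clade. Consensus of n copies of one
tree is therefore that tree, branch lengths included.

Penalized-likelihood dating jointly optimizes node ages and per-edge
rates to minimize Σ_e (b_e − r_e t_e)² + λ Σ (r_parent − r_child)², a
Gaussian approximation to the rate likelihood with a smoothness penalty
on parent-child edge pairs. Ages are parameterized as fractions of the
parent age (root fixed at `root_age`, default 1; tips at 0), so the
age-ordering constraint holds by construction, and rates are optimized on
the log scale with L-BFGS-B. λ defaults to 1.0 and is exposed in the
config; no cross-validation is performed. The output is ultrametric by
construction and verified against the configured tolerance.

## Synthetic data

The generators produce data with exactly the statistical structure the
analysis assumes, so every stage is testable without downloads:

* `simulate_yule` — pure-birth trees, depth rescaled to 1, seeded.
  Realized branch lengths are exact exponential waiting times, so
  ultrametricity is exact, not approximate.
* `simulate_mk` — ER states evolved down the (transform-adjusted) tree
  with the closed-form transition probabilities; the forward model of the
  fitted likelihood, which makes simulate-then-fit a closed loop.
* `simulate_bm` — Brownian tip values with Normal(0, rate·length)
  increments.
* `make_fixture_dataset` — 48 pseudo-species ("Genus_sp01"…) carrying the
  real category composition (EN 1, VU 14, NT 9, LC 24) on a seeded Yule
  tree. The pseudo-names avoid implying real phylogenetic placements; the
  verbatim species table ships separately for ingestion tests. Note the
  fixture assigns categories to tips at random, so it reproduces the data
  *shape*, not any real phylogenetic signal in risk.

What the generators do not emulate: the topology uncertainty of a real
posterior tree set (Yule trees are independent draws, not correlated
posterior samples), rate variation among lineages, extinction
(birth-death tips), or any ecological covariance between risk category
and clade. Passing tests on synthetic data therefore demonstrate
correctness of the machinery under its own assumptions, not the realism
of those assumptions for any particular clade.

### Simulation sizes and recovery experiments

The packaged experiments use 200-tip trees (50 replicates) for
constant-rate recovery and 300-tip trees (30 replicates) for
breakpoint recovery, with DTT calibration on 64-tip trees against
200-replicate null envelopes — sizes at which the estimators' behaviour
is stable while the full suite stays quick.

The two-rate recovery experiment uses q = 0.15, E = 4q = 0.6, B = 0.5.
The baseline rate was chosen on identifiability grounds: a breakpoint is
localized by the change in tip-state similarity around it, which requires
the chain not to saturate after the shift (whole-depth autocorrelation
e^(−k∫r dt) ≈ 0.22 here, a strongly conserved regime comparable to the
empirical data). At substantially higher rates an *increasing* shift on a
Yule tree is essentially unidentifiable — only a few percent of total
branch mass predates t = 0.5, and the ML breakpoint then migrates to a
terminal-branch boundary attractor that gains 1–3 log-units by absorbing
tip noise (it does so even on constant-rate data). Even in the chosen
regime the breakpoint estimator is heavy-tailed: roughly a third of
replicates land on that attractor, so median absolute error of B̂ is of
order 0.1–0.2 — a property of maximum likelihood under these conditions,
not of the optimizer, which matches exhaustive multi-start profiling on
the worst replicates.

## Known limitations

* Only the equal-rates (ER) transition structure is implemented; SYM/ARD
  matrices, hidden states and trait-dependent diversification are out of
  scope.
* The linear and two-rate models share a single global trajectory; no
  lineage-specific rates.
* The published parameter estimates of the motivating analysis print
  negative baseline rates for three models, which cannot be transition
  rates on the natural scale; the package reports rates on the natural
  scale only, so those printed values are not comparable quantities.
* Penalized-likelihood dating uses the Gaussian data term throughout; for
  trees whose input lengths are expected substitution counts with few
  events, a Poisson term would be preferable.
* DD/NE exclusion is the only missing-data policy for the risk table;
  tips can be marked ambiguous in the likelihood but there is no
  imputation.
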