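# Methods

`infodbn` infers a cyclic causal graph over a set of health conditions from
a weekly spatio-temporal panel of nonnegative search-query frequencies,
using a two-slice Gaussian dynamic Bayesian network (DBN).  This note
records the model, the estimators, the synthetic-data design, and the
numerical and design choices a maintainer would want to know about.

## The model

Let X_{i,c,t} be the frequency of condition i in county c at week t.  Two
assumptions make the problem tractable: dependence reaches back one week
only (order-1 Markov), and the process is stationary, so a single pair of
generic consecutive slices (t0, t1) describes the whole series.  Each
condition at t1 is modelled by a linear-Gaussian local regression on its
parents in the previous week:

    X_{i,t1} = mu_i + sum_{j in pa(i)} beta_ij X_{j,t0} + eps_i,
    eps_i ~ N(0, sigma_i^2),

i.e. a sparse structural VAR(1).  Arcs point forward in time only and
instantaneous (within-slice) arcs are disallowed, so the two-slice graph
is acyclic by construction.  Folding the two copies of each condition into
one node yields a directed cyclic graph: arc pairs X0->Y1 and Y0->X1
become feedback loops X<->Y, lone cross arcs stay unidirectional, and
X0->X1 becomes an autoloop expressing autocorrelation.  t0-slice nodes are
roots with marginal Gaussian fits; they contribute a structure-independent
constant to the score and can be excluded via configuration.

## Structure learning

The graph maximizes a penalized log-likelihood

    PL(D, w) = log L(D) - w * u(n) * k,

where k is the number of free parameters (|parents| + 2 per t1 node:
coefficients, intercept, residual variance) and u(n) is the penalty unit.
The default u(n) = log(n)/2 makes w = 1 exactly the Bayesian Information
Criterion; `penalty_unit="log_n"` doubles the penalty for a harsher
selection.  The score decomposes over t1 nodes, so scoring uses cached
sufficient statistics (one Gram matrix per data set); evaluating a parent
set costs O(k^3) independent of n.

Search is plain greedy hill-climbing from the empty graph over single-arc
additions and deletions, accepting the single best improving move per
step; reversal is not a move because a reversed arc would point backward
in time.  Ties are broken by (target, source) column position, and moves
must improve the score by more than 1e-9 to guard against float noise.
Because forward-only arcs cannot interact across nodes, the greedy search
can be checked against exhaustive per-node best-subset enumeration; on
p <= 5 systems with 2000 rows the two agree essentially always (the
acceptance suite requires >= 19/20 seeds).

The penalty coefficient w is tuned on a temporal split: learn on weeks
before `split_week` (default 52), evaluate average R^2 on the remaining
weeks, and keep the largest w from {1, 2, 4, ..., 128} whose validation
accuracy is at least `ratio_floor` (default 0.999) of the w=1 model's.
This is an explicit, reproducible stand-in for choosing the sparsest model
with no marked accuracy loss from a plot.

## Model averaging and the consensus graph

Arc strengths are bootstrap inclusion frequencies: B resamples (default
500) drawn with replacement at 75% of the original size, condition order
permuted per resample so that tie-breaking leaves no systematic imprint,
one structure learned per resample.  Per-resample seeds are spawned from a
single seed sequence, so results are independent of execution order.

The significance threshold is estimated from the strengths themselves by
matching their empirical CDF, in L1 distance, to the ideal two-point
configuration (noise arcs at strength 0, significant arcs at 1).  The
optimal noise fraction is the length-weighted median of the ECDF — a
closed form that a brute-force grid search verifies — and the threshold is
the strength quantile at that fraction, placed mid-gap so the strict
comparison `strength > threshold` is stable under ties.  If all strengths
are identical there is nothing to separate; a fallback of 0.5 is returned
with a warning.  Consensus arcs are inserted in decreasing strength order
with a cycle-discard rule that is vacuous for two-slice graphs but active
when the same routine assembles static (single-slice) networks.

## Variance attribution and generative inference

A parent's contribution to a node is its explained variance in the local
regression.  Since sequential ANOVA depends on entry order when parents
are correlated, increments are averaged over all orderings of the non-self
parents (LMG attribution, computed over all 2^m parent subsets); the
self-parent always enters first and is excluded from the normalized
shares, because autocorrelation would otherwise dwarf every cross effect.
Normalized non-self shares sum to one by construction.

The fitted network is also a generative model: t0 rows are resampled from
the observed slice (preserving their joint dependence; fitted marginal
Gaussians are an alternative that loses cross-condition correlation) and
t1 is drawn from the local models.  Same-week association between a focal
condition and a target is operationalized by augmenting the target's
regression with the focal condition at t1 — the only way to pose the
question inside a model class without instantaneous arcs.  Stratification
splits the simulated draws by the stratifier's t0 quartiles (low = Q1,
average = Q2-Q3, high = Q4; simulated quartiles by default, empirical
optional) and reports the focal's normalized share per stratum.

The mediation/confounding oracle used in the tests constructs a truth in
which the stratifier drives both the focal and the target while no direct
path connects them.  The stratifier is given three well-separated levels
(a trimodal mixture) so each quartile stratum is internally tight: with a
Gaussian stratifier the tail strata retain ~24% of its variance and the
within-stratum share only drops by a factor ~3, right at the assertion
boundary; with separated regimes the collapse is a robust factor 7-10.

## Spatio-temporal baseline

The panel's spatial structure is summarized by the fractions of each
condition's variance attributable to state and county random intercepts,
plus the additional fraction explained by an order-1 autoregression of the
within-county residuals (sequential attribution, so "county + AR(1)" is
the county share plus the increment phi^2 * residual share).

The default estimator is a split-half covariance ANOVA: because the
intercepts are constant over time, the covariance between a county's
first-half and second-half means isolates the intercept variance, with
only an O(long-run variance / T^2) boundary contamination from the
serially correlated within-county process.  A naive nested ANOVA or an
iid-error REML fit (available as `method="reml"` via statsmodels MixedLM)
folds slow autocorrelated variation into the county component — a bias of
+6 to +12 points at the persistence levels the generator produces — and
REML is roughly an order of magnitude slower on the default panel.
Negative component estimates are truncated at zero.  Residualization for
the static-model audit subtracts hierarchical group-mean offsets (the ML
estimates under a balanced design); AR(1) pre-whitening is opt-in.

## Missing data

Condition columns with strictly more than 30% missing cells are dropped.
Single-series imputation is a two-sided exponentially weighted moving
average: a gap takes the weighted mean of up to k = 4 observed neighbours
per side with weight 2^-lag, renormalized over available neighbours — a
convex combination, so observed bounds are respected and observed cells
are never modified.  Linear interpolation and a Kalman (local level)
smoother are comparators.  Series with fewer than `min_observed = 5`
observed values are unimputable and are blanked as whole (county,
condition) series.  The injection benchmark knocks out 2-20% of a fully
observed panel, either as independent cells or as runs of four consecutive
weeks (a month without measurements; runs are re-drawn rather than merged
with existing gaps), and scores each method by mean |imputed - true| /
|true| over injected cells, excluding and separately counting cells whose
true value is zero.

## Synthetic data

The generator draws a ground-truth two-slice network with a prescribed
number of feedback pairs, one-way arcs and an autoloop on every condition;
cross coefficients are uniform on +-[0.2, 0.6], self-coefficients on
[0.5, 0.8], and the folded coefficient matrix is rescaled (preserving
sparsity) to spectral radius 0.95 when needed, so the VAR(1) is stable.
Panels are simulated per county from a stationary start (50 burn-in
weeks), on top of state and county random intercepts that are constant
over time; intercepts are set so stationary means sit near 10 arbitrary
frequency units, and a per-condition shift-then-clip keeps at least 99.9%
of values nonnegative while leaving the linear-Gaussian model exact before
clipping (the clipping fraction stays below 0.1%).

By default the spatial components are zero — the generator then produces
exactly the model class the learner assumes, which is the right benchmark
for parameter and structure recovery.  `with_variance_fractions` adds
state/county intercepts calibrated per condition (from its stationary
variance) so that state carries ~12% and county ~49% of total variance,
emulating the dependence structure reported for real county-level search
panels.  This distinction matters: with county baselines at ~49% of
variance the pooled two-slice regression is genuinely confounded — the
pooled-optimal graph is dense, and the consensus network carries a ~50%
false-discovery rate against the within-county truth.  That is precisely
the misspecification phenomenon the static-model audit quantifies, not an
estimator defect, so recovery guarantees are stated for the correctly
specified generator and the spatially structured variant feeds the
variance-decomposition, imputation and audit scenarios.

What the generator does not emulate: normalization artifacts of real
search data, pandemic-scale shocks, non-stationary trends, heavy-tailed or
zero-inflated marginals, and missingness that is informative rather than
random.  Passing tests therefore demonstrate correctness of the estimators
under the model's own assumptions, not robustness to real-data pathology.

## Static-model audit

A classical static Gaussian BN (hill-climbing with add/delete/reverse
moves under an acyclicity check, same score family) is learned from raw
county-week rows and from rows residualized by the baseline model.
Coefficients on shared arcs are compared (fraction inflated by >= 2x,
fraction with flipped sign; intersection primary, union variant reported),
and each raw-data static arc is classified against the folded dynamic
truth as correct, collapsed feedback, reversed, or spurious.  On
feedback-rich panels the static model is mostly wrong — the qualitative
headline the acceptance suite checks on five seeds.

## Problem sizes and determinism

The default synthetic study uses 10 states x 20 counties x 100 weeks x 12
conditions (19,800 lag rows), B = 500 bootstrap resamples in the
acceptance script (100 in the three-seed recovery test), and 100,000
Monte-Carlo draws for stratified inference.  Every stochastic operation
takes an explicit seed; per-stage seeds are spawned deterministically, so
identical configurations produce byte-identical artifacts.
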