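# Methods

## Belief updating and sampling models

A hypothesis space is a flat list of candidate extensions of a novel
property.  Each hypothesis carries a label, an extension size `|h|`
(a positive integer count of species), explicit `members` /
`non_members` sets over the item vocabulary, and a prior weight;
priors are normalized at construction.  Membership is stored
explicitly rather than derived from a tree because the spaces used
here are flat (conjunctions of categories are not entertained); a
helper (`space_from_taxonomy`) expands a nesting declaration into the
explicit sets.  An evidence item found in neither set raises an error
instead of defaulting to non-membership — a silent default would
silently corrupt likelihoods.

Evidence is an ordered list of premises `(item, have | not_have)`
with no duplicate items (sampling is without replacement throughout;
the with-replacement variant is deliberately not offered).

Likelihoods:

* weak sampling: `P(x|h) = 1` if every positive premise is a member
  and every negative premise a non-member, else 0;
* strong sampling: 0 if inconsistent, else
  `prod_{k=0..m-1} 1/(|h|-k)` over the `m` positive premises.
  Negative premises contribute a constant factor of one under both
  models: the strong model samples among property bearers, so an item
  reported *not* to bear the property can only act as a consistency
  filter.  Hypotheses tied in size receive exactly equal strong
  likelihoods; no tie-breaking is applied.

Posteriors are computed in log space (`logsumexp`) so extensions in
the thousands with several premises cannot underflow, then
renormalized so the simplex constraint holds to machine precision.
Argument strength for a conclusion category is the posterior mass on
the conclusion hypothesis and every labelled superset, where
inclusion is witnessed through the declared member sets; the
conclusion must therefore list at least one member.

The bundled six-hypothesis taxonomy uses approximate real-world
species counts — canines 36, ursines 8, placentals 4,000, macropods
59, marsupials 334, mammals 5,000 — with a uniform prior, and items
dog, wolf (canines) and koala (a marsupial and hence not a
placental).  Koala's memberships are the minimal assignment that
makes the diverse dog-and-koala evidence consistent with exactly one
hypothesis (mammals).

## Diversity sweep

To show the sampling-by-diversity interaction is generic rather than
an artifact of the toy taxonomy, the sweep uses a standard 1-D
consequence space: items are integer positions `1..m`, hypotheses are
all `m(m+1)/2` contiguous intervals with a uniform prior, and
`extension_size` equals interval length.  Defaults: `m = 101` and
three positive premises, matching the three-premise arguments of the
rating experiment; the diversity grid is 51 evenly spaced spreads in
[0, 1].  The sweep is fully deterministic.

Diversity is operationalized as normalized span: premises cover
`ceil(spread·(m−1)) + 1` positions (at least the premise count),
centred, equally spaced with deterministic rounding.  The spread is
rounded to nine decimals before the ceiling so binary-float noise
cannot bump the span by a whole position.

Generalization to the superordinate is measured as the posterior
probability that a randomly chosen domain item bears the property,
`Σ_h P(h|x)·|h|/m` — the expected covered fraction of the domain.
An alternative all-or-none measure (posterior mass on the single
full-domain interval) was evaluated and rejected: it is vanishingly
small at all but extreme diversities for every domain size tried, so
it cannot express graded rating differences, and no latent-diversity
fit under it can reproduce a strong-condition diversity gap larger
than the weak-condition gap.  The graded measure yields all three
qualitative predictions on the default grid — both curves
nondecreasing in diversity, weak ≥ strong pointwise, and a larger
strong-sampling diversity gap — each enforced as a property test,
and the property tests also confirm them on randomized domain sizes,
premise counts and full-range grids.

## Latent-diversity fit

Observed rating-cell means (weak/strong × diverse/nondiverse) are
mapped onto the sweep curves by positing latent perceived diversities
`d` (diverse premises) and `n` (nondiverse premises) and an affine
map from generalization probability to the 1–7 scale.  The caption
quantity fitted is the sum of squared errors between the four cell
means and `a·[g_w(d), g_w(n), g_s(d), g_s(n)] + b`.  The affine link
is the minimal monotone assumption; the slope is constrained
nonnegative.  Fitting is a grid search over `(d, n) ∈ [0,1]²` with
`n ≤ d` (default resolution 0.01) with the affine map solved in
closed form at each grid point, followed by Nelder–Mead refinement of
the grid minimizer.  SSE ties prefer the smallest `d − n`, then the
smallest `d`, so flat (uninformative) cell means collapse to the
degenerate `d̂ = n̂` fit.  Curve values between grid points are
linearly interpolated, so the fit needs a reasonably dense sweep
grid; residuals never increase under grid refinement (tested).

## Synthetic experiment generator

The generator emulates a between-subjects rating experiment: 184
participants split equally into strong- and weak-sampling instruction
groups, 12 trials each (three diverse targets, three nondiverse
targets, six group-specific fillers), ratings on a 1–7 scale.
Target and filler argument inventories (premise triples and
superordinate conclusions from the biological domain) are bundled as
module constants.

Response model, per participant: a subject offset ~ Normal(0,
`subject_sd`); each rating is a latent Normal(condition mean +
offset, `rating_sd`) rounded to the nearest integer and clamped to
[1, 7]; fillers are drawn around the group grand mean.  Round-then-
clamp is the simplest mechanism producing integer Likert data with
controllable means.

Default cell means are weak-diverse 5.38, weak-nondiverse 5.08,
strong-diverse 4.78, strong-nondiverse 3.88 — the unique solution
consistent with marginal means of 5.08 (diverse), 4.48 (nondiverse),
5.23 (weak) and 4.33 (strong) once the weak-group diversity gap is
fixed at 0.30, i.e. a modest but positive weak-condition effect.
Noise defaults `rating_sd = 1.1` and `subject_sd = 0.5` put the
within-group standard errors near 0.09–0.12 at 92 participants per
group.

A configurable fraction (default 0.30) of strong-group participants
is *diversity-insensitive*: their diverse-condition mean equals their
nondiverse mean.  The remaining participants' diverse mean is raised
to `(μ_sd − f·μ_sn)/(1 − f)` so the group-level mixture still equals
the configured strong-diverse cell mean; configured cell means
therefore remain population targets regardless of the insensitive
fraction.  `expected_cell_means` returns the exact expectation of
the full response model (offset, mixture, rounding, clamping), and a
200-replicate calibration test checks the generator is unbiased for
it with near-nominal two-standard-error coverage.

What the generator does *not* emulate: trial-order effects, response
times, attention checks, per-argument idiosyncrasies (all targets in
a condition share one mean), or any heavy-tailed/skewed response
styles of real raters.  Tests passing on this synthetic data show the
analysis pipeline is correct and internally consistent, not that the
model fits any particular real dataset.

## Analysis

Summaries average within participant first (over the three targets
per condition), then across participants; standard errors are over
participant means.  The interaction is exactly the strong-group
effect minus the weak-group effect.  ECDFs are computed per argument
and group at the seven scale points; a pooled-by-condition variant
over participant condition means is provided for dominance checks.
Per-subject summaries report each participant's diverse/nondiverse
means and their difference; "little to no diversity effect" is
operationalized two ways — strictly (effect ≤ 0) and as a near-zero
band (effect ≤ ε, default ε = 1/3, one rating step across the three
targets).  The band version is the better estimate of the
insensitive-subpopulation rate: with trial noise of about 1.1 rating
points, a genuinely null subject lands below zero only about half
the time, so the strict fraction systematically underestimates the
rate, while subjects one rating step or less above zero are exactly
the "on the diagonal" cases the scatter criterion describes.

The paired-samples JZS Bayes factor reduces the differences to a
one-sample t statistic and integrates the noncentral-t likelihood
against a Cauchy(0, r) prior on standardized effect size
(default r = √2/2) by adaptive quadrature split at the likelihood
peak (absolute tolerance 1e-14, relative 1e-10); deep-tail
noncentral-t overflows are treated as zero density.  The test suite
checks it against an independent dense-grid quadrature of the
Zellner–Siow g-representation (to 1e-6 relative) and against
pingouin.  Omnibus mixed-ANOVA Bayes factors and effect-size
measures for the two main effects and interaction are out of scope —
they are off-the-shelf statistics whose published values additionally
depend on the original dataset and prior settings — so the package
covers only the paired-samples BF plus the descriptive structure.

## Numerical and degenerate-input choices

* Priors: nonnegative, not all zero; normalized at construction.
* Zero-normalizer posteriors (no consistent hypothesis) raise.
* Likelihood ratios with a zero denominator raise rather than
  returning infinity.
* `rating_sd = 0` collapses the generator to deterministic rounded
  cell means (used by the noiseless-limit tests).
* The JZS BF raises on fewer than two observations or zero variance.
* Ratings tables are validated on every read/write: schema, integer
  ratings within scale, no duplicate (participant, argument) pairs,
  exactly 12 records per participant; errors name the offending row.
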