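# Methods

## Model and hypotheses

Responses are normal with a common variance across k active doses and
placebo: Y_ij = μ_i + ε_ij, ε_ij ~ N(0, σ²), with n_i patients on arm
i and N = Σ n_i.  The elementary null hypotheses are one-sided
non-superiority statements H_i: μ_i ≤ μ_0 for i = 1…k.  (The package
always tests for an *increase*; callers negate responses for
decreasing-is-better endpoints.  Published descriptions of such
procedures write the elementary null inconsistently as μ_0 ≥ μ_i in one
place and μ_0 ≤ μ_i in another; we resolve this to one-sided
superiority testing throughout.)

## Candidate shapes and contrasts

A candidate set fixes M standardized dose–response shapes f⁰_m with
guessed parameters: Emax d/(ED50+d), sigmoid Emax d^h/(ED50^h+d^h),
beta (d/S)^{δ1}(1−(d/S))^{δ2}, exponential exp(d/δ) − 1, linear.
Standardized shapes matter only up to an affine transform: contrasts
are invariant to shifts (zero-sum) and scale, and simulation truths are
pinned by `scaled_mean_profile` to 0 at placebo and the chosen maximum
effect at the best design dose.  The exponential shape is anchored so
that f⁰(0) = 0; the dropped normalizing constant of the beta family is
absorbed the same way.

For a profile μ⁰ the optimal contrast maximizes c′μ⁰ / √(c′Ac) subject
to 1′c = 0, where A is the covariance of the arm-mean estimates up to
σ² (diag(1/n_i) without covariates; any symmetric positive-definite A
is accepted, covariate construction is out of scope).  The closed form
is c ∝ A⁻¹(μ⁰ − μ̄1) with μ̄ = 1′A⁻¹μ⁰ / 1′A⁻¹1, which reduces to
c_i ∝ n_i(μ⁰_i − μ̄) in the diagonal case.  Contrasts are normalized to
unit norm and oriented so that c′μ⁰ > 0.

### Constrained contrasts

The optimal contrast may put negative weight on an active dose, which
couples a harmful dose with a "significant trend".  The constrained
variant maximizes the same objective over nonnegative dose weights
(equivalently w ≥ 0 in the placebo-difference parameterization
w′Kμ⁰ / √(w′KAK′w)).  The solver enumerates all nonempty support
subsets S of the allowed doses, solves the unconstrained problem on
{0} ∪ S, screens both orientations of the stationary solution for
feasibility, and returns the feasible maximizer.  This is exact: on the
relative interior of each face of the nonnegativity cone the stationary
directions of the scale-invariant objective are exactly ± the
unconstrained solution of that face.  The negative orientation matters
only for profiles that decrease at every dose (the maximum of the ratio
is then negative); for the monotone candidate shapes used in practice
the solution always has c′μ⁰ > 0.  Cost is 2^|I| − 1 subproblems,
negligible for k ≤ 15.  Weights below −1e-12 count as infeasible;
magnitudes below that are snapped to exact zeros and the placebo
coefficient re-balanced so the zero-sum/unit-norm invariants hold to
machine precision.

## Inference

The statistics T_m = c′_m Ȳ / (S √(c′_m A c_m)) share the pooled
variance S² with ν = N − k − 1 degrees of freedom — also when a test
restricts attention to a dose subset; S² is *never* re-estimated on the
subset.  Under the null (T_1, …, T_M) is central multivariate t with
correlation R_mm′ = c′_m A c_m′ / √((c′_m A c_m)(c′_m′ A c_m′)).

Adjusted p-values q_m = 1 − P(max_j T_j ≤ t_m) and equicoordinate
critical values come from randomized quasi-Monte-Carlo integration of
that distribution (scipy's Genz-style integrator, 30 000 points per
evaluation, seeded).  Every probability carries an error estimate (the
half-range of two independently randomized evaluations, typically
≤ 1e-4).  Numerically identical contrasts (correlation 1 within 1e-12)
are collapsed before integration — on singleton intersections all
models collapse to the same pairwise contrast and the p-value is the
exact one-sided t probability.

M contrasts on k+1 arms span at most a k-dimensional space, so for
M > k the correlation matrix is singular.  The equicoordinate
probability is continuous in R; a ridge of 1e-7 (renormalized) makes
the integrator applicable with bias around 1e-5, below the integration
tolerance.  (scipy's own singular-matrix code path returns wrong
values for this case and is not used.)  Critical values are found by
Brent root bracketing between the unadjusted and Bonferroni t quantiles
on a single fixed QMC randomization, making the bracketing function
deterministic and monotone; quantile tolerance 1e-6, subject to
integration error.  Rejecting by min_m q_m < α and by T_max ≥ c_{1−α}
agree up to that tolerance (checked on random instances).

## Closed testing

All 2^k − 1 intersection hypotheses are tested exhaustively — the
procedure is not consonant, so no step-down shortcut is valid.  A dose
is rejected when every containing intersection is; its closed adjusted
p-value is the maximum p-value over containing intersections (standard
closure algebra).  The global intersection is the original model-based
trend test and acts as a gatekeeper.  Candidate models that are flat on
an intersection's doses are dropped for that intersection with a
warning rather than failing the procedure; the remaining models still
give a valid level-α test.  Choosing the unconstrained variant with
k ≥ 3 triggers a warning: strong FWER control is proven only for k ≤ 2
there, while the constrained variant controls it for any k.

## Competitors

Pairwise one-sided t-tests (pooled variance), Bonferroni and Hochberg
(via statsmodels' multiplicity machinery), fixed-sequence testing
(highest dose first by default, overridable by passing p-values in the
intended order), single-step Dunnett, and step-down Dunnett implemented
as the shortcut of the closed Dunnett test with shrinking
equicoordinate critical values; its decisions are verified against
explicit exhaustive closure in the tests.

## Simulation engine

Trials are generated patient-level: arm i gets n_i draws from
N(μ_i, σ²) with μ from a scaled candidate profile (or an explicit mean
vector for pathological configurations).  Randomness derives from a
seed sequence keyed by (master seed, scenario id, replicate), so every
replicate is an independent, reproducible substream and
`simulate_trial` and the vectorized study engine produce bit-identical
data.  Replicates are shared across procedures (common random numbers)
to sharpen ordering comparisons.

Because contrasts and critical values depend only on the design, they
are computed once per study; each replicate reduces to matrix products,
so 10 000 replicates of the full procedure battery run in seconds.
Reported metrics: RAO (probability of at least one rejection),
per-hypothesis power, AVE/k (mean rejections over k), each with
binomial Monte-Carlo SEs; the closed variants additionally report the
global (proof-of-concept) rejection rate.

Default study conditions mirror the motivating trial: doses
(0, 0.1, 0.4, 1), 100 patients per arm, σ = 1, one-sided α = 0.025,
maximum effects 0.3/0.4/0.5, 10 000 replicates (heavier ordering and
pathology checks in the test suite use 2 000, which resolves the
orderings at 2 SE ≈ 0.02).

Under the flat profile every hypothesis of the closed family is true,
and the closed procedure commits a familywise error exactly when its
global gatekeeper rejects — that rate is calibrated to α.  The rate of
elementary false rejections is strictly smaller (closure is
conservative at the dose level) and is checked against the one-sided
bound.

What the generator does *not* emulate: covariates, unequal variances,
dropout, non-normal responses.  Calibration and ordering results
therefore speak to the idealized homoscedastic normal setting; the
procedure itself only requires the arm means and a pooled variance, so
the same machinery applies to any design producing approximately
normal arm-mean estimates.

## Two-endpoint extension

Primary hypotheses H1i and secondary hypotheses H2i (same doses, shared
candidate set) form a weighted graph: node levels are fractions of α,
edges route a rejected node's level onward.  The default symmetric
graph puts α/k on each primary, sends a rejected primary's level to its
own-dose secondary (weight x, default 1, with (1−x)/(k−1) to the other
primaries for x < 1), and returns a rejected secondary's level equally
to the other doses' primaries.  For each of the 2^{2k} − 1
intersections, the standard node-removal algebra yields local levels
(removal-order invariant; checked by permutation).  The intersection is
tested with a Bonferroni split between the endpoint groups — endpoint
correlation is never estimated — each group using the constrained
maximum contrast test on its doses at the sum of its local levels.
Within a group the levels are pooled into a single group-level test;
the published construction only exercises equal within-group levels,
and pooling is the natural reading of testing the group "at the sum of
their local significance levels".

Since local levels are exact fractions of α, the intersection p-value
is min over groups of (group p) / (group fraction), and elementary
adjusted p-values follow the same max-over-containing-intersections
algebra as the single-endpoint case.  With the default graph a
secondary hypothesis can only be rejected after the same-dose primary;
this successiveness emerges from the level algebra and is asserted in
tests, not hard-coded.

## Numerical conventions and limitations

- One-sided α = 0.025 by default, configurable.
- Dose matching when reading CSVs is exact after canonical float
  parsing — silent mis-binning is worse than a hard error.
- Integration tolerance 1e-4 (absolute) for multivariate-t
  probabilities; duality between p-values and critical values holds to
  ~5e-4 near the decision boundary.
- The support-enumeration constrained solver is exponential in |I|;
  fine for the intended k ≤ 15.
- The Mod step (model fitting, dose–response and target-dose
  estimation), non-normal endpoints, covariate adjustment, adaptive
  designs and a consonant weight modification are out of scope.
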