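# Methods

## Model representation and estimation

Models are written in a compact formula dialect (`=~` measurement, `~`
regression, `~~` covariance, numeric premultipliers fix coefficients,
`#` comments) and normalized into an explicit parameter table: a free
variance (or disturbance variance) for every variable, free covariances
among all exogenous variables, and marker-variable identification of each
latent factor (first loading fixed to 1 unless the user fixed one).  The
marker method was chosen over factor-variance fixing because it is the
default of the major SEM packages, keeping free-parameter counts
comparable across software.  Variable order is order of first appearance
in the syntax; covariance pairs are normalized against it, which makes
candidate names deterministic.

Estimation uses the RAM parameterization,
Σ(θ) = F(I−A)⁻¹S(I−A)⁻ᵀFᵀ, and minimizes the normal-theory ML
discrepancy F = ln|Σ| + tr(SₛΣ⁻¹) − ln|Sₛ| − p by BFGS with analytic
gradients.  Free variances are optimized on the log scale so the search
cannot leave the admissible region; non-positive-definite Σ encountered
mid-search is handled by a smooth penalty, never a crash.  Start values:
half the sample variances for error variances, 0 for paths and
covariances, 0.7 for free loadings; up to 5 jittered restarts (seeded)
when the gradient norm has not reached 1e−6.  The χ² statistic is
(n−1)·F (Wishart convention; `chisq_multiplier="n"` switches to n).
Empirical identification is checked at the solution: the finite-difference
Hessian of F must not be numerically rank deficient (smallest eigenvalue
at least 1e−8 of the largest); failures are flagged on the result.  The
baseline (independence) model has the closed form χ² = (n−1)(−ln|R|),
with R the sample correlation matrix.

## Fit indices and BIC

CFI = 1 − max(χ²−df, 0)/max(χ²_b−df_b, χ²−df, 0), clamped to [0,1];
RMSEA = sqrt(max(χ²−df,0)/(df·(n−1))), defined as 0 for the saturated
model; SRMR is the root mean square of the residuals standardized by
sample standard deviations over the p(p+1)/2 unique elements.  RMSEA uses
the n−1 denominator; both n and n−1 reproduce the golden table at printed
precision, so the choice is cosmetic at these sample sizes.

The BIC feeding the posteriors is χ² + q·ln(n) with q the free-parameter
count.  A full-likelihood BIC (`bic_loglik`) is exposed for cross-software
comparison; the two differ by a dataset-dependent constant that cancels in
differences, so posteriors are identical under either convention (tested).

## Posterior model probabilities

Posterior(Mᵢ) ∝ exp(−(BICᵢ − BIC_ref)/2)·Prior(Mᵢ), normalized over the
candidate set.  Computation goes through log-sum-exp, since ΔBIC in the
hundreds or thousands occurs in real model sets and naive exponentiation
overflows.  Priors must be supplied for all models or none (unbiased
default 1/m); a partial assignment is completed by spreading the remaining
mass equally over unnamed models, and priors that do not sum to 1 are an
error, never silently renormalized.  Candidates flagged as nonconvergent
or unidentified receive prior 0 and stay visible in the output rather
than being dropped silently.

The minimum-prior sensitivity analysis solves Posterior(target) = b under
the scheme "target gets π, the other m−1 models share 1−π equally".  The
closed form is π = b·W̄ / (w_t(1−b) + b·W̄), with w_t the target's BIC
weight and W̄ the mean weight of the others; the test suite cross-checks
it against bisection to 1e−9.  Since the posterior is strictly increasing
in π on (0,1), the solution is unique, and any b < 1 is achievable.

## Neighborhood enumeration

Candidate additions are (a) directed paths among structural variables
(non-indicator observed variables and latent factors) whose addition keeps
the structural graph acyclic, (b) cross-loadings in latent models, and
(c) covariances between error terms/exogenous variables.  A covariance
is excluded when one member of the pair causally precedes the other —
"precedes" operationalized as ancestry in the directed structural graph
(transitive closure) — unless `exclude_xy_cov=False`.  Indicator error
covariances are excluded by default in latent models
(`exclude_error_cov=None` resolves to "exclude iff latents present"): with
13 indicators there are already 78 of them, and they are rarely
interpretable outside longitudinal designs.  A path addition between a
pair already linked by a free covariance is suppressed (the combination is
not identified).  Parameters fixed to zero count as absent, so freeing
them is an addition.  Drops are all free non-variance parameters: paths,
non-marker loadings, and covariances — including free exogenous
covariances, which are ordinary free parameters here (the alternative,
protecting them, was rejected as an arbitrary asymmetry).

Wider radii compose single modifications: up to `df_change_add` additions
and `df_change_drop` drops, with the total number of changes capped by the
larger of the two radii.  This makes radius (1,1) exactly the 1-df-away
set (no mixed add+drop pairs, which would have df_diff 0) while radius
(2,2) includes paired same-kind and mixed changes.  Jointly cyclic
composed additions are pruned after composition; enumeration above a cap
(default 500 models) is an error rather than a silent truncation, since
the model count grows exponentially with the radius.

Equivalence is empirical: two candidates are merged iff they have the same
df, |Δχ²| ≤ 1e−6 and implied covariance matrices equal elementwise to
1e−6 on the analyzed data.  This is a deliberate stand-in for
graph-theoretic equivalence rules (replacing-rule procedures): it detects
exactly the clusters those rules predict on the shipped analogs (e.g. the
m11→m2 / m2→m11 / m11~~m2 trio in the serial-parallel model), but is a
data-dependent criterion, not a structural proof.  The representative is
the lexicographically smallest name, except that the original model always
represents its own class.

## Synthetic-data generation

The generator draws multivariate-normal samples (seeded,
`numpy.random.default_rng`) with covariance Σ(θ) from a spec plus true
parameter values, or returns Σ(θ) exactly.  Shipped analogs:

* `serial_parallel` — the serial-parallel mediation structure
  (x→m11→m12→y; x→m2→y), standardized paths 0.5 on the x→m11, m11→m12,
  x→m2 legs and 0.3 into y, unit variances; n defaults to 200.
* `serial_parallel_weak_extra` — the same plus a weak (0.1) x→m12 path,
  for quasi-true-model selection studies.
* `cfa_three_factor` — 3 factors, 13 indicators (5/4/4), free loadings
  0.8, error variances 0.5, factor covariances 0.4, marker
  identification; n defaults to 145.
* `cfa_cross_loading` — the CFA plus one true cross-loading (0.3).

Path magnitudes {0.1, 0.3, 0.5} span weak-to-moderate standardized
effects, putting the weak-path regime (where parsimony can beat a true
small effect at small n) inside the tested range.  The generator emulates
exactly multivariate-normal data with a covariance structure and no mean
structure: passing tests demonstrate correct behaviour under normality
and correct model specification of the generator, and say nothing about
robustness to nonnormal, ordinal or missing data, which are out of scope
(as are MLR/MLM/DWLS estimators and multi-group or mean-structure
models).

## Test problem sizes and numerical choices

Simulation tests use n ∈ {200, 1000, 5000} with 5 seeded replicates per
n for the sample-size-consistency property (the mean BPP of the
generating model is non-decreasing in n and exceeds 0.5 at n = 5000),
and 20 replicates at n = 100 for the weak-path parsimony property; these
sizes give stable verdicts for the shipped effect sizes while keeping the
full suite fast on one CPU.  The independent cross-check oracle in the
test suite is a separately coded fitter (path-tracing implied covariance
via summed coefficient-matrix powers, derivative-free Nelder-Mead on the
raw scale) and agrees with the package to 1e−3 on random small models;
it shares no code path with the BFGS/RAM implementation.

Degenerate inputs: df = 0 models report a NaN p value (not applicable);
negative counting-rule df is an error before fitting; non-positive-definite
sample matrices are rejected with a clear message; ties in BPP sorting are
broken by model name for deterministic tables and DOT output.

## Known limitations

* Equivalence detection can in principle merge models that fit equally
  well on the analyzed data without being equivalent for all data; the
  1e−6 tolerance makes this unlikely but not impossible.
* The enumeration treats covariances involving one indicator and one
  structural variable as out of scope (neither an error covariance nor a
  structural covariance); MIMIC-style additions are therefore not
  searched.
* Identification screening is empirical (counting rule plus information
  rank), not algebraic; a model can pass both and still be empirically
  underidentified in pathological data.
* Posterior probabilities are relative to the candidate set by
  construction; a high BPP cannot certify that any candidate fits well in
  an absolute sense, which is why the conventional indices are reported
  alongside.
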