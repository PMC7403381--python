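# Methods

## The measurement problem

Empirical indices of eyewitness accuracy — the diagnosticity ratio, the
area under a confidence-based ROC — confound memory with task structure.
A fair `n`-item lineup caps the innocent-suspect identification rate at
`1/n`, so ROC curves from different lineup sizes or procedures terminate
at different points and enclose different areas even when the underlying
familiarity distributions are identical; the stopping-rule sequential
procedure additionally produces a non-monotonic ROC when response bias
varies between witnesses. `lineupsdt` therefore estimates the latent
quantities directly: each procedure gets a generative signal-detection
model, and procedures are compared on fitted parameters rather than on
surface rates.

## Model family

All models share the unequal-variance Gaussian familiarity layer: foil
familiarity is standard normal, target familiarity is `N(d_t, s_t)`, and
a designated innocent suspect (when one exists) is `N(d_s, s_s)`.
Decision criteria `c_1 < c_2 < … < c_k` partition the evidence axis into
a rejection region and `k` confidence levels; `c_1` is the choose /
no-choose threshold. The rules:

* **max** (independent observations): the witness identifies the most
  familiar item iff its familiarity exceeds `c_1`. Cumulative
  identification probabilities are one-dimensional integrals of the
  target (or suspect) density against `Φ(x)^(n−1)`; the target-present
  foil-identification probability follows from the same rule —
  `(n−1) ∫_c φ(x) Φ(x)^(n−2) Φ((x−d_t)/s_t) dx` — and is certified
  against the trial-level simulator.
* **int** (integration): identification iff the *sum* of all `n`
  familiarities exceeds `c_1`; the most familiar item is then chosen.
  Criteria live on the summed-familiarity scale. Conditional on the
  maximal item's value `x`, the remaining items are standard normals
  truncated above at `x`; their sum is approximated as normal with
  moments `(n−1)·μ_x` and `√(n−1)·σ_x`, where `(μ_x, σ_x)` are the
  truncated-normal mean and SD. The approximation is the model's
  definition here — the exact-sum process differs from it by design, and
  the test suite compares the model against trial-level simulators of
  *both* forms (the exact-sum comparison at a relaxed absolute
  tolerance of 0.01 that absorbs the documented approximation error).
  Fair target-absent sums are exactly `N(0, √n)`; no approximation is
  used there, in the probability formulas or in the approximate-sum
  simulator.
* **seq** (stopping rule): items are viewed in position order and the
  first whose familiarity reaches `c_1` is identified; confidence comes
  from the chosen item's familiarity against `c_2..c_k`, while every
  prior rejection uses `c_1`. Position distributions `p` (target) and
  `q` (suspect) enter the closed-form sums `Σ_i p_i Φ(c_1)^(i−1)`; a
  target-present lineup is rejected with probability
  `Φ((c_1−d_t)/s_t) Φ(c_1)^(n−1)` regardless of `p`.
* **ensemble**: the most familiar item is compared with the *mean of the
  remaining* items; identification iff the difference exceeds `c_1`.
* **evsd** (show up): `n = 1`, equal variance. The binary-outcome model
  is saturated and has the closed-form solution
  `d_t = Φ⁻¹(H) − Φ⁻¹(F)`, `c = Φ⁻¹(1 − F)`.

Fair target-absent lineups contain `n` exchangeable foils; the innocent
suspect rate is then the any-foil rate divided by `n` (the standard
designated-innocent-suspect proxy, used by the ROC module). With a
designated suspect, target-absent lineups have three outcome classes
(suspect, foil, reject) and the suspect contributes two extra free
parameters at most.

## Numerical evaluation

* **Quadrature.** The max- and integration-rule integrals are evaluated
  with fixed 128-point Gauss–Legendre rules on a support window of ±8
  standard-normal units (widened to cover the target and suspect
  densities). For these entire integrands the error is below 1e-12 —
  checked against adaptive quadrature in the tests — and evaluation
  vectorises over all criteria at once, which the fitting and
  simulation-study loops rely on.
* **Truncated-normal moments** use the scaled complementary error
  function for the Mills ratio and are stable far below the `x = −8`
  requirement.
* **Ensemble probabilities** have no convenient closed form: the
  decision variable mixes the maximum and the mean of the rest. They are
  evaluated by scrambled-Sobol quasi-Monte Carlo over the `n−1` foil
  dimensions with the remaining item integrated analytically, which
  makes the result smooth in the parameters and deterministic given the
  internal seed. The default 2^16 nodes give worst-cell errors around
  2e-4; `ensemble_precision()` lowers the node count for bulk studies
  (2^11–2^13 suffices when fitting 10,000-trial simulated datasets whose
  sampling noise is an order larger). Per-draw identification terms
  partition the outcome space, so category probabilities sum to one
  exactly rather than to within QMC error.

## Fitting

Parameters are estimated by minimising the Pearson χ²,
`Σ (O − N·P)² / (N·P)` summed over the target-present and target-absent
multinomials (and over datasets in joint fits). Degrees of freedom are
free cells minus free parameters, with free cells per condition equal to
categories − 1; structurally empty cells (target-present foil cells of a
show up) are excluded from the count. Expected probabilities are floored
at 1e-12 inside the objective to keep it finite near degenerate
parameter values; the public `chi_square` raises on a zero-probability
cell with observations instead.

Optimisation is Nelder–Mead from seeded, dispersed starting points
(10 by default), with standard deviations searched on the log scale and
criterion ordering enforced by a penalty that is inactive at any
admissible solution. Criteria are parameterised directly (not as
increments) so that any single criterion can be equated across datasets
in joint fits; equality constraints are implemented in the parameter
map, guaranteeing the +1 df bookkeeping per constraint. Local minima are
real for these likelihoods — hence the restarts, an automatic
restart-from-incumbent after each simplex run, and a flagged
`converged` field rather than an exception on failure. Bounds
(|d| ≤ 5, 0.1 ≤ s ≤ 5, −5 ≤ c ≤ 8) are generous relative to any
published estimate.

Joint fits with no shared parameters are solved as independent fits (the
summed objective separates). Constrained refits are typically seeded
with the unconstrained solution in addition to dispersed restarts.

## Simulator

The simulator draws one familiarity per lineup member and applies each
rule literally, trial by trial (vectorised); it is the brute-force
oracle for every probability formula and the data generator for the
simulation studies. Agreement is certified in the acceptance suite: 20
random parameter/design configurations per model at 10^6 trials per
condition, with every outcome cell within 3 binomial standard errors
(allowing the <1% of marginal exceedances expected across ~500
simultaneous comparisons, none beyond 4.5 SE). For the integration rule
the generator has both an exact-sum form and a truncated-normal
("normal-approx") form mirroring the model's own definition; the
simulation-study harness generates integration-rule data with the latter
so that the χ² goodness-of-fit test stays calibrated at its nominal α.

What the simulator emulates is the *model's* world: Gaussian
familiarity, witness-homogeneous parameters, no position-dependent
discriminability, encoding or face-similarity structure. Passing
oracle and recovery tests therefore demonstrates internal correctness
of the formulas and estimator, not that real witnesses obey any of
these rules.

## Simulation studies

The cross-fit study draws random parameter sets (defaults: `d_t` ~
U(0.5, 2.5), `s_t` ~ U(0.8, 1.6), `c_1` ~ U(0.5, 2), criterion
increments ~ U(0.1, 0.6), stretched ×2 onto the summed scale for the
integration rule — spanning the range of published estimates), simulates
6-item-lineup datasets of 10,000 target-present and 10,000 target-absent
trials, and fits every model to every dataset at α = .05. Self-fits
should reject at about α and cross-fits far more often; recovery is the
per-parameter correlation between generating and recovered values.
Self-fits whose χ² exceeds the value attained at the generating truth by
more than a margin (3.0) are refit from fresh dispersed starts and, if
the gap persists, flagged and excluded from the recovery correlations —
the local-minimum outlier rule. The test suite runs this at reduced
scale (50 parameter sets for recovery, a 10-set full cross-fit matrix,
2 restarts per fit) to keep the whole suite near ten minutes on one CPU;
the full 100-set protocol is a configuration change
(`CrossFitConfig(n_param_sets=100, n_datasets_per_set=100, n_starts=10)`)
and is reproducible from its single seed.

## Weighted corpus statistics

For meta-analytic summaries of per-study estimates the package uses the
sample-size-weighted mean and the population-convention weighted SD
(`σ_w² = Σw(v−μ_w)²/Σw`). The weighted Welch test treats each group's
unbiased weighted variance over its Kish effective sample size
(`n_eff = (Σw)²/Σw²`) as the squared standard error and applies
Satterthwaite degrees of freedom on the effective sizes; with equal
weights it reduces exactly to the standard Welch two-sample test, which
is the anchor property the tests enforce. Hedges' g uses the pooled-SD
standardised difference of the unweighted group values with the
`1 − 3/(4·df − 1)` small-sample correction. These normalisation and df
conventions are documented choices among several in circulation; the
reduction-to-unweighted property is what pins them down here.

## Other design choices

* Confidence bins are stored ascending internally (lowest confidence
  first, aligned with the criteria); published tables print
  highest-first and the I/O layer keeps explicit bin indices to avoid
  ambiguity. Bin edges for raw 0–100 confidence records are pooled
  even-as-possible frequency quantiles over identifications from all
  conditions.
* `C = c − d_t/2` is provided as the conventional bias index; it is
  meaningful only under equal variance, since a free `s_t` moves the
  truly unbiased point.
* Boundary hit/false-alarm rates (0 or 1) in the show-up closed form
  raise rather than being silently corrected; callers choose their own
  continuity correction.
* Ties between continuous familiarity draws have probability zero and no
  tie-breaking logic exists; `argmax` resolves the measure-zero event of
  exact float equality toward the earlier position.

## Limitations

* The integration rule inherits a central-limit approximation for `n−1 ≤ 5`
  truncated normals; its probabilities differ from the exact-sum process
  by up to ~1e-2 in extreme-criterion regions.
* No standard errors or confidence intervals on parameter estimates are
  produced, and no information criteria — model comparison is by nested
  χ² differences only.
* Position-dependent discriminability, lap-based sequential procedures
  (e.g. mandatory second viewings), backloading and continuous-confidence
  likelihoods are out of scope.
* The ensemble rule is evaluated for fair and designated-suspect
  target-absent lineups but requires `n ≥ 2` by construction.
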