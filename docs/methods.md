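# Methods

## Model and estimator

Scores from a balanced, fully crossed person × task × rater design are
modelled additively:

y_ptr = μ + a_p + b_t + c_r + (ab)_pt + (ac)_pr + (bc)_tr + e_ptr,

all effects random, independent, zero-mean, with variances
σ²_p, σ²_t, σ²_r, σ²_pt, σ²_pr, σ²_tr, σ²_e. With one observation per cell
the three-way interaction is confounded with residual error, so σ²_e is
"residual" in the broad sense.

Components are estimated by the ANOVA / expected-mean-squares (EMS)
method of moments. Mean squares come from marginal-total machine formulas
(uncorrected sums of squared totals minus the correction factor); the EMS
system is triangular and solved by substitution:

- σ²_e = MS_e
- σ²_pt = (MS_pt − MS_e)/n_r, σ²_pr = (MS_pr − MS_e)/n_t, σ²_tr = (MS_tr − MS_e)/n_p
- σ²_p = (MS_p − MS_pt − MS_pr + MS_e)/(n_t·n_r), and symmetrically for σ²_t, σ²_r.

EMS was chosen over REML because published crossed-design reliability
tables in this field follow the G-theory convention of EMS estimates with
negative solutions truncated to zero, which this package reproduces
(truncation is simple clamping, without re-solving the remaining
equations). On balanced data REML coincides with the ANOVA solution
whenever the latter is inside the parameter space, so nothing is lost; the
test suite exploits that identity as an independent cross-check against
lme4. Raw (untruncated) estimates are retained because truncation induces
positive bias, and bias/RMSE reporting must use the raw scale.

Requirements: all three facet sizes ≥ 2 (a singleton facet leaves effects
unestimable and raises rather than silently dropping terms); missing cells
are a hard error with the absent (person, task, rater) combinations listed
— the crossed-model algebra is only valid for complete balanced data and
imputation would silently change the estimand.

## D studies

Both facets are treated as random (scenarios and raters are exchangeable
samples from their universes). For a design with n′_t tasks and n′_r raters,
scores averaged over both:

- relative error σ²_δ = σ²_pt/n′_t + σ²_pr/n′_r + σ²_e/(n′_t·n′_r),
  generalizability Eρ² = σ²_p/(σ²_p + σ²_δ);
- absolute error σ²_Δ adds σ²_t/n′_t + σ²_r/n′_r + σ²_tr/(n′_t·n′_r),
  dependability Φ = σ²_p/(σ²_p + σ²_Δ) ≤ Eρ².

The published tables this package reproduces report only the relative
coefficient ("G"); Φ is provided as a standard companion and labelled as
such. D studies always consume truncated components. Facet sizes are
integers only. The minimum-tasks search solves the linear inequality in
n′_t exactly and verifies the boundary numerically; when the asymptote
σ²_p/(σ²_p + σ²_pr/n′_r) falls at or below the target the search returns an
explicit unattainable sentinel (`None`) rather than a huge number.

One reproduced table contains an internal inconsistency: the technical
column of the LAST/Hemorrhage pairing prints G(T=10, R=1)=0.43, while the
printed components imply ≈0.38. The package computes from components and
makes no attempt to guess the intended figure; that cell is excluded from
the verified set.

Coefficients are presented rounded half-up to 2 decimals (components to 2,
percentages to 1), with full precision retained internally; because
published components are themselves rounded to 2 decimals, comparisons
against published coefficients use a ±0.01 band. Percent-of-total shares
are computed from unrounded components, which reproduces published person
shares exactly and can differ from percentages recomputed from rounded
components by ≈0.1 point.

## Synthetic data

The simulator draws every effect from a normal distribution with its
specified variance — precisely the estimator's model, no more. Defaults
mirror the study conditions: 10 persons × 2 tasks × 2 raters, grand mean
5.5 (scale midpoint; components are translation-invariant in μ, asserted by
test), and component presets equal to the published columns of the two
pairings (`last_mh_behavioural`, `last_mh_technical`, `last_hem_behavioural`,
`last_hem_technical`). A single integer seed drives one `numpy` generator
for the whole replication stream.

Discretization (round to nearest integer, clip to [1, 9]) is off by
default: it shrinks total variance (clipping truncates tails by more than
rounding adds) and biases components, so recovery properties are stated for
the continuous generator. Recovery reports expose continuous vs discretized
totals to make that shrinkage visible.

What the simulator does *not* emulate: rater drift over time, halo effects
(correlated dimension errors), non-normal or floor/ceiling-skewed score
distributions, and unbalanced or nested designs. Passing tests therefore
validate the estimator and projection algebra under the stated model, not
the behaviour of real rating data that violates it.

Parameter-recovery scope (chosen as the package's test conditions):
unbiasedness is asserted over 1000 replications of a 20×4×3 design within
3 Monte-Carlo standard errors per component; consistency by comparing RMSE
at 10×2×2 against 200×20×10 (relative RMSE < 15 % there); and the
end-to-end link by the mean estimated G(2,2) over 200 replications at
n_p = 500 landing within 0.03 of the value implied by the generating
components. At the study's own 10×2×2 scale individual estimates are highly
variable — truncated person variance is zero in roughly half of simulated
replications of the 8-person pairing — which is itself the substantive
point about small crossed designs.

## Pipeline and numerical choices

- Axis ordering of cubes is lexicographic by identifier; all outputs are
  deterministic, and pipeline reruns with identical config and input are
  byte-identical (outputs staged in a temp directory and moved on success,
  so failures leave nothing behind).
- The inter-rater correlation pools (person, task) units across tasks by
  default (a per-task variant is available); the inter-task correlation
  averages raters within task first. Sample SDs use the n−1 denominator.
  Constant inputs make a Pearson correlation undefined and raise.
- If a score and its four BARS dimensions are both supplied and the score
  is not their mean (tolerance 1e-9), ingest fails: the total is defined as
  the dimension mean, so disagreement indicates corrupted data. Scores are
  accepted as reals, since dimension means like 7.5 are legitimate.
- A pipeline analysis whose truncated person variance is zero reports the
  error variances but leaves G/Φ empty instead of failing the whole run.
- Behavioural analyses take one score per (person, task, rater); BARS
  aggregation to that score is a preprocessing choice made at ingest, since
  the dimension-level rating structure is not part of the crossed model.
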