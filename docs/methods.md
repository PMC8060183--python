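# Methods

## The bounded integer model

A score `Y_ij ∈ {0, …, S}` for subject `i` at visit `j` is generated by a
latent standard-normal scale partitioned at the quantile cut-points
`q_s = Φ⁻¹(s/(S+1))`, `q_0 = −∞`, `q_{S+1} = +∞`. With latent mean
`f_ij = β_i + α_i · t_ij` (t in months) and latent SD `σ_i`,

    P(Y_ij = s) = Φ((q_{s+1} − f_ij)/σ_i) − Φ((q_s − f_ij)/σ_i).

Because `q_s = −q_{S+1−s}`, the model is reflection-symmetric: negating
`(β, α)` and mapping `s ↦ S−s` leaves every probability unchanged — a
property the test-suite uses as an end-to-end invariant.

Parameter model: `β_i = θ_β + η_{i,β}`, `η_{i,β} ~ N(0, ω²_β)`; likewise for
`α_i`. The latent SD is either fixed (`σ_i = θ_σ`) or log-normal
(`log σ_i = log θ_σ + η_{i,σ}`, `η_{i,σ} ~ N(0, ω²_σ)`), parameterized on
the log scale so positivity is structural. An optional covariate model on
the slope,

    α_i = θ_α · (age_i/75)^θ_age · θ_apoe^apoe_i · θ_sex^sex_i + η_{i,α},

uses a hard-coded age centering at 75 years; the slope random effect enters
additively after the multiplier.

## The two log-likelihood kernels

**Naive.** `log(Φ(z_{s+1}) − Φ(z_s))` evaluated literally. Two failure
modes: (i) for z-scores below ≈ −38 both CDFs underflow to 0; (ii) for
z-scores above ≈ +8.3 both CDFs round to values within one ulp of 1 and the
subtraction cancels to 0; either way the log is `−∞` (or NaN). The kernel is
deliberately not hardened — its breakdowns are the object of study — and the
asymmetry of (i) vs (ii) is why the naive curve dies on one side first when
plotted against `η`.

**Improved.** Three exact-or-asymptotic rewrites:

1. *Reflection*: when both z-scores are positive, use
   `Φ(b) − Φ(a) = Φ(−a) − Φ(−b)` so the dominant term is always a lower-tail
   probability (never a quantity near 1).
2. *Log-domain difference*: with `l⁺ = max(log Φ(z_s), log Φ(z_{s+1}))` and
   `l⁻ = min(...)`, the log-likelihood is
   `l⁺ + log1p(−exp(l⁻ − l⁺))`; the exponential argument is never positive
   and `log1p` keeps precision for small differences. Boundary categories
   (`s = 0`, `s = S`) short-circuit to a single log-CDF, avoiding
   `−∞ − (−∞)`.
3. *Asymptotic log-CDF*: for `z ≥ −6`, `log Φ(z)` comes from the
   complementary error function (`log1p` form on the upper side). For
   `z < −6` it uses the upper member of the classical error-function bracket

        1/(x+√(x²+2)) < e^{x²}∫ₓ^∞e^{−t²}dt ≤ 1/(x+√(x²+4/π)),  x = |z|/√2,

   i.e. `log(1−Φ(|z|)) ≈ log[√(2/π)/(x+√(x²+4/π))] − x² − log√2`. Beyond
   `|z| ≈ 1.3·10¹⁵⁴`, where `z²/2` itself overflows, the kernel returns
   `−∞`; estimation code treats that as a rejected step.

### Accuracy of the hard switch — what to expect

The bracket's two sides differ by `≈ (1 − 2/π)/z²` on the log scale
(0.0095 at z = 6), and the upper member's error against the exact tail is
`≈ (1/2 − 1/π)·2/z²` absolute — about 8.8·10⁻³ at z = 6, 9.0·10⁻⁴ at
z = 20, shrinking like 1/z². Three measured consequences, all asserted by
tests rather than hidden:

* `log Φ` has a ~8.8·10⁻³ discontinuity at the z = −6 switch (the tail
  formula slightly overestimates); monotonicity holds everywhere else and
  up to that jump across the switch. The kernel orders `l⁺/l⁻` by max/min,
  so a cut-point pair straddling the switch still yields a finite value.
* Relative accuracy of the log-likelihood is limited to ~10⁻⁴…10⁻² when the
  *dominant* z-score lands just above 6; it recovers to better than 10⁻⁶
  once |z| ≳ 30 (and is at machine precision for |z| < 6). The stress-grid
  oracle tests use η in steps of 0.5 at σ = 0.01, where dominant z-scores
  are either below 6 or above 40.
* As σ → ∞ all interior z-scores collapse to 0, so the probability mass
  drains to the two boundary categories (half each) — the flat-pmf intuition
  is wrong, and the test asserts the correct limit.

The arbitrary-precision oracle (`loglik_oracle`, mpmath, ≥30 digits,
default 50) evaluates CDF-subtract-log at full precision; when both
z-scores are positive it first applies the exact reflection identity,
because at 50 digits `1 − 10⁻¹⁹⁸⁰⁰` rounds to 1 — even an oracle must
respect the geometry of finite precision.

## Simulation

`simulate_dataset` draws, per subject and in subject order, random effects
then residuals from a single seeded stream; the latent value
`L = f + σ·ε` is binned with the lower-open/upper-closed convention
`q_s < L ≤ q_{s+1}`, matching the CDF-difference definition (ties have
probability zero; the convention fixes determinism). A chi-square test
confirms the binning law equals the categorical law of the analytic pmf.

Built-in scenarios share the design — score 0–70, 600 subjects, visits at
0, 3, 6, 9, 12 months, θ_β = −0.3, θ_α = 0.1/month, ω²_β = 1,
ω²_α = 0.000625 — and differ in the latent SD: S1 σ = 1 (benign), S2
σ = 0.1 (small), S3 log-normal σ with θ_σ = 0.1, ω²_σ = 0.1. The covariate
generator (age ~ uniform integers 60–90, APOE/sex ~ Bernoulli(½)) exists to
exercise the covariate code path; it is not calibrated to any real cohort.
What the generator does **not** emulate: dropout and missing visits,
non-monotone designs, floor/ceiling clustering beyond what the BI law
itself produces, or item-level structure. Passing tests therefore speak to
estimator behavior under the BI law, not to fit of any particular clinical
instrument.

## Laplace estimation

Per subject the random effects are integrated out by a second-order
expansion at the empirical-Bayes mode η̂_i:

    log p(y_i) ≈ log p(y_i, η̂_i) + (k/2)·log 2π − ½·log det(−H_i).

The mode search is a damped Newton ascent from η = 0 (analytic gradient via
the normal-hazard ratios `φ/P = exp(log φ − loglik)`, central-difference
Hessian, Cholesky with Levenberg damping, backtracking line search; at most
50 iterations, gradient tolerance 10⁻⁸). Subjects whose joint density is
non-finite at the start, or whose mode Hessian is not positive definite,
are flagged; they contribute a −10⁷ log-likelihood penalty so the outer
optimizer can continue — visible failure instead of a crash.

The outer problem minimizes OFV = −2·Σ log p(y_i) over
(θ_β, θ_α, log θ_σ, log ω²_β, log ω²_α[, log ω²_σ]) by BFGS with an
explicit central-difference gradient (relative step 10⁻⁴ — the objective
carries ~10⁻⁸ inner-optimization noise, far too large for a √ε
forward-difference step), warm-starting each subject's mode from the
previous objective evaluation.

**"Minimization successful" analog.** The reference software's criterion is
proprietary, so the package defines a transparent one: success iff the
final OFV is finite, AND no subject's inner optimization failed at the
solution (a failed subject means the evaluated OFV is the penalized
surrogate, not the model's marginal likelihood), AND
`max_i |g_i|·max(|x_i|, 1) < 10⁻³·max(1, |OFV_data|)` for the
central-difference OFV gradient `g` (penalty-free OFV sets the scale), AND
the central-difference OFV Hessian is positive definite. Defaults:
outer iteration cap 500, gradient tolerance 10⁻³, inner Newton tolerance
10⁻⁸, FD step 10⁻⁵. SSE runs initialize at the simulation truth (the usual
SSE default; exposed as an option).

Laplace accuracy: against an adaptive Gauss–Hermite oracle the per-subject
marginal agrees to better than 10⁻³ (typically 10⁻⁷) for σ ≥ 0.5 subjects
with interior scores; subjects pinned at a boundary score have visibly
skewed posteriors and second-order errors up to a few 10⁻³ — a property of
the Laplace method, not of the kernel.

## SAEM

SAEM alternates Metropolis random-walk sweeps over each subject's
individual parameters (stored as absolute values `β_i, α_i[, log σ_i]` so
population updates never move the chains) with stochastic-approximation
M-steps. Step size is 1 during burn-in and `(k−B)^{−1}` afterwards
(defaults: 300 + 300 iterations, 2 sweeps per iteration, per-subject
per-coordinate proposal scales adapted during burn-in toward 30–50%
acceptance, initialized at the prior SDs). Means and variances of effects
with matching random effects update in closed form from smoothed first and
second moments. A fixed-effect σ (S1/S2) is not exponential-family: its
update smooths the complete-data log-likelihood itself on a fixed 81-point
grid spanning ±2 log-units around the initial value and maximizes the
smoothed surface with parabolic refinement — a deliberate simplification
that keeps the update a pure stochastic approximation. Non-finite surface
values (naive-kernel breakdowns) are floored far below any attainable
value so they can neither poison the smoothing with NaNs nor attract the
argmax.

A proposal whose likelihood is non-finite is always rejected — this single
rule is why SAEM is insensitive to the kernel choice: the chain simply
never visits the region where the naive kernel breaks, and the probability
mass there is negligible anyway. Convergence flag: every parameter's
relative span over the final 20% of SA iterations below 10⁻². The reported
OFV is a single Laplace evaluation at the final estimates (a reporting
convenience; SAEM itself never computes a marginal likelihood). Covariate
models are out of the SAEM module's scope.

## SSE engine and metrics

`run_sse` simulates replicate datasets (derived seeds by default, explicit
seed lists supported), fits each, and summarizes REE = (θ̂−θ)/θ per
parameter, relative RMSE (root mean squared REE), and the success rate.
REE/RMSE are computed over successful replicates only; failures appear in
the success rate — the two metrics answer different questions and are kept
separate. RMSE is defined on the relative scale so parameters of different
magnitude share one table. A replicate whose fit raises is recorded as a
failure and the run continues. Subject-level bootstrap resampling keeps all
of a subject's rows together and re-identifies subjects 1..N.

Scaled-down study sizes used by the acceptance layer: 150 subjects and 20
replicates per arm (the full 600-subject design remains available through
`n_subjects`/scenario overrides). Runtime is logged per fit but never
asserted.

## Known limitations

* The z = 6 switch trades a ~10⁻² log-scale discontinuity for totality;
  applications needing uniform 10⁻⁶ relative accuracy in the 6 < |z| < 30
  band would need a higher-order tail expansion.
* The success-criterion analog is transparent but not the reference
  software's: success *rates* transfer qualitatively (orderings,
  benign-regime equivalence), not as calibrated percentages. In particular
  the naive kernel's inner-optimization failures are deterministic given
  the data here (every replicate contains subjects whose joint density is
  non-finite at the starting point when σ ≈ 0.1), so naive-arm success
  rates sit at the bottom of the scale rather than at intermediate values.
* Laplace accuracy degrades for boundary-pinned subjects (above); with
  σ-variability (S3) the ω²_σ estimate is strongly biased low under
  Laplace with either kernel, while SAEM recovers it — the approximation,
  not the arithmetic, is the limit there.
* SAEM's σ-grid M-step assumes the optimal θ_σ stays within ±2 log-units
  of the initial value.
* Only the linear latent trend, constant/log-normal σ and the printed
  slope-covariate form are supported; no general model language.
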