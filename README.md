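# bimod — bounded integer models for composite clinical scores

Composite scores (ADAS-cog, UPDRS, PANSS, …) are discrete, bounded outcomes:
integers between 0 and a maximum `S`. The bounded integer (BI) model respects
both properties by placing a latent standard-normal variable on a grid of
cut-points

```
q_s = Φ⁻¹( s / (S+1) ),        s = 1, …, S,     q_0 = −∞,  q_{S+1} = +∞,
```

and assigning score `s` the normal mass between adjacent cut-points,

```
P(Y_ij = s) = Φ( (q_{s+1} − f) / g ) − Φ( (q_s − f) / g ),
```

where `f` is the subject's latent mean (here `f = β + α·t`, time in months)
and `g = σ` the latent SD, with normal between-subject variability on `β`,
`α` and optionally log-normal variability on `σ`.

The catch is numerical: the obvious log-likelihood implementation —
compute both CDFs, subtract, take the log — underflows and cancels
catastrophically whenever an observation sits many latent SDs from the
subject's mean, which happens routinely during optimization whenever `σ` is
small. This package provides both implementations side by side:

* **naive**: `log(Φ(z_{s+1}) − Φ(z_s))`, deliberately unhardened;
* **improved**: symmetry reflection (`Φ(b)−Φ(a) = Φ(−a)−Φ(−b)` when both
  z-scores are positive), the log-domain identity
  `log(a−b) = log a + log1p(−exp(log b − log a))`, and an asymptotic
  (Mills-ratio-type) expression for `log(1−Φ(z))` beyond `z = 6`, making the
  log-likelihood finite wherever a double can represent it;

together with everything needed to quantify what the difference does to
estimation: a simulation module with three standard scenarios (S1/S2/S3:
latent SD 1, 0.1, and log-normal around 0.1 on a 0–70 score, five visits
over 12 months), Laplace-approximation and SAEM population estimators, an
arbitrary-precision oracle, and a simulation–estimation (SSE) engine
reporting relative estimation error (REE = (θ̂−θ)/θ), relative RMSE and
convergence rates.

It is aimed at pharmacometricians and biostatisticians who model composite
scores and want either a reference implementation of the stable kernel or a
test bed for studying numerical effects on mixed-effects estimation.

## Worked example

```python
import bimod

# simulate 150 subjects from scenario S2 (latent SD 0.1 — the hard regime)
spec = bimod.builtin_scenarios()["S2"].with_overrides(n_subjects=150)
data = bimod.simulate_dataset(spec, seed=5)

model = bimod.BoundedIntegerModel.from_dataframe(data, max_score=70)
res = model.fit(init=spec.pop, method="laplace", impl="improved")
print(res.summary())
```

```
Bounded integer model fit
==========================================
method:          laplace (improved kernel)
OFV (-2 log L):  4080.3377
success:         True
outer iters:     11
failed subjects: 0
------------------------------------------
    theta_beta  -0.38724
   theta_alpha   0.100164
   theta_sigma   0.0957005
   omega2_beta   0.836667
  omega2_alpha   0.000714219
```

The objective function value (OFV) is −2 × the Laplace-approximate marginal
log-likelihood; `success` is the package's "minimization successful" analog
(finite OFV, scaled-gradient criterion, positive-definite OFV Hessian). The
estimates sit close to the simulation truth (−0.3, 0.1, 0.1, 1, 0.000625) —
the discrepancies are this dataset's sampling noise, e.g. the fitted
baseline −0.39 is ~1 standard error from −0.3 at N = 150. Refitting the same
data with `impl="naive"` fails the success criterion and reports dozens of
subjects whose inner optimization broke down; `method="saem"` gives
essentially the same estimates with either kernel, because a sampling-based
algorithm never needs the log-likelihood in the region where the naive
kernel breaks.

The same operations are available from the shell:

```sh
bimod simulate S2 --seed 5 --n-subjects 150 --out data.csv
bimod fit data.csv --max-score 70 --impl improved --init-scenario S2
bimod sse S3 --impl naive --replicates 20 --n-subjects 150
bimod profile --out fig3.csv     # naive vs improved log-likelihood table
bimod bounds --out fig1.csv      # normal-tail bound bracket table
```

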