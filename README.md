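# ewocnets

Bayesian adaptive phase I dose finding with **E**scalation **W**ith
**O**verdose **C**ontrol driven by the **N**ormalized **E**quivalent
**T**oxicity **S**core, extended with a single patient covariate for
*personalized* maximum-tolerated-dose (MTD) estimation.

## Who this is for

Statisticians designing phase I oncology trials who want to

* use **all** toxicity information (every graded adverse event, not just a
  binary dose-limiting-toxicity indicator), and
* let a baseline biomarker or patient characteristic shift the estimated
  MTD, so different patients can be recommended different doses,

while keeping the ethical guarantee of overdose control during escalation.
The package provides the toxicity scoring system, the dose–toxicity
models and posterior inference, the dose-assignment rule, and a simulator
for computing a design's operating characteristics before running a trial.

## The model

Each patient's toxicity burden is summarised by a NETS score `S ∈ [0, 1]`:
CTCAE grades 0–4 plus DLT status are recoded to an adjusted grade
`G ∈ {0,…,6}` (grade 3/4 DLT → 5/6), and

```
S = (1/6) · [ G_max − 1 + logistic(c + β · A) ]
```

where `A` is the weighted residual toxicity burden (all events except one
instance of the worst, scaled by `G_max`), `c = −2`, `β = 0.25`.  A
patient with no toxicity scores 0; grade-1-only profiles score 1/60.  The
MTD is redefined as the dose where the *mean* NETS equals a target level
θ (TNETS, default 0.476), elicited from a target toxicity profile as
`θ = Σ m_l p_l` with fixed band mid-ranges `m_0..m_6`.

The mean NETS follows a logistic curve in dose `x` and covariate `c`:

```
logit μ(x, c) = β₀ + β₁ x + δ c        (β₁ > 0)
```

re-parameterized into clinically interpretable quantities: `γ_max` (the
MTD of the covariate level with the highest MTD), `ρ₁` and `ρ₂` (mean
NETS at the minimum dose for the low- and high-MTD level).  With
independent uniform priors — `γ_max ~ U(x_min, x_max)`, `ρ ~ U(0, θ)` —
the joint posterior under the **quasi-Bernoulli likelihood**

```
L = Π μᵢ^{sᵢ} (1 − μᵢ)^{1−sᵢ}      (fractional sᵢ)
```

is sampled by a seeded Metropolis–Hastings chain (1000 burn-in + 1000
kept draws).  The personalized MTD at covariate value `z` is
`γ(z) = γ_max + (δ/β₁)(z_max − z)`; the next patient is dosed at the
α-quantile of its posterior (α escalating 0.25 → 0.5 in steps of 0.05),
and the final recommendation is the posterior median.

Three fitted models: **model 1** (no covariate, pooled baseline),
**model 2** (binary covariate), **model 3** (continuous covariate).

## Worked example

Score a toxicity-event table (one row per event):

```
$ ewocnets score --input events.csv --output nets.csv
$ cat nets.csv
patient_id,n_events,max_adjusted_grade,nets
pt01,3,5,0.6888273733663048
pt02,1,1,0.016666666666666666
pt03,0,0,0.0
```

`pt01` had a grade-3 DLT (adjusted grade 5) plus a grade-2 and a
down-weighted grade-1 event, so the score lies in the grade-5 band
(4/6–5/6); `pt02` had only a grade-1 event (1/60); `pt03` had none.

Simulate one adaptive trial under scenario S1 (binary covariate, true
MTDs 0.5 for C=1 and 0.27 for C=0) fitting model 2:

```
$ ewocnets trial --scenario S1 --model 2 --seed 7 --out trial.csv
trial complete: gamma_max_hat=0.523 gamma_0_hat=0.357 -> trial.csv
```

The per-patient log records covariate, feasibility bound α, assigned
dose, observed NETS and the running posterior median of γ_max.  Run a
replicate study and get operating characteristics:

```
$ ewocnets simulate --scenario S1 --model 2 --seed 1 --n-sims 50 --out oc.csv
S1 model2 n_sims=50: gamma_max mean=0.529 gamma_0 mean=0.284 MTD+%=44.9 LNETS%=48.1 -> oc.csv
```

i.e. over 50 simulated 30-patient trials the mean final estimates were
0.529 and 0.284 for true MTDs 0.5 / 0.27, 44.9% of administered doses
exceeded the dosed patient's true personalized MTD by more than the 0.05
tolerance (MTD+), and 48.1% of observed NETS values exceeded θ + 0.05
(LNETS).  Every run writes a `.meta.json` sidecar with the package
version, seed and config hash; identical commands reproduce identical
outputs byte for byte.

The same functionality is available as a library
(`ewocnets.scenario`, `run_trial`, `run_study`, `sample_posterior`, …).

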