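# Methods

`rumordyn` analyses the interplay between online health-rumor propagation
and social trust with a system-dynamics toolkit: two small ODE models, a
set of closed-form text and lifecycle statistics, an intervention
scenario engine, and a seeded synthetic-corpus generator that stands in
for a private rumor-refutation database.  This note documents the models,
their assumptions, the parameter defaults and why they were chosen, and
what the synthetic data do and do not establish.

## 1. Extended SIR rumor model

Believers `B`, susceptibles `S` and immune individuals `I` (with
`B + S + I = N`) follow

```
dB/dt =  β·S·B/N − δ·η·B − λ·B         (spread − debunking − forgetting)
dS/dt = −β·S·B/N + λ·B + ρ·I           (spread, forgetting, reinfection)
dI/dt =  δ·η·B − ρ·I                   (debunking − reinfection)
```

- `β` — rumor transmission rate per contact (1/period);
- `δ` — intensity of refutation interventions; `η ∈ [0, 1]` — refutation
  efficiency (fraction of refutation contacts that actually immunise);
- `λ` — forgetting rate: believers lose the rumor and become susceptible
  again;
- `ρ` — reinfection rate: immunity wanes.

The right-hand sides sum to zero, so population is conserved exactly in
real arithmetic; Runge–Kutta methods preserve this linear invariant, and
the integrator additionally asserts conservation to `1e-6·N` and clips
stock excursions below `−1e-9·N` to zero with a logged warning.

Time units are abstract "periods" — the source analyses never state
whether a period is an hour or a day, and nothing in the package depends
on the choice.

## 2. Coupled trust–rumor model

Trust level `T` and rumor level `R` under intervention forcing `E(t) ≥ 0`:

```
dT/dt = α(1 − T) + βE − γRT
dR/dt = −δR − εER − ζTR
```

Natural trust recovery pulls `T` toward 1, interventions add trust, and
rumor prevalence erodes it; the rumor decays naturally and is suppressed
by both interventions and trust.  Every `dR/dt` term is non-positive, so
`R` is non-increasing whenever parameters and forcing are non-negative —
this monotonicity and the comparative-statics property (a larger `ζ`
never yields a larger `R(t)`) are tested.

`T` is deliberately **not clamped** to `[0, 1]`: the equations permit
`T* = 1 + βE/α > 1` under constant forcing, and silently clamping would
hide parameterisation mistakes.  Excursions above 1 are logged and left
in the output.

## 3. Integration

The default integrator is classical fixed-step RK4 with the step equal to
the output-grid spacing — bit-for-bit reproducible across runs and
platforms, which matters more here than adaptivity since all systems are
small and non-stiff.  An `adaptive` mode (scipy `RK45`, `rtol 1e-8`)
exists and is cross-checked against RK4 in the tests; with transmission
switched off both systems reduce to linear decay and both integrators
match the closed forms to better than `1e-4` relative error.

## 4. Text statistics

**Smoothed topic-word probability.**
`P(word_i | topic_k) = (β_{k,i} + n_{k,i}) / Σ_j (β_{k,j} + n_{k,j})` on
*given* count matrices with strictly positive prior counts.  No topic
model is fitted here — document-topic shares and count matrices are
inputs (from the generator or from the user); the estimator is verified
against a brute-force implementation on 1,000 random matrices.

**Source-topic conditional.**
`P(source_j | topic_k)` by direct indicator counting.  Conditioning on a
never-observed topic is an explicit error, not zero: returning 0 would
silently conflate "no data" with "never associated".

**Keyword-adjusted sentiment score.**

```
S_final = ((S_base + α·(N_pos − N_neg)) + adj_panic + adj_trust − 0.5) × 2
```

with `S_base ∈ [0, 1]` an input feature (the upstream polarity model is
out of scope; the generator emits it) and, at the corpus level,
`adj_panic = −w_panic·n_panic`, `adj_trust = +w_trust·n_trust`.  Two
deliberate decisions:

- *Range.*  The score is described as lying in (0, 2), but the raw
  formula does not enforce that (with zero adjustments it maps [0, 1]
  onto [−1, 1]).  The package clamps to [0, 2] **by default but
  explicitly** (`SentimentParams.clamp`); with `clamp=False` the raw
  value is returned so the discrepancy is observable.
- *Signs.*  Only the existence of panic/trust adjustments is specified,
  not their direction; panic lowers and trust raises the score here,
  consistent with the panic-amplifies-negativity mechanism the models
  encode.  Both weights are configurable, including sign.

Category boundaries are nowhere defined in the source analyses; the
default cuts `(0.4, 0.8, 1.2, 1.6)` partition [0, 2] evenly into the five
categories.

**Stage-topic clustering.**  Documents' topic-share vectors are centred,
projected onto the top-2 principal axes (deterministic sign convention:
the largest-magnitude loading of each axis is positive) and partitioned
by seeded k-means with `n_init=10`.  A corpus of identical documents
yields one effective cluster, reported rather than raised.

## 5. Lifecycle statistics

Landmarks of an intensity series `R(t)` relative to `R_max`:
emergence `t_e` (first `R > 0.1·R_max`), peak `t_p` (earliest argmax),
decline onset `t_d` (first `t > t_p` with `R < 0.7·R_max`), dissipation
onset `t_r` (first `t > t_d` with `R < 0.2·R_max`); stage durations are
the landmark differences and transition rates are
`(R(b) − R(a))/(b − a)` per phase.  Numerical decisions:

- inequalities are strict exactly as defined, and landmarks are grid
  points; sub-grid linear interpolation of the three crossings is opt-in
  (`interpolate=True`), with the peak always a grid point;
- `argmax` ties (plateaus) resolve to the earliest point;
- a landmark whose condition never holds is an *undefined* first-class
  value that propagates through durations — monotone or slowly-decaying
  series legitimately have no `t_d`/`t_r` within the window (the demo
  pipeline's baseline believer curve is exactly such a case);
- a zero series and a zero-duration phase are distinct explicit errors
  (`DegenerateSeriesError`, `PhaseDegenerateError`).

The extractor is verified against an independent exhaustive-scan oracle
on 1,000 random unimodal series.

**Trust-transfer efficiency.**  `T_trans = α·C_cred·exp(−β·D_time)`:
credibility-scaled and exponentially discounted in the refutation delay
`D_time` (abstract time units).  Log-linearity in the delay is tested.

**Hijack–spread relation.**  OLS of spread intensity on the trust-hijack
index with Pearson correlation and a pointwise 95 % band from the
classical homoscedastic linear-model formula (the published figure shows
a band without defining it; this is the textbook choice).

**Stage levels.**  Per-stage arithmetic means of trust and rumor level;
how the published per-stage levels were computed from the original corpus
is not stated, and the group mean is this package's definition.  All
three stages must be present; missing stages are reported by name.

## 6. Synthetic corpus generator

The generator emulates the *published summary statistics* of a 1,100-event
rumor-refutation corpus (February–March 2020): topic shares
(28.20 / 16.24 / 19.95 / 18.46 / 17.15 %), sentiment shares
(36.75 / 9.33 / 6.16 / 8.12 / 39.65 %, normalized — the printed values sum
to 100.01 %), stage-conditional trust means (0.563 / 0.893 / 0.957) and
rumor means (0.101 / 0.050 / 0.050), a degree distribution bulked in
100–300 with a supernode rebound near 600, and a hijack index spanning
[0, 0.15] with a spread-intensity rebound above 0.1.

No distributional family is published for any of these variables, so
every family here is a stand-in chosen once:

- **Categoricals** (topic, sentiment, stage, tier, behavior) are i.i.d.
  draws from the configured mixtures.  Stage is independent of day by
  default; `stage_by_day=True` ties it to day terciles instead.
- **Trust/rumor levels** are `[0, 1]`-truncated normals
  (`trust_noise_sd = 0.05`).  The location parameter is solved so that
  the *truncated* mean equals the configured mean: near the boundary the
  naive parameterisation is biased (≈ −0.017 at mean 0.957), which would
  break mean recovery at any sample size.  The sd 0.05 keeps values well
  inside [0, 1] without distorting spreads.
- **Keyword counts** are Poisson with sentiment-category-conditional
  rates — the simplest count model that gives the scoring stage a signal
  to recover — and the base polarity is then set to
  `clip(target − keyword_term + N(0, 0.02), 0, 1)`, where `target` is the
  category's bin-centre score: the category label is the latent truth and
  the features are generated to be consistent with it.  At the defaults
  the analytic between-bin leakage is under 0.2 percentage points.
- **Degrees** mix a bulk component (rounded normal, mode 225, sd 60) with
  a tail component (600 ± 40) at fraction 0.03, clipped to ≥ 1.
- **Hijack → spread link**:
  `spread = clip(0.55 − 1.8·h + 4.0·max(0, h − 0.1) + N(0, 0.15), 0, ∞)`
  with `h ~ U(0, 0.15)` — a weak negative trend (population correlation
  ≈ −0.2) with a localized rebound above the 0.1 threshold.
- **Day horizon** is 60 days (≈ the February–March collection window);
  tier shares (0.25 / 0.35 / 0.40) and behavior shares
  (0.35 / 0.10 / 0.20 / 0.35) are unpublished and set once to plausible
  values.
- **Token counts** use a 20-token vocabulary with "pneumonia" at the top
  rate, and **document topic shares** are Dirichlet draws around
  stage-specific archetypes (emerging / diffusive / consensus topics).

**What passing tests show — and do not.**  Recovery tests establish that
the analysis stages are *correct inverses of this generative process* at
the published marginals.  They say nothing about real text (no language
is modelled, only feature counts), real network structure (degrees are
i.i.d. draws, not a graph), or real temporal correlation (events are
exchangeable given their stage).  Conclusions about actual corpora
require actual corpora.

## 7. Intervention scenario engine

The published scenario comparison involves believers, trust and panic
jointly, but no equations are given for that system — only the causal
arrows (trust throttles uptake; spread fuels panic; panic amplifies
spread) and the intervention strengths.  The engine closes the loops
using the two models above and nothing else:

```
spread = β₀·(1 + k_P·P)·(1 − k_T·T)·S·B/N
dB/dt  = spread − δ·η·B − λ·B            (and dS, dI as in the SIR model)
dP/dt  = a_P·spread/N − d_P·P
dT/dt  = α_T(1 − T) + β_T·E − γ_T·(B/N)·T
```

optionally with a health-literacy stock `dH/dt = g_H(1 − H)` boosting the
trust throttle to `k_T(1 + c_H·H)` (off by default).  Intervention
attachment points, config-overridable: *trust enhancement (+30 %)* scales
the initial trust (capped at 1), *panic reduction (−20 %)* scales `a_P`,
*strengthened debunking (+25 %)* scales `δ`.

Default closure constants (`ScenarioEngineConfig`): `N = 10,000`,
`B₀ = 100`, `S₀ = 9,850`, `I₀ = 50`, `T₀ = 0.5`, `P₀ = 0.05`,
`β₀ = 0.88`, `k_P = 2.0`, `k_T = 0.70`, `δ = 0.25`, `η = 0.02`,
`λ = 0.30`, `ρ = 0.10`, `a_P = 1.0`, `d_P = 0.3`, `α_T = β_T = 0.01`,
`γ_T = 0.05`, `E = 0.2`, horizon 30 periods at `dt = 0.1`.  The regime is
deliberate:

- high forgetting and reinfection give a high-turnover endemic system in
  which believers rise monotonically to a plateau within the horizon
  instead of peaking and crashing;
- trust dynamics are slow (`α_T, γ_T` small), so the initial-trust lever
  persists across the horizon and baseline trust stays in a low band;
- refutation efficiency is small (`η = 0.02`), reflecting the documented
  weakness of debunking alone ("debunking failure"); scaling `δ` by 1.25
  therefore moves little, while the trust and panic levers act on the
  transmission term itself.

Under these defaults the engine reproduces the published qualitative
findings, each of which is a test: every intervention keeps believers at
or below baseline at every grid time; the comprehensive intervention is
the strongest everywhere; debunking alone is the weakest single
intervention at the final time; panic rises toward a plateau in all
scenarios; and trust under trust-enhancement rises early and then
declines as believer prevalence erodes it.

Whether the model's S/I classes coincide with the published diagram's
"Skeptics"/"Informed" boxes is ambiguous in the source; the engine treats
them as susceptible/immune and this note records the ambiguity.

## 8. Pipeline, seeding and reproducibility

`run_pipeline` executes generate → text analytics → stage levels →
scenarios → lifecycle (on the baseline believer curve), writing CSV/JSON
sidecars and a Markdown report with no timestamps, so identical config
and seed give byte-identical report bodies.  Stages are isolated: a
failing stage is recorded and independent stages still run.  One global
seed fans out to per-stage child seeds via `seed XOR crc32(stage_name)`
(mod 2³¹), so adding a stage never perturbs earlier stages' randomness.

## 9. Problem sizes

Parameter-recovery checks run at n = 50,000 records, where the binomial
3-σ half-widths (≈ 0.6 pp for a share near 28 %, ≈ 0.002 for a stage
mean with sd 0.05) sit comfortably inside the stated recovery tolerances;
oracle comparisons use 1,000 random instances; ODE checks use grids of a
few hundred points.  The entire suite and the acceptance script each run
in well under a minute on a single CPU.

## 10. Known limitations

- All generator families are stand-ins (see §6); only marginal structure
  is matched, not joint or temporal structure.
- The scenario engine's closure is one consistent reading of the stated
  causal arrows; other closures could fit the same qualitative findings.
  Every constant is exposed in config for exactly that reason.
- No network-explicit or stochastic (agent-based) simulation; the models
  are deterministic mean-field ODEs.
- No multi-peak lifecycle segmentation: the landmark set assumes a
  unimodal series; variant "reproduction" rebounds appear only as
  undefined late landmarks.
- No real NLP: Chinese segmentation, polarity models and topic-model
  inference are upstream of this package; text enters as feature counts.
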