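# rumordyn

System-dynamics analysis of online health-rumor propagation and social
trust: how rumors emerge into a trust vacuum, spread by hijacking
existing trust relationships, and dissipate as trust is rebuilt — and
what interventions (debunking, trust-building, panic management) do to
that cycle.

The package is aimed at computational social scientists and infodemic
researchers who want a tested, reproducible implementation of this model
family rather than one-off simulation scripts.

## What is inside

**Extended SIR rumor model.**  Believers B, susceptibles S and immune I
(B + S + I = N):

    dB/dt =  β·S·B/N − δ·η·B − λ·B
    dS/dt = −β·S·B/N + λ·B + ρ·I
    dI/dt =  δ·η·B − ρ·I

with transmission β, refutation intensity δ and efficiency η, forgetting
λ and reinfection ρ — rumors are forgotten and recur, unlike classical
epidemics.

**Coupled trust–rumor model.**  dT/dt = α(1−T) + βE − γRT,
dR/dt = −δR − εER − ζTR, with intervention forcing E(t).

**Trust-transfer efficiency.**  T_trans = α·C_cred·exp(−β·D_time):
credibility-scaled and exponentially discounted in the refutation delay.

**Text statistics.**  Prior-smoothed topic-word probabilities
(β + n)/Σ(β + n) on given counts, source-topic conditionals by counting,
and a keyword-adjusted sentiment score
S_final = ((S_base + α(N_pos − N_neg)) + adj_panic + adj_trust − 0.5)×2
binned into five categories.

**Rumor lifecycle.**  Landmarks by threshold crossings of R(t) relative
to its maximum (emergence > 10 %, decline < 70 %, dissipation < 20 %),
stage durations, and per-phase transition rates — with undefined
landmarks as first-class results for series that never decay.

**Intervention scenario engine.**  A believers–trust–panic closure of the
two models that compares baseline, trust enhancement (+30 %), panic
reduction (−20 %), strengthened debunking (+25 %) and the comprehensive
combination.

**Synthetic corpus generator.**  Seeded corpora (default 1,100 records)
that reproduce the published summary statistics of a COVID-19-era
rumor-refutation database — topic mixture, bipolar sentiment mixture,
stage-conditional trust/rumor levels, core–periphery degrees, and the
hijack–spread relation — so the whole pipeline is testable without any
data download.  See `docs/methods.md` for what the synthetic data do and
do not establish.

## Worked example

Run the full pipeline with the default study conditions:

```bash
rumordyn report --seed 42 --out demo
```

This generates a 1,100-record corpus, analyses it, runs the scenario set
and writes `demo/report.md`, CSV/JSON sidecars and six figures.  The
report printed by the run above contains, among others:

```
## stage levels

| stage   |   mean_trust |   mean_rumor |
|:--------|-------------:|-------------:|
| early   |       0.5658 |       0.1048 |
| mid     |       0.9037 |       0.0486 |
| late    |       0.9555 |       0.0485 |

## scenarios

| scenario               |   believers |   ... |   trust |   panic |
|:-----------------------|------------:|------:|--------:|--------:|
| baseline               |   7842.5450 |       |  0.3850 |  0.7970 |
| trust_enhancement      |   7521.7740 |       |  0.5380 |  0.7640 |
| panic_reduction        |   7518.2130 |       |  0.4010 |  0.6110 |
| strengthened_debunking |   7747.1090 |       |  0.3870 |  0.7910 |
| comprehensive          |   6876.7300 |       |  0.5770 |  0.5600 |
```

Reading the numbers: trust accumulates across propagation stages (0.57 →
0.90 → 0.96) while the rumor level halves — the see-saw between trust
rebuilding and rumor dissipation.  In the scenario table the
comprehensive intervention keeps believers lowest (6,877 of 10,000 at
period 30) and panic best contained, while strengthened debunking alone
is the weakest single lever (7,747, barely below the 7,843 baseline) —
refutation after the fact does little once a rumor is entrenched.

The same pieces are available as a library:

```python
import numpy as np
import rumordyn as rd

corpus = rd.generate_corpus(rd.GeneratorConfig(seed=42))
print(rd.stage_levels(corpus))

series = rd.generate_intensity_curve(
    "triangular", {"t_start": 0, "t_peak": 10, "t_end": 20, "peak": 10},
    np.arange(21),
)
times = rd.detect_lifecycle_times(series)      # te=2, tp=10, td=14, tr=19
durations = rd.compute_durations(times)        # (8, 4, 5, 17)
```

Other subcommands: `generate`, `analyze-text`, `lifecycle`,
`simulate-sir`, `simulate-trust`, `run-scenarios` — each takes
`--config` (YAML, all sections optional), `--seed` and `--out`.

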