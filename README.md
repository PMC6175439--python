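# swssre

Design, power, and mid-trial **s**ample-**s**ize **re**estimation for
**s**tepped-**w**edge cluster randomized trials (SW-CRTs).

A stepped-wedge trial rolls an intervention out across `C` clusters over
`T` time periods, each cluster crossing from control to intervention at a
randomized step.  Sizing such a trial requires guessing two nuisance
parameters — the between-cluster variance σ_c² and the residual variance
σ_e² of the Hussey–Hughes linear mixed model

    Y_ijk = μ + π_j + τ X_ij + c_i + ε_ijk,
    c_i ~ N(0, σ_c²),  ε_ijk ~ N(0, σ_e²),

and a wrong guess leaves the trial under- or over-powered.  `swssre`
implements internal-pilot remedies for cross-sectional SW-CRTs: after a
prespecified period `t`, the accumulated data are used to reestimate
(σ_c², σ_e²) — either **unblinded** (interim REML) or **blinded**, via
moment estimators built only from cluster-period means and within-cell
spread, never from individual treatment labels — and the
per-cluster-per-period sample size for the remaining periods is
recomputed to restore the target power, clamped to a prespecified window
`[n_min, n_max]`.  A Monte-Carlo engine estimates the operating
characteristics (type-I error, power, realized total sample size) of the
resulting adaptive designs.

The package is aimed at trial statisticians evaluating whether a
reestimation step is worth building into an SW-CRT protocol, and at
methodologists studying such procedures by simulation.

## What's inside

| module | contents |
|---|---|
| `swssre.design` | allocation matrices, variance components, cluster-period summaries, compound-symmetry closed forms |
| `swssre.power` | information for τ, balanced-ANOVA degrees of freedom, shifted-t power, minimal-integer sample-size searches |
| `swssre.estimators` | blinded moment estimators, profiled REML on sufficient statistics, the final one-sided test |
| `swssre.ssre` | the reestimation step and single-trial orchestration |
| `swssre.scenarios`, `swssre.simulation` | scenario descriptors (two worked trial settings included), Monte-Carlo engine, factor grids |
| `swssre.cli` | `swssre samplesize / power / reestimate / simulate` for scripted use |

Short narrative scripts live in `examples/`.

## Worked example

Size the 4-cluster, 5-period roll-out (one cluster switches per period)
for 90% power at a one-sided α = 0.05 against δ = 0.2, assuming
σ_c² = 0.02 and σ_e² = 0.51:

```python
>>> from swssre import (PowerSpec, TwoPhasePlan, VarianceComponents,
...                     fixed_design_n, power, tds1_design)
>>> design = tds1_design()
>>> vc = VarianceComponents(sigma_c2=0.02, sigma_e2=0.51)
>>> spec = PowerSpec(alpha=0.05, beta=0.10, delta=0.2)
>>> fixed_design_n(design, vc, spec)
70
>>> power(TwoPhasePlan.single_phase(design, 70), vc, spec)
0.9010219498688379
>>> power(TwoPhasePlan.single_phase(design, 69), vc, spec)
0.8974602943874048
```

Seventy patients per cluster per period (1,400 in total) is the minimal
integer meeting the target; one fewer drops power below 0.9.

Now let a 20-cluster, 9-period trial (three clusters switching in each of
periods 2–5, two in each of 6–9; true σ_c² = 1/9, σ_e² = 1) be sized from
variances *under-assumed by half*, and compare the blinded reestimation
procedure (after period 5, correction effect τ* = 0) with the
conventional fixed design (`examples/03_operating_characteristics.py`,
1,000 replicates):

```
blinded SSRE (t=5)   n_init=4  empirical power=0.781 (MC SE 0.013)  median N_hat=1440
fixed design         n_init=4  empirical power=0.588 (MC SE 0.016)  median N_hat=720

With the residual variance under-assumed by half, the fixed design is sized
too small and misses its 80% power target; the reestimation procedure
recovers the shortfall mid-trial by enlarging the per-cluster-period sample
size for the remaining periods.
```

The misspecified fixed design recruits 720 patients and reaches only ~59%
power; the blinded procedure roughly doubles recruitment mid-trial and
restores power to near the 80% target, without ever unblinding a
treatment label.

## Command line

```sh
swssre samplesize config.yaml        # minimal n and its power, as CSV
swssre reestimate config.yaml --data interim.csv
swssre simulate config.yaml --replicates 10000 --out oc.csv
```

Configs are YAML/JSON mirrors of the `Scenario` fields; allocation
matrices may be inline, a headerless 0/1 CSV, or one of the shipped
presets (`tds1`, `tds2`).

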