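# Methods

## Model

`swssre` works with cross-sectional stepped-wedge cluster randomized
trials (SW-CRTs) analyzed with the Hussey–Hughes linear mixed model

    Y_ijk = μ + π_j + τ X_ij + c_i + ε_ijk,

where `i = 1..C` indexes clusters, `j = 1..T` time periods, and
`k = 1..n_j` the individuals newly sampled in cluster `i` during period
`j` (cross-sectional: nobody is measured twice).  `π_j` are fixed period
effects with `π_1 = 0`, `τ` is the treatment effect, `X` the binary
allocation matrix, `c_i ~ N(0, σ_c²)` a cluster random intercept shared by
*every* observation the cluster ever contributes, and
`ε_ijk ~ N(0, σ_e²)` independent individual error.  The response
covariance is therefore block diagonal by cluster with compound-symmetry
blocks `σ_e² I_m + σ_c² J_m`; all linear algebra uses the rank-one closed
forms

    (σ_e² I + σ_c² J)⁻¹ = (1/σ_e²)(I − σ_c²/(σ_e² + m σ_c²) J),
    log det = (m−1) log σ_e² + log(σ_e² + m σ_c²),

so no dense covariance matrix is ever materialized on a fitting path
(dense construction exists only in test oracles).  Rows of `X` are not
required to be monotone; non-monotone rows draw a warning because they are
not stepped-wedge-like, but incomplete and unbalanced roll-outs are valid.

## Test, power, and sample size

The one-sided test of `H0: τ ≤ 0` rejects when `T = τ̂ Î^{1/2}` exceeds
the upper-α quantile of a central t distribution with

    ν = n_init C t + n_final C (T − t) − C − T

degrees of freedom — the balanced multilevel-ANOVA count for the realized
per-phase cell sizes (`t = T` collapses it to `n C T − C − T`).  No
Satterthwaite or Kenward–Roger adjustment is applied; with few clusters
this ν is known to be liberal, which is visible in the simulated type-I
error of the 4-cluster setting.

Power at effect δ is evaluated under a *location-shifted central t*
density with mean `δ I^{1/2}` rather than a noncentral t.  At the degrees
of freedom arising here the two differ in the fourth decimal of power, but
the convention is fixed because the integer sample-size searches sit on
knife edges (e.g. the 4-cluster setting needs exactly 70 per cell at its
published variances; 69 gives power 0.8975).

The information `I` for τ is `1/[(D'Σ⁻¹D)⁻¹]_{τ,τ}` assembled over the
*whole* trial: each cluster contributes one compound-symmetry block
covering all `T` periods with per-period cell counts (`n_init` up to the
reestimation period, `n_reest` after).  A tempting alternative is to sum
two per-phase information matrices as if the phases were independent
experiments; that is wrong here, because the cluster intercept correlates
the phases, and the phase-split version materially overstates the
remainder sample size needed in designs whose early periods carry much of
the treatment information.  The unified form equals brute-force dense
construction of the full `(D, Σ)` system to 1e-10 (tested).

Integer searches (`fixed_design_n`, `find_nreest`) exploit verified
monotonicity of power in `n`: doubling then bisection over `[1, n_cap]`,
default cap 1,000.  At the design stage an unreachable power target is an
error; at reestimation the search returns the cap and the clamp takes
over (capping the search at `n_max` is equivalent to searching the global
cap and clamping, which is asserted in tests).

## Interim variance estimation

**Blinded.**  With only cluster and period labels (no individual
treatment indicators), form from periods `1..t`

    S̄² = n/(Ct−t) Σ_i Σ_{j≤t} (Ȳ_ij − Ȳ_·j)²,
    S²  = pooled within-cell SS / (nCt − Ct),

whose expectations are `σ_e² + n σ_c² + n τ² A(X,t)` and `σ_e²`, with the
allocation term `A = Σ_j s_j/(Ct−t) − Σ_j s_j²/(C(Ct−t))` built from the
per-period treated-cluster counts `s_j` of the (public) randomization
schedule.  Inverting the first expectation at an assumed effect `τ*`
gives `f(τ*) = (S̄² − σ̂_e² − n τ*² A)/n`, unbiased for `σ_c²` when `τ*`
equals the true effect (Monte-Carlo checked).  The estimator is

    σ̂_e² = S²;   σ̂_c² = f(τ*)  if f(τ*) > 0,
                  f(0)    if f(τ*) < 0 < f(0),
                  0       otherwise,

the middle branch guarding against an overlarge `τ*` (a truly zero
between-cluster variance being the less plausible reading of a negative
corrected value).  `f` exactly zero falls to the final branch — a
measure-zero tie resolved conservatively.  Two notational points are
resolved in the only dimensionally consistent way: the left 1-vector in
the allocation term has length `C` (so the products are `Σ s_j` and
`Σ s_j²`), and `1/n` divides the whole bracket of `f` — both are forced by
the unbiasedness requirement and verified by simulation.

**Unblinded.**  REML on the accumulated data, with the treatment term
included only if any cell has been treated by period `t` and period
effects only if `t > 1` (four cases).

## REML implementation

REML is profiled over the variance ratio `λ = σ_c²/σ_e²`: for fixed λ,
GLS gives the fixed effects and `σ̂_e²(λ) = RSS_W/(N − p)` in closed form
via the block identities, and the restricted criterion
`(N−p) log σ̂_e² + Σ_i log(1 + λ m_i) + log|D'W⁻¹D|` is minimized by
bounded scalar optimization on `λ ∈ [0, 10³]` (tolerance 1e-8), with the
boundary `λ = 0` always evaluated and preferred on ties — this also
resolves profiles that are exactly flat in λ, such as a single cluster
whose intercept absorbs the random effect.  All fits consume cluster-period
sufficient statistics (cell means, pooled within-cell sums of squares,
cell counts), proven equal to raw-observation GLS quantities at every λ in
the tests, so a fit costs the same whether a cell holds 4 patients or
1,000.  `Var(τ̂)` is the model-based `σ̂_e² [(D'W⁻¹D)⁻¹]_{τ,τ}`; note that
general-purpose mixed-model software sometimes reports a
profiled-Hessian covariance for the fixed effects instead, which is a
different (typically larger) quantity — the tests therefore check point
estimates against `statsmodels.MixedLM` and the variance against dense
GLS linear algebra.

## Reestimation procedure

After period `t` (chosen in `1..T−1`): estimate `(σ̂_c², σ̂_e²)` blinded
or unblinded; find the minimal `n_reest` restoring power `1−β` at those
estimates given that periods `1..t` were run at `n_init`; clamp to the
prespecified `[n_min, n_max]` (with `n_min ≥ 1` the trial always runs to
completion; `n_min = n_max` forces the total); run periods `t+1..T` at
`n_final` for all clusters; test with the mixed-size ν above.  The
cluster count never changes.  Should an unblinded interim REML fail (a
degenerate fit — never observed in the shipped scenarios), the replicate
falls back to the blinded estimator and is flagged rather than dropped,
and fallback counts are reported.

## Synthetic data generator

Data are drawn exactly from the model: one `c_i` per cluster per trial —
persisting across the reestimation boundary, since the model has a single
cluster intercept — and i.i.d. individual errors.  Two equivalent
samplers exist: individual-level responses, and direct draws of the
sufficient statistics (cell mean `N(·, σ_e²/n)`, within-cell SS
`σ_e² χ²_{n−1}`, independent).  The simulation engine uses the direct
form so replicate cost is independent of cell size; agreement of the two
samplers' moments is tested.  Scenario defaults mirror the two shipped
settings: `μ = π_j = 0` (nonzero period effects are supported in the API —
the procedures are only asymptotically invariant to them — but are not
part of the default conditions), true effect `τ ∈ {0, δ}`, clamp
`[1, 1000]`, blinded correction `τ* = 0`.

What the generator does *not* emulate: non-normal outcomes, unequal
cluster sizes within a period, cohort (repeated-measures) sampling,
time-varying cluster effects, or missing cells.  Passing tests therefore
certify the procedures under the exact model, not robustness to these
departures.

## Randomness and reproducibility

Each scenario carries one master seed; replicate `s` runs on an
independent child stream spawned from it (`numpy` `SeedSequence`), so
results are bit-reproducible and phase-1 data are identical when blinded
and unblinded procedures are compared under the same seed.

## Problem sizes and tolerances

Simulation studies in the tests and in `scripts/acceptance.py` use 10⁴
replicates per scenario — enough to pin rejection rates to a binomial
standard error of ~0.004 near power 0.8 and ~0.002 near α — and compare
published rates within three such standard errors; medians of the
realized total sample size are compared within one step of their
attainable grid (`C(T−t)` patients).  Closed-form identities are held to
1e-10 against dense oracles, REML point estimates to 1e-3 against an
independent mixed-model implementation (the restricted criterion itself is
required to be at least as good as the oracle's, since variance
components sit on flat likelihood ridges), and sufficient-statistic
equalities to 1e-8.

## Known limitations

* The balanced-ANOVA ν is anti-conservative with very few clusters; the
  4-cluster setting shows type-I error near 0.06 at nominal 0.05, for the
  fixed design and both reestimation procedures alike.
* One published cell family resists reproduction: the 20-cluster blinded
  procedure with a true effect present and `τ* = 0` is reported with
  noticeably higher power (and a larger median total sample size) than
  the exact model and estimators imply; the discrepancy traces to a
  stronger response of the published remainder sample sizes to the
  blinded σ̂_c² inflation than the true information matrix produces.  The
  corresponding checks are left failing rather than met by altering the
  formulas, and the blinded machinery itself (null-effect cells,
  `τ* = δ` cells, and the 4-cluster setting) reproduces the published
  values.
* Early-stopping rules, reestimation of δ, adding clusters mid-trial,
  and Kenward–Roger or α-adjusted small-sample corrections are out of
  scope.
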