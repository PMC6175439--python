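"""Design-stage power and sample size for a stepped-wedge trial.

Builds the small 4-cluster, 5-period roll-out (one cluster switching per
period), assumes a between-cluster variance of 0.02 and residual variance
0.51, and finds the minimal per-cluster-per-period sample size for 90%
power against a one-sided alternative of delta = 0.2 at alpha = 0.05.
"""

from swssre import (
    PowerSpec,
    TwoPhasePlan,
    VarianceComponents,
    fixed_design_n,
    information_for_tau,
    power,
    tds1_design,
)

design = tds1_design()
vc = VarianceComponents(sigma_c2=0.02, sigma_e2=0.51)
spec = PowerSpec(alpha=0.05, beta=0.10, delta=0.2)

n = fixed_design_n(design, vc, spec)
plan = TwoPhasePlan.single_phase(design, n)

print(f"allocation matrix ({design.C} clusters x {design.T} periods):")
print(design.X)
print(f"ICC rho = {vc.icc:.4f}")
print(f"minimal n per cluster per period: {n}  (total {n * design.C * design.T})")
print(f"information for tau at n = {n}: {information_for_tau(plan, vc):.2f}")
print(f"power at n = {n}:   {power(plan, vc, spec):.4f}")
print(
    f"power at n = {n - 1}: "
    f"{power(TwoPhasePlan.single_phase(design, n - 1), vc, spec):.4f}"
)
print(
    "\nThe returned n is the smallest integer whose one-sided t test of the "
    "treatment effect reaches the target power; one patient fewer per cell "
    "drops power below 90%."
)
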