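"""One blinded mid-trial sample-size reestimation, step by step.

Simulates the first 5 periods of the 20-cluster trial at a design-stage
cell size computed from *under*-assumed variances (half the truth), forms
the treatment-masked mean squares, inverts them into blinded variance
estimates, and searches for the remainder cell size that restores 80%
power.  No individual treatment label is used at any point — only the
publicly known allocation schedule enters, through the bias-correction
term of the between-cluster estimator.
"""

import numpy as np

from swssre import (
    ReestimationControls,
    VarianceComponents,
    blinded_summaries,
    reestimate,
    tds2_scenario,
)
from swssre.generation import draw_cluster_effects, draw_summary

scenario = tds2_scenario(assumed_multipliers=(0.5, 0.5), seed=7)
design, t = scenario.design, scenario.t
print(f"assumed variances: sigma_c2 = {scenario.vc_assumed.sigma_c2:.4f}, "
      f"sigma_e2 = {scenario.vc_assumed.sigma_e2:.4f}")
print(f"true variances:    sigma_c2 = {scenario.vc_true.sigma_c2:.4f}, "
      f"sigma_e2 = {scenario.vc_true.sigma_e2:.4f}")
print(f"design-stage cell size n_init = {scenario.n_init}")

rng = np.random.default_rng(scenario.seed)
c = draw_cluster_effects(design.C, scenario.vc_true, rng)
phase1 = draw_summary(
    design, range(1, t + 1), scenario.n_init, scenario.fixed_effects,
    scenario.vc_true, rng, c,
)

bs = blinded_summaries(phase1, t)
print(f"\nblinded summaries after period {t}:")
print(f"  between-cell mean square S_bar2 = {bs.s_bar2:.4f}")
print(f"  within-cell mean square  S2     = {bs.s2:.4f}")

controls = ReestimationControls(t=t, n_min=1, n_max=1000, blinded=True, tau_star=0.0)
out = reestimate(phase1, design, controls, scenario.n_init, scenario.power_spec)
print(f"\nblinded variance estimates: sigma_c2_hat = {out.vc_hat.sigma_c2:.4f}, "
      f"sigma_e2_hat = {out.vc_hat.sigma_e2:.4f}")
print(f"reestimated remainder cell size: n_reest = {out.n_reest}, "
      f"clamped n_final = {out.n_final}")
print(f"realized total sample size N_hat = "
      f"{out.total_n(design.C, design.T, t, scenario.n_init)}")
print(
    "\nBecause the variances were under-assumed, the interim estimates are "
    "larger than the design assumptions and the remainder of the trial is "
    "run with more patients per cluster-period than initially planned."
)
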