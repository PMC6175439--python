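"""Monte-Carlo operating characteristics of SSRE vs the fixed design.

Simulates the 20-cluster trial with both variance components assumed at
half their true values, comparing the blinded reestimation procedure
(reestimating after period 5) with the conventional fixed design, at a
reduced replicate count so the example runs in a few seconds.
"""

from swssre import simulate_scenario, tds2_scenario

R = 1000  # increase to 10_000+ for publication-grade estimates

ssre = tds2_scenario(assumed_multipliers=(0.5, 0.5), seed=11, replicates=R)
fixed = ssre.with_(t=9, seed=12)  # t = T: no interim, conventional design

for label, sc in [("blinded SSRE (t=5)", ssre), ("fixed design", fixed)]:
    oc = simulate_scenario(sc)
    print(
        f"{label:20s} n_init={oc.n_init}  empirical power={oc.err:.3f} "
        f"(MC SE {oc.mc_se:.3f})  median N_hat={oc.n_hat_median:.0f}"
    )

print(
    "\nWith the residual variance under-assumed by half, the fixed design "
    "is sized too small and misses its 80% power target; the reestimation "
    "procedure recovers the shortfall mid-trial by enlarging the "
    "per-cluster-period sample size for the remaining periods."
)
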