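"""Monte-Carlo operating characteristics of SSRE and fixed SW-CRT designs.

:func:`simulate_scenario` runs independent replicates of
:func:`swssre.ssre.run_trial` and summarizes the empirical rejection rate
(type-I error when the true effect is 0, power when it equals delta), the
distribution of the realized total sample size
``N_hat = n_init C t + n_final C (T - t)``, and the interim variance
estimates.  :func:`run_grid` sweeps factor grids (assumed-variance
multipliers, true effect, blinding, reestimation period, tau_star, clamp
policies) into a long-format table, one row per scenario cell.

Randomness discipline: each scenario carries a master seed; replicate s
runs on an independent child stream spawned from it, so results are
reproducible and phase-1 data are identical across procedures compared
under the same seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd

from .generation import generate_data
from .scenarios import Scenario
from .ssre import run_trial

__all__ = [
    "OperatingCharacteristics",
    "generate_data",
    "simulate_scenario",
    "run_grid",
    "replicate_frame",
]


@dataclass(frozen=True)
class OperatingCharacteristics:
    """Summaries of one simulated scenario."""

    err: float  # empirical rejection rate
    mc_se: float  # binomial standard error sqrt(err (1 - err) / r)
    replicates: int
    n_init: int
    n_hat_median: float
    n_hat_q1: float
    n_hat_q3: float
    sigma_c2_median: float
    sigma_c2_iqr: float
    sigma_e2_median: float
    sigma_e2_iqr: float
    fallback_count: int

    def as_row(self) -> dict:
        return dict(self.__dict__)


def _replicate_rngs(seed: int, r: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(r)]


def replicate_frame(scenario: Scenario, replicates: int | None = None) -> pd.DataFrame:
    """Raw per-replicate records (reject, N_hat, variance estimates, n_final)."""
    r = scenario.replicates if replicates is None else replicates
    recs = [
        run_trial(scenario, rng) for rng in _replicate_rngs(scenario.seed, r)
    ]
    return pd.DataFrame(
        {
            "reject": [rec.reject for rec in recs],
            "n_hat": [rec.total_n for rec in recs],
            "sigma_c2_hat": [rec.sigma_c2_hat for rec in recs],
            "sigma_e2_hat": [rec.sigma_e2_hat for rec in recs],
            "n_final": [rec.n_final for rec in recs],
            "n_reest": [rec.n_reest for rec in recs],
            "used_fallback": [rec.used_fallback for rec in recs],
        }
    )


def summarize(frame: pd.DataFrame, n_init: int) -> OperatingCharacteristics:
    r = len(frame)
    err = float(frame["reject"].mean())
    q1, med, q3 = np.quantile(frame["n_hat"], [0.25, 0.5, 0.75])
    c1, cmed, c3 = np.quantile(frame["sigma_c2_hat"], [0.25, 0.5, 0.75])
    e1, emed, e3 = np.quantile(frame["sigma_e2_hat"], [0.25, 0.5, 0.75])
    return OperatingCharacteristics(
        err=err,
        mc_se=float(np.sqrt(err * (1 - err) / r)),
        replicates=r,
        n_init=n_init,
        n_hat_median=float(med),
        n_hat_q1=float(q1),
        n_hat_q3=float(q3),
        sigma_c2_median=float(cmed),
        sigma_c2_iqr=float(c3 - c1),
        sigma_e2_median=float(emed),
        sigma_e2_iqr=float(e3 - e1),
        fallback_count=int(frame["used_fallback"].sum()),
    )


def simulate_scenario(
    scenario: Scenario,
    replicates: int | None = None,
    return_replicates: bool = False,
):
    """Estimate the scenario's operating characteristics by simulation.

    Deterministic given ``scenario.seed``.  ``replicates`` overrides the
    scenario's own count (the presets default to 10^4).
    """
    frame = replicate_frame(scenario, replicates)
    oc = summarize(frame, scenario.n_init)
    return (oc, frame) if return_replicates else oc


# clamp policies: how (n_min, n_max) are derived from the design-stage n_init
CLAMP_POLICIES = {
    "unrestricted": lambda n_init: (1, 1000),  # no practical limit
    "never_decrease": lambda n_init: (n_init, 1000),  # Wittes-Brittain floor
    "never_increase": lambda n_init: (1, n_init),  # Gould-style ceiling
}


def run_grid(
    base: Scenario,
    assumed_multipliers: Sequence[tuple[float, float]] = ((1.0, 1.0),),
    taus: Sequence[float] | None = None,
    blinded_flags: Sequence[bool] = (True,),
    ts: Sequence[int] | None = None,
    tau_stars: Sequence[float] = (0.0,),
    clamp_policies: Sequence[str] = ("unrestricted",),
    replicates: int | None = None,
) -> pd.DataFrame:
    """Cartesian sweep of scenario factors; one summary row per cell.

    ``assumed_multipliers`` scale the *true* variance components of
    ``base`` to produce the design-stage assumptions.  ``taus`` defaults
    to (0, delta); ``ts`` to the base reestimation period.  ``tau_stars``
    applies to blinded cells only (unblinded cells ignore it and are not
    duplicated across its values).
    """
    taus = (0.0, base.delta) if taus is None else taus
    ts = (base.t,) if ts is None else ts
    rows = []
    for (cm, em), tau, blinded, t, policy in product(
        assumed_multipliers, taus, blinded_flags, ts, clamp_policies
    ):
        stars = tau_stars if blinded else (None,)
        for star in stars:
            sc = base.with_(
                vc_assumed=base.vc_true.scaled(cm, em),
                tau=tau,
                blinded=blinded,
                t=t,
                tau_star=star if blinded else None,
            )
            n_min, n_max = CLAMP_POLICIES[policy](sc.n_init)
            if n_min > n_max:
                continue
            sc = sc.with_(n_min=n_min, n_max=n_max)
            oc = simulate_scenario(sc, replicates)
            rows.append(
                {
                    "sigma_c2_mult": cm,
                    "sigma_e2_mult": em,
                    "tau": tau,
                    "blinded": blinded,
                    "t": t,
                    "tau_star": star,
                    "clamp": policy,
                    **oc.as_row(),
                }
            )
    return pd.DataFrame(rows)
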