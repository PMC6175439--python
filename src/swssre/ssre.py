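"""Mid-trial sample-size reestimation for a stepped-wedge trial.

The procedure: run periods 1..t at the design-stage cell size ``n_init``;
estimate the nuisance variances from the accumulated data (blinded moment
estimators or unblinded interim REML); search for the minimal cell size
``n_reest`` for the remaining periods that restores the target power at
those estimates; clamp it to the prespecified window ``[n_min, n_max]``;
complete periods t+1..T at the clamped ``n_final``; and run the final
one-sided test with the balanced-ANOVA degrees of freedom implied by the
realized per-phase cell sizes.  The number of clusters never changes, and
because ``n_min >= 1`` the trial always runs to completion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

from .design import (
    ClusterPeriodSummary,
    DesignError,
    SWDesign,
    VarianceComponents,
)
from .estimators import (
    AnalysisResult,
    EstimationError,
    blinded_estimate,
    final_test,
    reml_fit,
    select_interim_model,
)
from .generation import draw_cluster_effects, draw_summary
from .power import PowerSpec, dof, find_nreest

if TYPE_CHECKING:  # pragma: no cover
    from .scenarios import Scenario


@dataclass(frozen=True)
class ReestimationControls:
    """Prespecified reestimation rules: period t, clamp window, blinding.

    ``tau_star`` (the effect assumed by the blinded bias correction) is
    required when ``blinded`` and ignored otherwise.
    """

    t: int
    n_min: int = 1
    n_max: int = 1000
    blinded: bool = True
    tau_star: float | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.n_min <= self.n_max:
            raise DesignError("need 1 <= n_min <= n_max")
        if self.blinded and self.tau_star is None:
            raise DesignError("blinded reestimation requires tau_star")


@dataclass(frozen=True)
class ReestimationOutcome:
    """What the interim analysis decided."""

    vc_hat: VarianceComponents
    n_reest: int  # unclamped search result
    n_final: int  # clamped to [n_min, n_max]
    used_fallback: bool  # unblinded REML failed; blinded estimates used

    def total_n(self, C: int, T: int, t: int, n_init: int) -> int:
        return n_init * C * t + self.n_final * C * (T - t)


@dataclass(frozen=True)
class TrialReplicate:
    """Per-replicate record of one simulated SSRE (or fixed) trial."""

    reject: bool
    total_n: int
    sigma_c2_hat: float  # interim estimate (final-fit value for fixed designs)
    sigma_e2_hat: float
    n_final: int
    n_reest: int
    test_stat: float
    used_fallback: bool
    analysis: AnalysisResult


def clamp_n(n_reest: int, n_min: int, n_max: int) -> int:
    """Clamp the reestimated cell size to the prespecified window.

    ``n_min == n_max`` is allowed (a forced cell size, which makes the
    realized total sample size deterministic).
    """
    if n_min > n_max:
        raise DesignError("need n_min <= n_max")
    return min(max(int(n_reest), n_min), n_max)


def reestimate(
    data_through_t,
    design: SWDesign,
    controls: ReestimationControls,
    n_init: int,
    spec: PowerSpec,
) -> ReestimationOutcome:
    """Interim variance estimation plus the remainder sample-size search.

    The search is capped at ``n_max``: searching beyond the ceiling and
    clamping afterwards yields the same ``n_final``, since the minimal
    qualifying integer either lies within the window or exceeds it.

    If the unblinded interim REML fails (a rare degenerate fit), the
    blinded estimators are used instead and the outcome is flagged; a
    replicate is never dropped.
    """
    t = controls.t
    used_fallback = False
    if controls.blinded:
        vc_hat = blinded_estimate(data_through_t, design, t, controls.tau_star)
    else:
        try:
            fit = reml_fit(data_through_t, design, select_interim_model(design, t))
            vc_hat = fit.vc
        except EstimationError:
            vc_hat = blinded_estimate(data_through_t, design, t, 0.0)
            used_fallback = True
    n_reest = find_nreest(design, t, n_init, vc_hat, spec, n_cap=controls.n_max)
    n_final = clamp_n(n_reest, controls.n_min, controls.n_max)
    return ReestimationOutcome(vc_hat, n_reest, n_final, used_fallback)


def run_trial(
    scenario: "Scenario",
    rng: np.random.Generator,
    keep_data: bool = False,
):
    """Simulate one complete trial under the scenario and analyze it.

    Returns a :class:`TrialReplicate`; with ``keep_data=True`` returns
    ``(replicate, full_summary)`` for diagnostics.  A scenario with
    ``t = T`` runs the conventional fixed design (no interim step).
    """
    design = scenario.design
    C, T = design.C, design.T
    t = scenario.t
    n_init = scenario.n_init
    fx = scenario.fixed_effects
    c_i = draw_cluster_effects(C, scenario.vc_true, rng)
    phase1 = draw_summary(
        design, range(1, t + 1), n_init, fx, scenario.vc_true, rng, c_i
    )
    if t < T:
        controls = ReestimationControls(
            t=t,
            n_min=scenario.n_min,
            n_max=scenario.n_max,
            blinded=scenario.blinded,
            tau_star=scenario.tau_star,
        )
        outcome = reestimate(
            phase1, design, controls, n_init, scenario.power_spec
        )
        n_final = outcome.n_final
        phase2 = draw_summary(
            design, range(t + 1, T + 1), n_final, fx, scenario.vc_true, rng, c_i
        )
        full = ClusterPeriodSummary.concat(phase1, phase2)
    else:
        outcome = None
        n_final = n_init
        full = phase1

    nu = dof(C, T, t, n_init, n_final)
    result = final_test(full, design, scenario.alpha, nu)
    total_n = n_init * C * t + n_final * C * (T - t)
    interim_vc = outcome.vc_hat if outcome is not None else None
    rec = TrialReplicate(
        reject=result.reject,
        total_n=total_n,
        sigma_c2_hat=(
            interim_vc.sigma_c2 if interim_vc is not None else result.sigma_c2_hat
        ),
        sigma_e2_hat=(
            interim_vc.sigma_e2 if interim_vc is not None else result.sigma_e2_hat
        ),
        n_final=n_final,
        n_reest=outcome.n_reest if outcome is not None else n_init,
        test_stat=result.test_stat,
        used_fallback=outcome.used_fallback if outcome is not None else False,
        analysis=result,
    )
    return (rec, full) if keep_data else rec
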