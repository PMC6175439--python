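"""Power and sample-size calculation for the Hussey-Hughes SW-CRT model.

The treatment-effect information ``I`` is taken from the model-based
covariance of the GLS/ML estimator of the fixed effects over the whole
trial,

    I = 1 / [ (D' Sigma^{-1} D)^{-1} ]_{tau,tau},

where each cluster contributes one compound-symmetry covariance block
spanning all T periods with per-period cell counts (n_init up to the
reestimation period, n_reest after) — the cluster random effect correlates
the two recruitment phases, so they are never treated as independent
experiments.  Blocks are applied through the rank-one inverse, so no
dense covariance matrix is ever formed.  The final one-sided test of
H0: tau <= 0 rejects when T = tau_hat * I_hat^{1/2} exceeds the upper-alpha
quantile of a t distribution whose degrees of freedom are those of the
corresponding balanced multilevel ANOVA,

    nu = n_init C t + n_reest C (T - t) - C - T,

and power at effect delta is evaluated under a location-shifted central t
density with mean delta * I^{1/2} (not a noncentral t; at the degrees of
freedom arising in practice the two are nearly indistinguishable, but the
shifted-t convention is what the sample sizes in this package reproduce).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

from .design import (
    SWDesign,
    VarianceComponents,
    cell_design_rows,
)


class PowerError(ValueError):
    """Power or sample-size calculation is not defined for the arguments."""


@dataclass(frozen=True)
class PowerSpec:
    """Operating-characteristic targets: one-sided alpha, type-II rate beta,
    and the clinically relevant effect delta > 0 to power for."""

    alpha: float
    beta: float
    delta: float

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise PowerError("alpha must lie in (0, 1)")
        if not 0 < self.beta < 1:
            raise PowerError("beta must lie in (0, 1)")
        if not self.delta > 0:
            raise PowerError("delta must be > 0")


@dataclass(frozen=True)
class TwoPhasePlan:
    """Recruitment plan: n_init per cell in periods 1..t, n_reest after.

    ``t = T`` denotes a single-phase (conventional) design, in which case
    ``n_reest`` is ignored.
    """

    design: SWDesign
    t: int
    n_init: int
    n_reest: int | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.t <= self.design.T:
            raise PowerError("reestimation period t must lie in 1..T")
        if self.n_init < 1:
            raise PowerError("n_init must be >= 1")
        if self.t < self.design.T:
            if self.n_reest is None or self.n_reest < 1:
                raise PowerError("n_reest must be >= 1 when t < T")

    @classmethod
    def single_phase(cls, design: SWDesign, n: int) -> "TwoPhasePlan":
        return cls(design, design.T, n)


def plan_information(plan: TwoPhasePlan, vc: VarianceComponents) -> np.ndarray:
    """M = D' Sigma^{-1} D over the whole trial for the full theta layout.

    The cluster random effect spans every period of the trial, so each
    cluster contributes a single compound-symmetry block covering all T
    periods with per-period cell counts (n_init before/at t, n_reest
    after); the two recruitment phases are correlated within a cluster and
    must not be treated as independent datasets.  Assembled with the
    rank-one block inverse, so cost is independent of the cell sizes.
    """
    d = plan.design
    counts = _plan_counts(plan)
    A = cell_design_rows(d, range(1, d.T + 1), range(2, d.T + 1), True)
    return _cluster_information(A, counts, vc)


def _plan_counts(plan: TwoPhasePlan) -> np.ndarray:
    T = plan.design.T
    n2 = plan.n_init if plan.t == T else plan.n_reest
    return np.array(
        [plan.n_init] * plan.t + [n2] * (T - plan.t), dtype=float
    )


def _cluster_information(
    A: np.ndarray, counts: np.ndarray, vc: VarianceComponents
) -> np.ndarray:
    """Sum of D_i' Sigma_i^{-1} D_i from cell rows and per-period counts."""
    m = counts.sum()
    G = np.einsum("j,cja,cjb->ab", counts, A, A)
    h = np.einsum("j,cja->ca", counts, A)  # (C, p): per-cluster D_i' 1
    c = vc.sigma_c2 / (vc.sigma_e2 * (vc.sigma_e2 + m * vc.sigma_c2))
    return G / vc.sigma_e2 - c * (h.T @ h)


def information_for_tau(plan: TwoPhasePlan, vc: VarianceComponents) -> float:
    """Information for tau: inverse of the (tau, tau) entry of M^{-1}."""
    return _tau_information(plan_information(plan, vc))


def _tau_information(M: np.ndarray) -> float:
    try:
        cov = np.linalg.inv(M)
    except np.linalg.LinAlgError as err:
        raise PowerError(
            "summed information matrix is singular: the design does not "
            "identify all fixed effects (rank deficiency in the period or "
            "treatment columns)"
        ) from err
    var_tau = cov[-1, -1]
    if not var_tau > 0 or not np.isfinite(var_tau):
        raise PowerError("non-positive variance for tau: rank-deficient design")
    return 1.0 / var_tau


def dof(C: int, T: int, t: int, n_init: int, n_reest: int) -> int:
    """Balanced multilevel-ANOVA degrees of freedom for the final test."""
    if min(C, T, t, n_init, n_reest) < 1 or t > T:
        raise PowerError("dof arguments must be positive with t <= T")
    nu = n_init * C * t + n_reest * C * (T - t) - C - T
    if nu <= 0:
        raise PowerError(f"degrees of freedom {nu} <= 0: test not defined")
    return nu


def critical_value(alpha: float, nu: int) -> float:
    """Upper-alpha quantile of the central t distribution with nu dof."""
    if nu < 1:
        raise PowerError("degrees of freedom must be >= 1")
    if not 0 < alpha < 1:
        raise PowerError("alpha must lie in (0, 1)")
    return float(special.stdtrit(nu, 1.0 - alpha))


def rejection_probability(
    plan: TwoPhasePlan, vc: VarianceComponents, alpha: float, delta: float
) -> float:
    """P(reject H0 | tau = delta) for the plan; delta = 0 gives exactly alpha."""
    info = information_for_tau(plan, vc)
    n_reest = plan.n_init if plan.t == plan.design.T else plan.n_reest
    nu = dof(plan.design.C, plan.design.T, plan.t, plan.n_init, n_reest)
    return _power_from_info(info, nu, alpha, delta)


def power(plan: TwoPhasePlan, vc: VarianceComponents, spec: PowerSpec) -> float:
    """Power at the clinically relevant effect, under the shifted-t convention."""
    return rejection_probability(plan, vc, spec.alpha, spec.delta)


def _power_from_info(info: float, nu: int, alpha: float, delta: float) -> float:
    e = critical_value(alpha, nu)
    # P(X > e) for X = delta * sqrt(I) + t_nu
    return float(special.stdtr(nu, delta * np.sqrt(info) - e))


def find_nreest(
    design: SWDesign,
    t: int,
    n_init: int,
    vc_hat: VarianceComponents,
    spec: PowerSpec,
    n_cap: int = 1000,
) -> int:
    """Minimal integer n for periods t+1..T achieving power >= 1 - beta.

    Returns ``n_cap`` when even the cap fails to reach the target (the
    caller clamps to its own ceiling, which yields the same final sample
    size).  Power is monotone non-decreasing in n, so the search doubles
    then bisects.
    """
    if not 1 <= t < design.T:
        raise PowerError("reestimation requires 1 <= t < T")
    if n_cap < 1:
        raise PowerError("n_cap must be >= 1")
    C, T = design.C, design.T
    A = cell_design_rows(design, range(1, T + 1), range(2, T + 1), True)
    phase1 = np.array([float(n_init)] * t + [0.0] * (T - t))
    phase2_unit = np.array([0.0] * t + [1.0] * (T - t))
    # G and h are linear in the per-period counts, so precompute the phase
    # pieces and assemble per candidate n without re-running the einsums
    G1 = np.einsum("j,cja,cjb->ab", phase1, A, A)
    G2 = np.einsum("j,cja,cjb->ab", phase2_unit, A, A)
    h1 = np.einsum("j,cja->ca", phase1, A)
    h2 = np.einsum("j,cja->ca", phase2_unit, A)
    sc2, se2 = vc_hat.sigma_c2, vc_hat.sigma_e2

    def achieves(n: int) -> bool:
        m = n_init * t + n * (T - t)
        h = h1 + n * h2
        c = sc2 / (se2 * (se2 + m * sc2))
        M = (G1 + n * G2) / se2 - c * (h.T @ h)
        info = _tau_information(M)
        nu = dof(C, T, t, n_init, n)
        return _power_from_info(info, nu, spec.alpha, spec.delta) >= 1 - spec.beta

    return _minimal_integer(achieves, n_cap)


def fixed_design_n(
    design: SWDesign,
    vc_assumed: VarianceComponents,
    spec: PowerSpec,
    n_cap: int = 1000,
) -> int:
    """Design-stage sample size: minimal per-cluster-per-period n for a
    conventional (single-phase) SW-CRT to reach power 1 - beta.

    Raises :class:`PowerError` if no n <= n_cap suffices; at the design
    stage an unreachable target is a specification problem, not something
    to clamp.
    """

    def achieves(n: int) -> bool:
        return power(TwoPhasePlan.single_phase(design, n), vc_assumed, spec) >= (
            1 - spec.beta
        )

    n = _minimal_integer(achieves, n_cap, skip_small_dof=True)
    if not achieves(n):
        raise PowerError(
            f"target power {1 - spec.beta} unreachable with n <= {n_cap}"
        )
    return n


def _minimal_integer(achieves, n_cap: int, skip_small_dof: bool = False) -> int:
    """Smallest n in [1, n_cap] with achieves(n), else n_cap.

    ``skip_small_dof`` treats n whose test is undefined (nu <= 0) as
    failing rather than erroring, so design-stage searches can start at 1.
    """

    def ok(n: int) -> bool:
        try:
            return achieves(n)
        except PowerError:
            if skip_small_dof:
                return False
            raise

    lo, hi = 1, 1
    while not ok(hi):
        if hi >= n_cap:
            return n_cap
        lo = hi + 1
        hi = min(2 * hi, n_cap)
    # invariant: ok(hi), not ok(lo - 1)
    while lo < hi:
        mid = (lo + hi) // 2
        if ok(mid):
            hi = mid
        else:
            lo = mid + 1
    return lo
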