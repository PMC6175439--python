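"""Variance-component estimation and the final hypothesis test.

Two interim estimation routes are provided for the nuisance variances of
the Hussey-Hughes model:

* **Blinded** (:func:`blinded_estimate`): moment estimators built from two
  treatment-masked summaries of the first ``t`` periods — the between-cell
  mean square ``S_bar2`` of cell means around period means and the pooled
  within-cell mean square ``S2``.  Their expectations are

      E[S_bar2] = sigma_e^2 + n sigma_c^2
                  + n tau^2 [ sum_j s_j / (Ct - t) - sum_j s_j^2 / (C(Ct - t)) ],
      E[S2]     = sigma_e^2,

  where ``s_j`` are the per-period treated-cluster counts (publicly known
  from the allocation schedule; individual treatment labels are never
  used).  Inverting the first expectation at an assumed effect ``tau*``
  gives the bias-corrected moment estimator ``f``; a three-branch rule
  keeps the between-cluster estimate non-negative while guarding against
  overcorrection when ``tau*`` overstates the true effect.

* **Unblinded** (:func:`reml_fit` on :func:`select_interim_model`): REML on
  the accumulated data, with the treatment term included only if any cell
  has been treated by period ``t`` and period effects only if ``t > 1``.

REML is implemented by profiling the variance ratio
``lambda = sigma_c^2 / sigma_e^2``: for fixed lambda, GLS gives the fixed
effects and the residual variance in closed form through the
compound-symmetry rank-one identities, and the restricted log-likelihood is
maximized over lambda in [0, 1e3] by bounded scalar optimization with the
boundary lambda = 0 checked explicitly.  All fits consume cluster-period
sufficient statistics, so the cost per fit does not grow with the
per-cell sample size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .design import (
    ClusterPeriodSummary,
    SWDesign,
    TrialDataset,
    VarianceComponents,
    cell_design_rows,
    per_period_treated,
    treated_cell_count,
)
from .power import critical_value

LAMBDA_MAX = 1e3
_PROFILE_XATOL = 1e-8


class EstimationError(RuntimeError):
    """An estimator is undefined or failed on the given data."""


@dataclass(frozen=True)
class BlindedSummaries:
    """Treatment-masked mean squares from periods 1..t.

    ``s_bar2`` is the between-cell mean square S_bar^2_{Ct-t}; ``s2`` the
    pooled within-cell mean square S^2_{Ct}.
    """

    s_bar2: float
    s2: float
    t: int
    n: int


@dataclass(frozen=True)
class InterimModelSpec:
    """Which fixed-effect terms the interim REML model carries."""

    include_treatment: bool
    include_periods: bool


@dataclass(frozen=True)
class REMLFit:
    """A restricted-maximum-likelihood fit of a random-intercept model."""

    theta: np.ndarray
    term_names: tuple[str, ...]
    vc: VarianceComponents
    lambda_hat: float
    tau_hat: float | None
    var_tau: float | None
    reml_criterion: float  # -2 * restricted log-likelihood, up to a constant


@dataclass(frozen=True)
class AnalysisResult:
    """The final one-sided test of H0: tau <= 0."""

    tau_hat: float
    info_hat: float  # I_hat = 1 / Var(tau_hat)
    sigma_c2_hat: float
    sigma_e2_hat: float
    test_stat: float  # T = tau_hat * I_hat^{1/2}
    nu: int
    crit: float
    reject: bool


def _as_summary(data) -> ClusterPeriodSummary:
    if isinstance(data, ClusterPeriodSummary):
        return data
    if isinstance(data, TrialDataset):
        return ClusterPeriodSummary.from_dataset(data)
    raise TypeError("expected TrialDataset or ClusterPeriodSummary")


def blinded_summaries(data, t: int) -> BlindedSummaries:
    """Compute S_bar^2 and S^2 from periods 1..t without any treatment labels.

    Requires C >= 2 clusters and a common per-cell count n >= 2 (the
    within-cell variance is undefined for singleton cells).
    """
    s = _as_summary(data).restrict(range(1, t + 1))
    C = s.C
    if C < 2:
        raise EstimationError("blinded summaries need at least 2 clusters")
    n_vals = np.unique(s.counts)
    if len(n_vals) != 1:
        raise EstimationError("blinded summaries require a common cell count")
    n = int(n_vals[0])
    if n < 2:
        raise EstimationError(
            "within-cell variance undefined: need n >= 2 per cell"
        )
    dev = s.means - s.period_means()[None, :]
    s_bar2 = n * (dev**2).sum() / (C * t - t)
    s2 = s.ssw.sum() / (n * C * t - C * t)
    return BlindedSummaries(float(s_bar2), float(s2), t, n)


def f_function(
    s_bar2: float,
    sigma_e2: float,
    design: SWDesign,
    t: int,
    n: int,
    tau: float,
) -> float:
    """Bias-corrected moment estimator of sigma_c^2 at assumed effect tau.

    f = (1/n) [ S_bar^2 - sigma_e^2
                - n tau^2 ( sum_j s_j / (Ct - t) - sum_j s_j^2 / (C(Ct - t)) ) ]

    with s_j the treated-cluster count in period j of the (public)
    allocation schedule; unbiased for sigma_c^2 when tau equals the true
    effect.
    """
    C = design.C
    if C * t - t <= 0:
        raise EstimationError("f requires Ct - t > 0, i.e. C >= 2")
    s = per_period_treated(design, t).astype(float)
    alloc = s.sum() / (C * t - t) - (s**2).sum() / (C * (C * t - t))
    return (s_bar2 - sigma_e2 - n * tau**2 * alloc) / n


def blinded_estimate(
    data, design: SWDesign, t: int, tau_star: float
) -> VarianceComponents:
    """Blinded variance estimates via the three-branch non-negativity rule.

    sigma_e2_hat = S^2 always; sigma_c2_hat is f(tau*) when positive, else
    f(0) when f(tau*) < 0 < f(0) (a negative corrected value more likely
    signals an overlarge tau* than a truly zero between-cluster variance),
    else 0.
    """
    bs = blinded_summaries(data, t)
    sigma_e2 = bs.s2
    f_star = f_function(bs.s_bar2, sigma_e2, design, t, bs.n, tau_star)
    if f_star > 0:
        sigma_c2 = f_star
    else:
        f0 = f_function(bs.s_bar2, sigma_e2, design, t, bs.n, 0.0)
        sigma_c2 = f0 if (f_star < 0 < f0) else 0.0
    return VarianceComponents(sigma_c2, max(sigma_e2, np.finfo(float).tiny))


def select_interim_model(design: SWDesign, t: int) -> InterimModelSpec:
    """Interim fixed-effect terms: treatment iff any cell treated by t,
    period effects iff t > 1."""
    return InterimModelSpec(
        include_treatment=treated_cell_count(design, t) > 0,
        include_periods=t > 1,
    )


def reml_fit(
    data,
    design: SWDesign,
    model: InterimModelSpec | None = None,
) -> REMLFit:
    """REML for the random-intercept model on the observed periods.

    ``model=None`` fits the full analysis model (all period effects plus
    the treatment term).  Returns ``Var(tau_hat)`` from the model-based
    covariance ``sigma_e2_hat [ (D' W^{-1} D)^{-1} ]_{tau,tau}`` whenever
    the treatment term is present.
    """
    s = _as_summary(data)
    if model is None:
        model = InterimModelSpec(include_treatment=True, include_periods=True)
    periods = list(s.periods)
    pi_periods = [j for j in periods if j >= 2] if model.include_periods else []
    A = cell_design_rows(design, periods, pi_periods, model.include_treatment)
    names = ["mu"] + [f"pi_{j}" for j in pi_periods] + (
        ["tau"] if model.include_treatment else []
    )
    C, P, p = A.shape
    counts = s.counts.astype(float)
    N = C * counts.sum()
    if N - p <= 0:
        raise EstimationError("not enough observations for REML")
    rows = (A * np.sqrt(counts)[None, :, None]).reshape(-1, p)
    if np.linalg.matrix_rank(rows) < p:
        raise EstimationError(
            "rank-deficient fixed effects: model terms not identifiable "
            "on the observed periods"
        )

    # per-cluster accumulators; the J-shrinkage coefficient is a scalar
    # because cell counts are shared across clusters
    G = np.einsum("j,cja,cjb->ab", counts, A, A)
    h = np.einsum("j,cja->ca", counts, A)  # (C, p)
    g = np.einsum("j,cj,cja->a", counts, s.means, A)
    ysum = (counts[None, :] * s.means).sum(axis=1)  # (C,)
    q_tot = float((counts[None, :] * s.means**2).sum() + s.ssw.sum())
    m = float(counts.sum())  # observations per cluster

    hth = h.T @ h
    hy = h.T @ ysum
    y2 = float(ysum @ ysum)

    def components(lam: float):
        c = lam / (1.0 + lam * m)
        M = G - c * hth
        v = g - c * hy
        ssq = q_tot - c * y2
        return M, v, ssq

    def objective(lam: float) -> float:
        M, v, ssq = components(lam)
        sign, logdet_m = np.linalg.slogdet(M)
        if sign <= 0:
            return np.inf
        theta = np.linalg.solve(M, v)
        rss = ssq - theta @ v
        if rss <= 0:
            return np.inf
        sigma_e2 = rss / (N - p)
        return (
            (N - p) * np.log(sigma_e2)
            + C * np.log1p(lam * m)
            + logdet_m
        )

    res = minimize_scalar(
        objective,
        bounds=(0.0, LAMBDA_MAX),
        method="bounded",
        options={"xatol": _PROFILE_XATOL},
    )
    # the boundary lambda = 0 is always a candidate, and preferred on ties
    # (covers profiles that are flat in lambda, e.g. a single cluster)
    obj0 = objective(0.0)
    if obj0 <= res.fun + 1e-9:
        lam, crit = 0.0, obj0
    else:
        lam, crit = float(res.x), float(res.fun)
    if not np.isfinite(crit):
        raise EstimationError(
            "REML profile search failed: restricted likelihood degenerate "
            f"(criterion at lambda=0: {obj0}, at optimizer point: {res.fun})"
        )

    M, v, ssq = components(lam)
    theta = np.linalg.solve(M, v)
    rss = ssq - theta @ v
    sigma_e2 = rss / (N - p)
    vc = VarianceComponents(lam * sigma_e2, sigma_e2)
    tau_hat = var_tau = None
    if model.include_treatment:
        tau_hat = float(theta[-1])
        var_tau = float(sigma_e2 * np.linalg.inv(M)[-1, -1])
    return REMLFit(
        theta=theta,
        term_names=tuple(names),
        vc=vc,
        lambda_hat=lam,
        tau_hat=tau_hat,
        var_tau=var_tau,
        reml_criterion=float(crit),
    )


def final_test(data, design: SWDesign, alpha: float, nu: int) -> AnalysisResult:
    """Fit the full model by REML and test H0: tau <= 0 one-sided.

    ``nu`` is supplied by the caller (the balanced-ANOVA degrees of
    freedom for the realized per-phase sample sizes).
    """
    fit = reml_fit(data, design, model=None)
    if fit.var_tau is None or fit.var_tau <= 0:
        raise EstimationError("treatment effect variance not available")
    info_hat = 1.0 / fit.var_tau
    test_stat = fit.tau_hat * np.sqrt(info_hat)
    crit = critical_value(alpha, nu)
    return AnalysisResult(
        tau_hat=fit.tau_hat,
        info_hat=info_hat,
        sigma_c2_hat=fit.vc.sigma_c2,
        sigma_e2_hat=fit.vc.sigma_e2,
        test_stat=float(test_stat),
        nu=nu,
        crit=float(crit),
        reject=bool(test_stat > crit),
    )
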