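"""Blinded moment estimators, REML, and the final hypothesis test."""

import numpy as np
import pandas as pd
import pytest

from swssre import (
    ClusterPeriodSummary,
    EstimationError,
    FixedEffects,
    SWDesign,
    TrialDataset,
    VarianceComponents,
    blinded_estimate,
    blinded_summaries,
    f_function,
    final_test,
    generate_data,
    per_period_treated,
    reml_fit,
    select_interim_model,
)
from swssre.estimators import InterimModelSpec
from swssre.generation import draw_cluster_effects, draw_summary


def _criterion_at(data, design, lam):
    """Profiled restricted -2 log-likelihood (up to constant) at a given
    variance ratio, computed independently of the fitting routine."""
    from swssre.design import cell_design_rows

    summ = ClusterPeriodSummary.from_dataset(data)
    T = design.T
    A = cell_design_rows(design, list(summ.periods), [j for j in summ.periods if j >= 2], True)
    counts = summ.counts.astype(float)
    C, _, p = A.shape
    G = np.einsum("j,cja,cjb->ab", counts, A, A)
    h = np.einsum("j,cja->ca", counts, A)
    g = np.einsum("j,cj,cja->a", counts, summ.means, A)
    ysum = (counts * summ.means).sum(axis=1)
    q = float((counts * summ.means**2).sum() + summ.ssw.sum())
    m = counts.sum()
    N = C * m
    c = lam / (1 + lam * m)
    M = G - c * (h.T @ h)
    v = g - c * (h.T @ ysum)
    theta = np.linalg.solve(M, v)
    rss = q - c * (ysum @ ysum) - theta @ v
    return (
        (N - p) * np.log(rss / (N - p))
        + C * np.log1p(lam * m)
        + np.linalg.slogdet(M)[1]
    )


def small_dataset(rng, C=4, T=3, n=4, sc2=0.15, se2=0.8, tau=0.3):
    d = SWDesign.from_switch_periods(list(rng.integers(2, T + 1, size=C)), T=T)
    fx = FixedEffects(mu=0.5, pi=rng.normal(0, 0.2, T - 1), tau=tau)
    vc = VarianceComponents(sc2, se2)
    return d, generate_data(d, range(1, T + 1), n, fx, vc, rng)


class TestBlindedSummaries:
    def test_hand_computed_two_cluster_example(self):
        data = TrialDataset({1: np.array([[0.0, 0.0], [2.0, 2.0]])})
        bs = blinded_summaries(data, t=1)
        # cell means 0 and 2, period mean 1: S_bar2 = 2 * (1 + 1) / (2 - 1)
        assert bs.s_bar2 == pytest.approx(4.0)
        assert bs.s2 == pytest.approx(0.0)

    def test_constant_responses_give_zero_mean_squares(self):
        data = TrialDataset({j: np.full((3, 2), 7.0) for j in (1, 2)})
        bs = blinded_summaries(data, t=2)
        assert bs.s_bar2 == 0.0 and bs.s2 == 0.0

    def test_singleton_cells_rejected(self):
        data = TrialDataset({1: np.array([[1.0], [2.0]])})
        with pytest.raises(EstimationError, match="n >= 2"):
            blinded_summaries(data, 1)

    def test_single_cluster_rejected(self):
        data = TrialDataset({1: np.array([[1.0, 2.0]])})
        with pytest.raises(EstimationError, match="clusters"):
            blinded_summaries(data, 1)

    def test_invariant_to_cluster_relabelling(self, rng):
        d, data = small_dataset(rng)
        bs = blinded_summaries(data, 3)
        perm = rng.permutation(d.C)
        shuffled = TrialDataset({j: arr[perm] for j, arr in data.y.items()})
        bs2 = blinded_summaries(shuffled, 3)
        assert bs2.s_bar2 == pytest.approx(bs.s_bar2)
        assert bs2.s2 == pytest.approx(bs.s2)

    def test_expectations_by_monte_carlo(self, rng):
        # E[S2] = sigma_e2 and E[S_bar2] = sigma_e2 + n sigma_c2 at tau = 0
        d = SWDesign.from_switch_periods([2, 3, 3, 4, 4], T=4)
        vc = VarianceComponents(0.3, 1.2)
        fx = FixedEffects(mu=1.0, pi=np.array([0.5, -0.3, 0.2]), tau=0.0)
        n, t, R = 5, 3, 10_000
        s2s = np.empty(R)
        sbar2s = np.empty(R)
        for r in range(R):
            c = draw_cluster_effects(d.C, vc, rng)
            summ = draw_summary(d, range(1, t + 1), n, fx, vc, rng, c)
            bs = blinded_summaries(summ, t)
            s2s[r], sbar2s[r] = bs.s2, bs.s_bar2
        assert abs(s2s.mean() - 1.2) < 3 * s2s.std() / np.sqrt(R)
        assert abs(sbar2s.mean() - (1.2 + 5 * 0.3)) < 3 * sbar2s.std() / np.sqrt(R)


class TestFFunction:
    def test_zero_effect_reduces_to_moment_difference(self, tds1):
        f = f_function(3.0, 1.0, tds1, t=3, n=5, tau=0.0)
        assert f == pytest.approx((3.0 - 1.0) / 5)

    def test_algebraic_inversion_recovers_sigma_c2(self, tds2):
        C, t, n, tau, se2, sc2 = tds2.C, 5, 7, 0.31, 0.9, 0.22
        s = per_period_treated(tds2, t).astype(float)
        alloc = s.sum() / (C * t - t) - (s**2).sum() / (C * (C * t - t))
        s_bar2 = se2 + n * sc2 + n * tau**2 * alloc
        assert f_function(s_bar2, se2, tds2, t, n, tau) == pytest.approx(sc2)

    def test_unbiased_when_assumed_effect_is_true(self, tds2, rng):
        # tau* = tau = delta: E[f] = sigma_c2
        vc = VarianceComponents(1 / 9, 1.0)
        delta = 0.267
        fx = FixedEffects.null(9, tau=delta)
        n, t, R = 4, 5, 10_000
        fs = np.empty(R)
        for r in range(R):
            c = draw_cluster_effects(tds2.C, vc, rng)
            summ = draw_summary(tds2, range(1, t + 1), n, fx, vc, rng, c)
            bs = blinded_summaries(summ, t)
            fs[r] = f_function(bs.s_bar2, bs.s2, tds2, t, n, delta)
        assert abs(fs.mean() - 1 / 9) < 3 * fs.std() / np.sqrt(R)


class TestBlindedEstimate:
    def make_summary(self, s_bar2, s2, C=4, t=3, n=5):
        """Summary whose blinded mean squares equal (s_bar2, s2) exactly."""
        z = np.zeros(C)
        z[0] = np.sqrt(s_bar2 * (C * t - t) / (n * t) * C / (C - 1))
        z -= z.mean()
        means = np.tile(z[:, None], (1, t))
        ssw = np.full((C, t), s2 * (n * C * t - C * t) / (C * t))
        return ClusterPeriodSummary(tuple(range(1, t + 1)), [n] * t, means, ssw)

    def test_first_branch_positive_corrected_estimate(self, tds1):
        summ = self.make_summary(s_bar2=3.0, s2=1.0)
        vc = blinded_estimate(summ, tds1, 3, tau_star=0.0)
        assert vc.sigma_e2 == pytest.approx(1.0)
        assert vc.sigma_c2 == pytest.approx((3.0 - 1.0) / 5)

    def test_second_branch_falls_back_to_uncorrected(self, tds1):
        # pick tau* so large that f(tau*) < 0 < f(0)
        summ = self.make_summary(s_bar2=1.5, s2=1.0)
        vc = blinded_estimate(summ, tds1, 3, tau_star=5.0)
        assert vc.sigma_c2 == pytest.approx((1.5 - 1.0) / 5)

    def test_third_branch_truncates_at_zero(self, tds1):
        summ = self.make_summary(s_bar2=0.5, s2=1.0)  # f(0) < 0
        vc = blinded_estimate(summ, tds1, 3, tau_star=0.0)
        assert vc.sigma_c2 == 0.0


class TestInterimModelSelection:
    def test_treatment_and_periods_included_mid_rollout(self, tds1):
        m = select_interim_model(tds1, 3)
        assert m.include_treatment and m.include_periods

    def test_first_period_before_any_switch(self, tds1):
        m = select_interim_model(tds1, 1)
        assert not m.include_treatment and not m.include_periods

    def test_control_only_design_keeps_periods_only(self):
        d = SWDesign(np.zeros((3, 4)))
        m = select_interim_model(d, 3)
        assert not m.include_treatment and m.include_periods


class TestREML:
    @pytest.mark.parametrize("seed", [1, 2, 3, 4])
    def test_agrees_with_statsmodels_mixedlm(self, seed):
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(seed)
        d, data = small_dataset(rng, C=5, T=4, n=5, sc2=0.2, se2=1.0, tau=0.4)
        fit = reml_fit(data, d)

        rows = []
        for j, arr in data.y.items():
            for i in range(arr.shape[0]):
                for y in arr[i]:
                    rows.append((i, j, y, d.X[i, j - 1]))
        df = pd.DataFrame(rows, columns=["cluster", "period", "y", "x"])
        m = smf.mixedlm("y ~ C(period) + x", df, groups=df["cluster"]).fit(
            reml=True
        )
        assert fit.tau_hat == pytest.approx(m.params["x"], rel=1e-4, abs=1e-6)
        assert fit.vc.sigma_e2 == pytest.approx(m.scale, rel=1e-3)
        # variance components sit on a flat ridge of the restricted
        # likelihood, so optimizers stop at slightly different points;
        # require close agreement plus a criterion at least as good as the
        # oracle's (profile evaluated at the oracle's lambda)
        assert fit.vc.sigma_c2 == pytest.approx(
            float(m.cov_re.iloc[0, 0]), rel=1e-3, abs=1e-5
        )
        lam_oracle = float(m.cov_re.iloc[0, 0]) / m.scale
        refit = reml_fit(data, d)
        assert refit.reml_criterion <= _criterion_at(data, d, lam_oracle) + 1e-6
        # Var(tau_hat) against the model-based dense GLS covariance at the
        # oracle's own estimates (statsmodels reports a profiled-Hessian
        # covariance for fixed effects, which is a different quantity)
        from swssre.design import design_matrix

        D = design_matrix(d, range(1, d.T + 1), data.n(1))
        mblk = d.T * data.n(1)
        V = m.scale * np.eye(mblk) + float(m.cov_re.iloc[0, 0]) * np.ones(
            (mblk, mblk)
        )
        Vinv = np.linalg.inv(V)
        M = sum(
            D[i * mblk : (i + 1) * mblk].T @ Vinv @ D[i * mblk : (i + 1) * mblk]
            for i in range(d.C)
        )
        dense_var = np.linalg.inv(M)[-1, -1]
        assert fit.var_tau == pytest.approx(dense_var, rel=1e-3)

    def test_sufficient_statistics_match_raw_gls_quantities(self, rng):
        # the profiled criterion's ingredients (D'W^-1 D, D'W^-1 y, RSS_W)
        # computed from cell summaries must equal the raw-observation
        # dense computation at every lambda
        d, data = small_dataset(rng, C=3, T=3, n=4)
        summ = ClusterPeriodSummary.from_dataset(data)
        from swssre.design import design_matrix
        from swssre.estimators import _as_summary

        D = design_matrix(d, range(1, 4), 4)
        y = np.concatenate(
            [np.concatenate([data.y[j][i] for j in (1, 2, 3)]) for i in range(3)]
        )
        mblk = 12
        for lam in (0.0, 0.05, 0.4, 2.0):
            W1 = np.eye(mblk) + lam * np.ones((mblk, mblk))
            Winv = np.kron(np.eye(3), np.linalg.inv(W1))
            M_raw = D.T @ Winv @ D
            v_raw = D.T @ Winv @ y
            theta = np.linalg.solve(M_raw, v_raw)
            rss_raw = y @ Winv @ y - theta @ v_raw

            # same quantities via the summary-based accumulators
            from swssre.design import cell_design_rows

            A = cell_design_rows(d, [1, 2, 3], [2, 3], True)
            counts = summ.counts.astype(float)
            G = np.einsum("j,cja,cjb->ab", counts, A, A)
            h = np.einsum("j,cja->ca", counts, A)
            g = np.einsum("j,cj,cja->a", counts, summ.means, A)
            ysum = (counts * summ.means).sum(axis=1)
            q = float((counts * summ.means**2).sum() + summ.ssw.sum())
            c = lam / (1 + lam * mblk)
            M_s = G - c * (h.T @ h)
            v_s = g - c * (h.T @ ysum)
            theta_s = np.linalg.solve(M_s, v_s)
            rss_s = q - c * (ysum @ ysum) - theta_s @ v_s
            assert np.allclose(M_s, M_raw, rtol=1e-8)
            assert np.allclose(v_s, v_raw, rtol=1e-8)
            assert rss_s == pytest.approx(rss_raw, rel=1e-8)

    def test_fit_identical_on_raw_and_summarized_data(self, rng):
        d, data = small_dataset(rng)
        f_raw = reml_fit(data, d)
        f_sum = reml_fit(ClusterPeriodSummary.from_dataset(data), d)
        assert f_raw.tau_hat == pytest.approx(f_sum.tau_hat, rel=1e-12)
        assert f_raw.vc.sigma_c2 == pytest.approx(f_sum.vc.sigma_c2, abs=1e-12)

    def test_single_cluster_reduces_to_ols(self, rng):
        # with one cluster the period effects would absorb the treatment
        # column, so the identifiable single-cluster model drops them;
        # the cluster intercept is then redundant with mu and REML sits on
        # the sigma_c2 = 0 boundary with tau_hat equal to OLS
        d = SWDesign(np.array([[0, 1, 1]]))
        fx = FixedEffects(mu=0.2, pi=np.zeros(2), tau=0.5)
        data = generate_data(
            d, range(1, 4), 6, fx, VarianceComponents(0.0, 1.0), rng
        )
        fit = reml_fit(data, d, InterimModelSpec(True, False))
        y = np.concatenate([data.y[j][0] for j in (1, 2, 3)])
        x = np.repeat([0.0, 1.0, 1.0], 6)
        D = np.column_stack([np.ones_like(x), x])
        ols = np.linalg.lstsq(D, y, rcond=None)[0]
        assert fit.tau_hat == pytest.approx(ols[-1], rel=1e-8)
        assert fit.vc.sigma_c2 == 0.0

    def test_rank_deficient_model_errors(self):
        d = SWDesign(np.zeros((3, 2), dtype=int))
        data = TrialDataset(
            {1: np.random.default_rng(0).normal(size=(3, 2)), 2: np.zeros((3, 2))}
        )
        with pytest.raises(EstimationError, match="identifiable"):
            reml_fit(data, d, InterimModelSpec(True, True))

    def test_interim_model_without_treatment_term(self, rng):
        d = SWDesign(np.zeros((4, 3), dtype=int))
        data = generate_data(
            d, range(1, 3), 4, FixedEffects.null(3), VarianceComponents(0.2, 1.0), rng
        )
        fit = reml_fit(data, d, InterimModelSpec(False, True))
        assert fit.tau_hat is None and fit.var_tau is None
        assert fit.vc.sigma_e2 > 0


class TestFinalTest:
    def test_shift_invariance(self, rng):
        d, data = small_dataset(rng)
        r1 = final_test(data, d, alpha=0.05, nu=30)
        r2 = final_test(data.shifted(100.0), d, alpha=0.05, nu=30)
        # exact invariance holds analytically; numerically the profile
        # optimizer stops within its tolerance of the same ridge point
        assert r2.test_stat == pytest.approx(r1.test_stat, rel=1e-5)
        assert r2.sigma_c2_hat == pytest.approx(r1.sigma_c2_hat, rel=1e-4, abs=1e-7)

    def test_rejection_rule(self, rng):
        d, data = small_dataset(rng, tau=2.5, n=6)
        res = final_test(data, d, alpha=0.05, nu=50)
        assert res.reject == (res.test_stat > res.crit)
        assert res.info_hat == pytest.approx(1 / (res.tau_hat / res.test_stat) ** 2)
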