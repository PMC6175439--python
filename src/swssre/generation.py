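"""Synthetic trial data under the Hussey-Hughes model.

Responses are drawn exactly from

    Y_ijk = mu + pi_j + tau X_ij + c_i + eps_ijk,

with one cluster effect ``c_i ~ N(0, sigma_c^2)`` per cluster per trial
(shared across all periods, including across a reestimation boundary) and
``eps_ijk ~ N(0, sigma_e^2)`` i.i.d.

Two equivalent samplers are provided.  :func:`generate_data` draws every
individual response.  :func:`draw_summary` draws the cluster-period
sufficient statistics directly — the cell mean is
``N(cell expectation + c_i, sigma_e^2 / n)`` and the within-cell sum of
squares is ``sigma_e^2`` times a chi-square on ``n - 1`` degrees of
freedom, independent of the mean.  Since every estimator in this package
consumes only these sufficient statistics, the two samplers induce
identical distributions for all downstream quantities; the simulation
engine uses the direct form so replicate cost does not grow with the
per-cell sample size.
"""

from __future__ import annotations

import numpy as np

from .design import (
    ClusterPeriodSummary,
    FixedEffects,
    SWDesign,
    TrialDataset,
    VarianceComponents,
)


def draw_cluster_effects(
    C: int, vc: VarianceComponents, rng: np.random.Generator
) -> np.ndarray:
    """One random intercept per cluster, c_i ~ N(0, sigma_c^2)."""
    return rng.normal(0.0, np.sqrt(vc.sigma_c2), size=C)


def generate_data(
    design: SWDesign,
    periods,
    n: int,
    fx: FixedEffects,
    vc: VarianceComponents,
    rng: np.random.Generator,
    cluster_effects: np.ndarray | None = None,
) -> TrialDataset:
    """Individual-level responses for the given periods at n per cell.

    ``cluster_effects`` lets a caller share the c_i across separately
    generated phases of the same trial; by default fresh effects are drawn.
    """
    periods = list(periods)
    c = (
        draw_cluster_effects(design.C, vc, rng)
        if cluster_effects is None
        else np.asarray(cluster_effects, dtype=float)
    )
    mean = fx.cell_mean(design)  # (C, T)
    y = {}
    for j in periods:
        eps = rng.normal(0.0, np.sqrt(vc.sigma_e2), size=(design.C, n))
        y[j] = mean[:, j - 1 : j] + c[:, None] + eps
    return TrialDataset(y)


def draw_summary(
    design: SWDesign,
    periods,
    n: int,
    fx: FixedEffects,
    vc: VarianceComponents,
    rng: np.random.Generator,
    cluster_effects: np.ndarray,
) -> ClusterPeriodSummary:
    """Cluster-period sufficient statistics drawn directly.

    Exactly distributed as ``ClusterPeriodSummary.from_dataset`` applied to
    :func:`generate_data` with the same cluster effects.
    """
    periods = list(periods)
    C = design.C
    P = len(periods)
    cols = [j - 1 for j in periods]
    mean = fx.cell_mean(design)[:, cols] + np.asarray(cluster_effects)[:, None]
    means = rng.normal(mean, np.sqrt(vc.sigma_e2 / n))
    if n >= 2:
        ssw = vc.sigma_e2 * rng.chisquare(n - 1, size=(C, P))
    else:
        ssw = np.zeros((C, P))
    return ClusterPeriodSummary(
        tuple(periods), np.full(P, n, dtype=np.int64), means, ssw
    )
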