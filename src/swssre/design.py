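"""Domain types for cross-sectional stepped-wedge cluster randomized trials.

A stepped-wedge cluster randomized trial (SW-CRT) rolls an intervention out
across ``C`` clusters over ``T`` time periods according to a binary
allocation matrix ``X`` (rows are clusters, columns are periods;
``X[i, j] = 1`` means cluster ``i`` receives the intervention in period
``j``).  The analysis model throughout this package is the Hussey-Hughes
linear mixed model for a cross-sectional design:

    Y_ijk = mu + pi_j + tau * X_ij + c_i + eps_ijk,

with a fixed period effect ``pi_j`` (``pi_1 = 0`` for identifiability), a
fixed treatment effect ``tau``, a cluster random intercept
``c_i ~ N(0, sigma_c^2)`` shared by every observation in cluster ``i``
across all periods, and individual error ``eps_ijk ~ N(0, sigma_e^2)``.

Under this model the covariance matrix of the responses is block diagonal
by cluster, each block being the compound-symmetry matrix
``sigma_e^2 I_m + sigma_c^2 J_m``; :class:`CompoundSymmetryBlock` carries
the closed-form inverse and log-determinant of such blocks so that the
main code paths never materialize dense covariance matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np


class DesignError(ValueError):
    """Invalid trial design or design-stage argument."""


@dataclass(frozen=True)
class SWDesign:
    """A stepped-wedge allocation: binary C x T matrix of treatment cells.

    Rows need not be monotone non-decreasing (clusters may start treated or
    revert), although a warning is emitted at validation time for
    non-monotone rows since they are not stepped-wedge-like.
    """

    X: np.ndarray

    def __post_init__(self) -> None:
        X = np.asarray(self.X)
        if X.ndim != 2 or X.size == 0:
            raise DesignError("allocation matrix must be a non-empty 2-d array")
        if not np.isin(X, (0, 1)).all():
            raise DesignError("allocation matrix entries must all be 0 or 1")
        object.__setattr__(self, "X", X.astype(np.int8))
        if self.T < 2:
            raise DesignError("a stepped-wedge design needs at least 2 periods")

    @property
    def C(self) -> int:
        """Number of clusters (rows of X)."""
        return self.X.shape[0]

    @property
    def T(self) -> int:
        """Number of time periods (columns of X)."""
        return self.X.shape[1]

    def truncated(self, t: int) -> np.ndarray:
        """X(t): the first ``t`` columns of the allocation matrix."""
        _check_period(t, self.T)
        return self.X[:, :t]

    @classmethod
    def from_switch_periods(cls, switches: Sequence[int], T: int) -> "SWDesign":
        """Build a design from each cluster's first treated period.

        ``switches[i] = s`` means cluster ``i`` is treated in periods
        ``s..T`` (1-based); ``s > T`` leaves the cluster untreated.
        """
        X = np.zeros((len(switches), T), dtype=np.int8)
        for i, s in enumerate(switches):
            if s < 1:
                raise DesignError("switch periods must be >= 1")
            X[i, s - 1 :] = 1
        return cls(X)

    @classmethod
    def from_csv(cls, path) -> "SWDesign":
        """Read an allocation matrix from a headerless CSV of 0/1."""
        return validate_design(np.loadtxt(path, delimiter=",", ndmin=2))

    def to_csv(self, path) -> None:
        np.savetxt(path, self.X, fmt="%d", delimiter=",")


def _check_period(t: int, T: int) -> None:
    if not 1 <= t <= T:
        raise DesignError(f"period index t={t} outside 1..{T}")


def validate_design(X) -> SWDesign:
    """Validate an allocation matrix and wrap it as an :class:`SWDesign`.

    Raises :class:`DesignError` for empty or non-binary input.  Rows that
    are not monotone non-decreasing are permitted (incomplete/unbalanced
    designs are valid) but trigger a warning.
    """
    d = SWDesign(np.asarray(X))
    if (np.diff(d.X, axis=1) < 0).any():
        warnings.warn(
            "allocation matrix has non-monotone rows: clusters revert from "
            "intervention to control, which is not stepped-wedge-like",
            stacklevel=2,
        )
    return d


def treated_cell_count(design: SWDesign, t: int) -> int:
    """Total number of treated cluster-period cells among periods 1..t."""
    _check_period(t, design.T)
    return int(design.truncated(t).sum())


def per_period_treated(design: SWDesign, t: int) -> np.ndarray:
    """Column sums s_j of X(t): clusters treated in each period j = 1..t."""
    _check_period(t, design.T)
    return design.truncated(t).sum(axis=0).astype(np.int64)


@dataclass(frozen=True)
class VarianceComponents:
    """Between-cluster variance sigma_c^2 >= 0 and residual variance sigma_e^2 > 0."""

    sigma_c2: float
    sigma_e2: float

    def __post_init__(self) -> None:
        if not self.sigma_e2 > 0:
            raise DesignError("residual variance sigma_e2 must be > 0")
        if self.sigma_c2 < 0:
            raise DesignError("between-cluster variance sigma_c2 must be >= 0")

    @property
    def icc(self) -> float:
        """Intracluster correlation rho = sigma_c^2 / (sigma_c^2 + sigma_e^2)."""
        return self.sigma_c2 / (self.sigma_c2 + self.sigma_e2)

    def scaled(self, c_mult: float, e_mult: float) -> "VarianceComponents":
        """Multiply each component (used for misspecification grids)."""
        return VarianceComponents(self.sigma_c2 * c_mult, self.sigma_e2 * e_mult)


@dataclass(frozen=True)
class FixedEffects:
    """Fixed effects theta = (mu, pi_2..pi_T, tau); pi_1 = 0 is implicit.

    ``pi`` holds the T-1 free period effects pi_2..pi_T.
    """

    mu: float
    pi: np.ndarray
    tau: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "pi", np.atleast_1d(np.asarray(self.pi, dtype=float)))

    @classmethod
    def null(cls, T: int, mu: float = 0.0, tau: float = 0.0) -> "FixedEffects":
        return cls(mu=mu, pi=np.zeros(T - 1), tau=tau)

    def theta(self) -> np.ndarray:
        """Full coefficient vector (mu, pi_2, ..., pi_T, tau), length T + 1."""
        return np.concatenate(([self.mu], self.pi, [self.tau]))

    def cell_mean(self, design: SWDesign, tau: float | None = None) -> np.ndarray:
        """E[Y] per cluster-period cell (C x T), optionally overriding tau."""
        t = self.tau if tau is None else tau
        pi_full = np.concatenate(([0.0], self.pi))
        return self.mu + pi_full[None, :] + t * design.X.astype(float)


@dataclass
class TrialDataset:
    """Individual-level responses keyed by period.

    ``y[j]`` is a ``(C, n_j)`` array of responses for (1-based) period
    ``j``; the per-cluster-per-period sample size ``n_j`` is constant
    across clusters within a period (cross-sectional balanced recruitment)
    but may differ between periods (before/after a reestimation point).
    """

    y: dict[int, np.ndarray]

    def __post_init__(self) -> None:
        if not self.y:
            raise DesignError("dataset holds no periods")
        C = None
        for j, arr in self.y.items():
            arr = np.atleast_2d(np.asarray(arr, dtype=float))
            self.y[j] = arr
            if arr.shape[1] < 1:
                raise DesignError(f"period {j} has no observations")
            if C is None:
                C = arr.shape[0]
            elif arr.shape[0] != C:
                raise DesignError("inconsistent cluster count across periods")

    @property
    def C(self) -> int:
        return next(iter(self.y.values())).shape[0]

    @property
    def periods(self) -> tuple[int, ...]:
        return tuple(sorted(self.y))

    def n(self, j: int) -> int:
        return self.y[j].shape[1]

    def shifted(self, delta: float) -> "TrialDataset":
        return TrialDataset({j: arr + delta for j, arr in self.y.items()})

    @classmethod
    def from_long(cls, cluster, period, response) -> "TrialDataset":
        """Build from long-format columns (cluster, period, response), 1-based."""
        cluster = np.asarray(cluster, dtype=int)
        period = np.asarray(period, dtype=int)
        response = np.asarray(response, dtype=float)
        C = cluster.max()
        y: dict[int, np.ndarray] = {}
        for j in np.unique(period):
            rows = []
            sizes = set()
            for i in range(1, C + 1):
                vals = response[(period == j) & (cluster == i)]
                rows.append(vals)
                sizes.add(len(vals))
            if len(sizes) != 1 or 0 in sizes:
                raise DesignError(
                    f"period {j}: per-cluster sample sizes must be equal and >= 1"
                )
            y[int(j)] = np.vstack(rows)
        return cls(y)


@dataclass(frozen=True)
class ClusterPeriodSummary:
    """Sufficient statistics of a cross-sectional dataset by cluster-period cell.

    For the compound-symmetry model every likelihood quantity depends on the
    data only through the cell means, the pooled within-cell sums of squares
    and the cell counts, so all estimation in this package runs on this
    container; its equality with raw-data REML is exercised in the tests.
    """

    periods: tuple[int, ...]
    counts: np.ndarray  # (P,) per-cluster cell count for each period
    means: np.ndarray  # (C, P) cell means
    ssw: np.ndarray  # (C, P) within-cell sums of squares

    def __post_init__(self) -> None:
        object.__setattr__(self, "counts", np.asarray(self.counts, dtype=np.int64))
        object.__setattr__(self, "means", np.asarray(self.means, dtype=float))
        object.__setattr__(self, "ssw", np.asarray(self.ssw, dtype=float))
        if (self.counts < 1).any():
            raise DesignError("cell counts must be >= 1")
        if (self.ssw < -1e-9).any():
            raise DesignError("within-cell sums of squares must be >= 0")
        if self.means.shape != self.ssw.shape or self.means.shape[1] != len(
            self.periods
        ):
            raise DesignError("inconsistent summary dimensions")

    @property
    def C(self) -> int:
        return self.means.shape[0]

    @classmethod
    def from_dataset(cls, data: TrialDataset) -> "ClusterPeriodSummary":
        periods = data.periods
        counts = np.array([data.n(j) for j in periods])
        means = np.column_stack([data.y[j].mean(axis=1) for j in periods])
        ssw = np.column_stack(
            [((data.y[j] - data.y[j].mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
             for j in periods]
        )
        return cls(tuple(periods), counts, means, ssw)

    def period_means(self) -> np.ndarray:
        """Unweighted across-cluster mean of cell means per period (counts are
        equal across clusters within a period, so this is the period mean)."""
        return self.means.mean(axis=0)

    def restrict(self, periods: Sequence[int]) -> "ClusterPeriodSummary":
        idx = [self.periods.index(j) for j in periods]
        return ClusterPeriodSummary(
            tuple(periods), self.counts[idx], self.means[:, idx], self.ssw[:, idx]
        )

    @classmethod
    def concat(
        cls, a: "ClusterPeriodSummary", b: "ClusterPeriodSummary"
    ) -> "ClusterPeriodSummary":
        if set(a.periods) & set(b.periods):
            raise DesignError("cannot concatenate overlapping period sets")
        order = np.argsort(a.periods + b.periods)
        periods = tuple(np.array(a.periods + b.periods)[order])
        counts = np.concatenate([a.counts, b.counts])[order]
        means = np.concatenate([a.means, b.means], axis=1)[:, order]
        ssw = np.concatenate([a.ssw, b.ssw], axis=1)[:, order]
        return cls(periods, counts, means, ssw)


class CompoundSymmetryBlock:
    """One cluster's covariance block sigma_e^2 I_m + sigma_c^2 J_m.

    Provides the rank-one closed forms used throughout:

    * inverse: (1/sigma_e^2) (I_m - sigma_c^2/(sigma_e^2 + m sigma_c^2) J_m)
    * log-determinant: (m - 1) log sigma_e^2 + log(sigma_e^2 + m sigma_c^2)

    Dense construction (:meth:`dense`, :meth:`dense_inverse`) exists for
    test oracles only; nothing on the main path builds an m x m matrix.
    """

    def __init__(self, vc: VarianceComponents, m: int):
        if m < 1:
            raise DesignError("block dimension must be >= 1")
        self.vc = vc
        self.m = int(m)

    @property
    def _shrink(self) -> float:
        """Coefficient of J_m in the inverse, times sigma_e^2."""
        vc = self.vc
        return vc.sigma_c2 / (vc.sigma_e2 + self.m * vc.sigma_c2)

    def logdet(self) -> float:
        vc = self.vc
        return (self.m - 1) * np.log(vc.sigma_e2) + np.log(
            vc.sigma_e2 + self.m * vc.sigma_c2
        )

    def solve(self, b: np.ndarray) -> np.ndarray:
        """Apply the closed-form inverse to columns of ``b`` in O(m)."""
        b = np.asarray(b, dtype=float)
        return (b - self._shrink * b.sum(axis=0, keepdims=True)) / self.vc.sigma_e2

    def dense(self) -> np.ndarray:
        vc = self.vc
        return vc.sigma_e2 * np.eye(self.m) + vc.sigma_c2 * np.ones((self.m, self.m))

    def dense_inverse(self) -> np.ndarray:
        return (np.eye(self.m) - self._shrink * np.ones((self.m, self.m))) / (
            self.vc.sigma_e2
        )


def covariance_blocks(vc: VarianceComponents, m: int) -> CompoundSymmetryBlock:
    """The per-cluster covariance block of dimension ``m`` (closed forms)."""
    return CompoundSymmetryBlock(vc, m)


def design_matrix(
    design: SWDesign, periods: Sequence[int], n: int
) -> np.ndarray:
    """Individual-level design matrix linking theta to the response vector.

    Rows are ordered cluster-major, then period, then individual; columns
    are (mu, pi_2..pi_T, tau), so the matrix has C * |periods| * n rows and
    T + 1 columns regardless of which periods are observed.
    """
    periods = list(periods)
    if not periods:
        raise DesignError("period set must be non-empty")
    for j in periods:
        _check_period(j, design.T)
    if n < 1:
        raise DesignError("per-cell sample size must be >= 1")
    A = cell_design_rows(design, periods, range(2, design.T + 1), True)
    return np.repeat(A.reshape(-1, A.shape[-1]), n, axis=0)


def cell_design_rows(
    design: SWDesign,
    periods: Sequence[int],
    pi_periods: Sequence[int],
    include_treatment: bool,
) -> np.ndarray:
    """Cell-level design rows: a (C, |periods|, p) array.

    Within a cross-sectional cell every individual shares a design row, so
    the cell-level rows plus cell counts are all any fit or information
    computation needs.  ``pi_periods`` lists the periods carrying a free
    period-effect column (period 1 never does); ``include_treatment``
    appends the tau column (always last when present).
    """
    periods = list(periods)
    pi_periods = list(pi_periods)
    p = 1 + len(pi_periods) + bool(include_treatment)
    A = np.zeros((design.C, len(periods), p))
    A[:, :, 0] = 1.0
    for r, j in enumerate(periods):
        if j in pi_periods:
            A[:, r, 1 + pi_periods.index(j)] = 1.0
    if include_treatment:
        A[:, :, -1] = design.X[:, [j - 1 for j in periods]]
    return A
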