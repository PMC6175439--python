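"""Simulation scenario descriptors and the two worked trial settings.

A :class:`Scenario` bundles everything needed to simulate one
sample-size-reestimation SW-CRT configuration: the allocation, the
reestimation period, the true and the design-stage (assumed) variance
components, error rates and target effect, the true effect in the
generated data, the clamp on the reestimated cell size, and whether the
interim estimation is blinded (with its assumed effect ``tau_star``).

Two preset settings ship with the package:

* **TDS1** — a small balanced complete-block trial: C = 4 clusters over
  T = 5 periods, one cluster switching to intervention in each of periods
  2-5; sigma_c^2 = 0.02, sigma_e^2 = 0.51, one-sided alpha = 0.05, power
  0.9 at delta = 0.2.
* **TDS2** — a trial with typical review characteristics: C = 20 clusters
  over T = 9 periods, three clusters switching in each of periods 2-5 and
  two in each of periods 6-9; sigma_c^2 = 1/9, sigma_e^2 = 1 (ICC 0.1),
  one-sided alpha = 0.025, power 0.8 at delta = 0.267.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .design import DesignError, FixedEffects, SWDesign, VarianceComponents
from .power import PowerSpec, fixed_design_n


@dataclass(frozen=True)
class Scenario:
    """Full descriptor of one simulated SSRE (or fixed) trial configuration."""

    design: SWDesign
    t: int  # reestimation period; t = T means a fixed (single-phase) design
    vc_true: VarianceComponents
    vc_assumed: VarianceComponents
    alpha: float
    beta: float
    delta: float
    tau: float  # true effect in the generated data (0 or delta in the grids)
    mu: float = 0.0
    pi: np.ndarray | None = None  # period effects pi_2..pi_T; None = zeros
    n_min: int = 1
    n_max: int = 1000
    blinded: bool = True
    tau_star: float | None = None
    replicates: int = 10_000
    seed: int = 0
    n_init: int | None = None  # None: computed from the assumed variances

    def __post_init__(self) -> None:
        T = self.design.T
        if not 1 <= self.t <= T:
            raise DesignError("t must lie in 1..T")
        if self.t < T:
            if not 1 <= self.n_min <= self.n_max:
                raise DesignError("need 1 <= n_min <= n_max")
            if self.blinded and self.tau_star is None:
                raise DesignError("blinded reestimation requires tau_star")
        if self.pi is not None and len(np.atleast_1d(self.pi)) != T - 1:
            raise DesignError("pi must have length T - 1")
        if self.n_init is None:
            object.__setattr__(
                self,
                "n_init",
                fixed_design_n(self.design, self.vc_assumed, self.power_spec),
            )
        elif self.n_init < 1:
            raise DesignError("n_init must be >= 1")

    @property
    def power_spec(self) -> PowerSpec:
        return PowerSpec(self.alpha, self.beta, self.delta)

    @property
    def fixed_effects(self) -> FixedEffects:
        pi = np.zeros(self.design.T - 1) if self.pi is None else np.asarray(self.pi)
        return FixedEffects(mu=self.mu, pi=pi, tau=self.tau)

    def with_(self, **changes) -> "Scenario":
        """Copy with changes; n_init is recomputed unless given explicitly."""
        changes.setdefault("n_init", None)
        return replace(self, **changes)


def tds1_design() -> SWDesign:
    """4 clusters x 5 periods; cluster i switches in period i + 1."""
    return SWDesign.from_switch_periods([2, 3, 4, 5], T=5)


def tds2_design() -> SWDesign:
    """20 clusters x 9 periods; 3 clusters switch in each of periods 2-5,
    2 clusters in each of periods 6-9."""
    switches = [j for j in range(2, 6) for _ in range(3)]
    switches += [j for j in range(6, 10) for _ in range(2)]
    return SWDesign.from_switch_periods(switches, T=9)


_TDS1_VC = VarianceComponents(0.02, 0.51)
_TDS2_VC = VarianceComponents(1.0 / 9.0, 1.0)


def tds1_scenario(
    assumed_multipliers: tuple[float, float] = (1.0, 1.0),
    tau: float | None = None,
    **overrides,
) -> Scenario:
    """A TDS1 scenario; defaults: t = 3, blinded with tau_star = 0, tau = delta."""
    delta = 0.2
    base = Scenario(
        design=tds1_design(),
        t=overrides.pop("t", 3),
        vc_true=_TDS1_VC,
        vc_assumed=_TDS1_VC.scaled(*assumed_multipliers),
        alpha=0.05,
        beta=0.1,
        delta=delta,
        tau=delta if tau is None else tau,
        blinded=overrides.pop("blinded", True),
        tau_star=overrides.pop("tau_star", 0.0),
    )
    return base.with_(**overrides) if overrides else base


def tds2_scenario(
    assumed_multipliers: tuple[float, float] = (1.0, 1.0),
    tau: float | None = None,
    **overrides,
) -> Scenario:
    """A TDS2 scenario; defaults: t = 5, blinded with tau_star = 0, tau = delta."""
    delta = 0.267
    base = Scenario(
        design=tds2_design(),
        t=overrides.pop("t", 5),
        vc_true=_TDS2_VC,
        vc_assumed=_TDS2_VC.scaled(*assumed_multipliers),
        alpha=0.025,
        beta=0.2,
        delta=delta,
        tau=delta if tau is None else tau,
        blinded=overrides.pop("blinded", True),
        tau_star=overrides.pop("tau_star", 0.0),
    )
    return base.with_(**overrides) if overrides else base
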