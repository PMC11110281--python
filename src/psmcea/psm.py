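"""The 3-state partitioned survival model.

State occupancy is read directly off the two survival curves — no transition
probabilities: PF(t) = min(PFS(t), OS(t)), PP(t) = OS(t) - PF(t),
dead(t) = 1 - OS(t) — on a monthly cycle grid. Discounted person-time in
each alive state is a trapezoid integral with a continuous annual discount
factor, and costs/QALYs/LYs accrue as annual rates times discounted
person-years:

- PF costs medication (times any price multiplier) plus non-medication care;
- PP costs supportive care;
- PF utility is the state utility minus the intravenous-administration
  disutility (IV arms only) minus the adverse-event disutility weighted by
  the per-cycle grade >= 3 AE proportion;
- life-years are the same person-times with utility weight 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import EconomicSettings, StrategySpec
from .survival import SurvivalCurve

__all__ = [
    "StateTrace",
    "PersonTime",
    "StrategyOutcome",
    "build_trace",
    "person_time",
    "accrue_outcomes",
    "evaluate_strategy",
]


@dataclass(frozen=True)
class StateTrace:
    """Occupancy probabilities at every cycle boundary (times in months)."""

    grid_months: np.ndarray
    pf_occ: np.ndarray
    pp_occ: np.ndarray
    dead_occ: np.ndarray

    def __post_init__(self) -> None:
        total = self.pf_occ + self.pp_occ + self.dead_occ
        if not np.allclose(total, 1.0, atol=1e-9):
            raise ValueError("state occupancies must sum to 1 at every boundary")
        for occ in (self.pf_occ, self.pp_occ, self.dead_occ):
            if np.any((occ < -1e-12) | (occ > 1 + 1e-12)):
                raise ValueError("occupancies must lie in [0, 1]")


@dataclass(frozen=True)
class PersonTime:
    """Discounted person-years spent in each alive state."""

    pf_years: float
    pp_years: float

    def __post_init__(self) -> None:
        if self.pf_years < 0 or self.pp_years < 0:
            raise ValueError("person-time must be non-negative")


@dataclass(frozen=True)
class StrategyOutcome:
    """Discounted totals for one arm (costs in NT$, effects per patient)."""

    strategy: str
    cost_pf: float
    cost_pp: float
    ly_pf: float
    ly_pp: float
    qaly_pf: float
    qaly_pp: float

    @property
    def cost_total(self) -> float:
        return self.cost_pf + self.cost_pp

    @property
    def ly_total(self) -> float:
        return self.ly_pf + self.ly_pp

    @property
    def qaly_total(self) -> float:
        return self.qaly_pf + self.qaly_pp

    def effect(self, metric: str) -> float:
        if metric == "qaly":
            return self.qaly_total
        if metric == "ly":
            return self.ly_total
        raise ValueError("metric must be 'qaly' or 'ly'")


def build_trace(
    os_curve: SurvivalCurve,
    pfs_curve: SurvivalCurve,
    horizon_years: float,
    cycle_years: float,
) -> StateTrace:
    """Evaluate state occupancy at every cycle boundary.

    A PFS curve exceeding OS (possible with independently fitted or
    adversarial curves) is capped at OS, putting zero mass in PP there.
    """
    if horizon_years <= 0 or cycle_years <= 0:
        raise ValueError("horizon and cycle length must be positive")
    n_cycles = int(round(horizon_years / cycle_years))
    grid = np.linspace(0.0, n_cycles * cycle_years * 12.0, n_cycles + 1)
    s_os = np.clip(np.asarray(os_curve(grid), dtype=float), 0.0, 1.0)
    s_pfs = np.clip(np.asarray(pfs_curve(grid), dtype=float), 0.0, 1.0)
    pf = np.minimum(s_pfs, s_os)
    return StateTrace(
        grid_months=grid, pf_occ=pf, pp_occ=s_os - pf, dead_occ=1.0 - s_os
    )


def person_time(trace: StateTrace, rate_per_year: float) -> PersonTime:
    """Discounted trapezoid integral of PF and PP occupancy, in years."""
    if rate_per_year < 0:
        raise ValueError("discount rate must be non-negative")
    t_years = trace.grid_months / 12.0
    w = (1.0 + rate_per_year) ** (-t_years)
    return PersonTime(
        pf_years=float(np.trapezoid(trace.pf_occ * w, t_years)),
        pp_years=float(np.trapezoid(trace.pp_occ * w, t_years)),
    )


def accrue_outcomes(
    pt: PersonTime, strat: StrategySpec, econ: EconomicSettings
) -> StrategyOutcome:
    """Accrue discounted costs, QALYs and LYs from state person-time."""
    u_pf_eff = (
        econ.u_pf
        - (econ.d_iv if strat.route == "intravenous" else 0.0)
        - econ.d_ae * strat.ae_rate_per_cycle
    )
    if u_pf_eff < 0:
        raise ValueError(
            f"{strat.name}: disutilities exceed the PF utility ({u_pf_eff:.3f})"
        )
    pf_cost_rate = (
        strat.med_cost_per_year * strat.price_multiplier + strat.nonmed_cost_per_year
    )
    return StrategyOutcome(
        strategy=strat.name,
        cost_pf=pt.pf_years * pf_cost_rate,
        cost_pp=pt.pp_years * econ.supportive_cost_per_year,
        ly_pf=pt.pf_years,
        ly_pp=pt.pp_years,
        qaly_pf=pt.pf_years * u_pf_eff,
        qaly_pp=pt.pp_years * econ.u_pp,
    )


def evaluate_strategy(
    strat: StrategySpec,
    econ: EconomicSettings,
    os_curve: SurvivalCurve | None = None,
    pfs_curve: SurvivalCurve | None = None,
) -> tuple[StrategyOutcome, PersonTime]:
    """Full per-arm pipeline: curves -> trace -> person-time -> accrual.

    Curves default to the arm's pure parametric distributions; hybrid
    KM+extrapolation curves can be passed in instead.
    """
    from .survival import ParametricCurve

    os_curve = os_curve or ParametricCurve(strat.os)
    pfs_curve = pfs_curve or ParametricCurve(strat.pfs)
    trace = build_trace(os_curve, pfs_curve, econ.horizon_years, econ.cycle_length_years)
    pt = person_time(trace, econ.discount_rate_per_year)
    return accrue_outcomes(pt, strat, econ), pt
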