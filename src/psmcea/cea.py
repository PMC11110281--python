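"""Pairwise cost-effectiveness comparison and the scenario engine.

The comparison layer computes incremental cost, incremental effect
(QALY or LY), the ICER, dominance flags, and the incremental net monetary
benefit INMB = dE * WTP - dC. The scenario engine re-runs the full pipeline
under policy-relevant switches: a drug-price grid (90% down to 40% of the
hypothesised ivosidenib price), a point-value conversion factor on
non-medication cost rates, alternative horizons, and life-years instead of
QALYs as the effectiveness metric.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .parameters import ModelConfig
from .psm import PersonTime, StrategyOutcome, accrue_outcomes, evaluate_strategy

__all__ = [
    "CEAResult",
    "ScenarioSpec",
    "PRICE_GRID",
    "compare",
    "evaluate_all",
    "run_scenarios",
]

PRICE_GRID = (0.9, 0.8, 0.7, 0.6, 0.5, 0.4)


@dataclass(frozen=True)
class CEAResult:
    """Incremental comparison of one intervention against one comparator."""

    intervention: str
    comparator: str
    delta_cost: float
    delta_effect: float
    wtp: float
    metric: str
    dominance: str | None  # None | "intervention dominant" | "comparator dominant"

    @property
    def icer(self) -> float | None:
        """dC/dE; undefined (None) under dominance or zero incremental effect."""
        if self.dominance is not None or self.delta_effect == 0.0:
            return None
        return self.delta_cost / self.delta_effect

    @property
    def inmb(self) -> float:
        return self.delta_effect * self.wtp - self.delta_cost


def compare(
    intervention: StrategyOutcome,
    comparator: StrategyOutcome,
    wtp: float,
    metric: str = "qaly",
) -> CEAResult:
    """Incremental CEA of intervention minus comparator at a WTP threshold."""
    d_cost = intervention.cost_total - comparator.cost_total
    d_eff = intervention.effect(metric) - comparator.effect(metric)
    dominance = None
    if d_eff > 0 and d_cost < 0:
        dominance = "intervention dominant"
    elif d_eff < 0 and d_cost > 0:
        dominance = "comparator dominant"
    return CEAResult(
        intervention=intervention.strategy,
        comparator=comparator.strategy,
        delta_cost=d_cost,
        delta_effect=d_eff,
        wtp=wtp,
        metric=metric,
        dominance=dominance,
    )


def evaluate_all(
    cfg: ModelConfig,
    overrides: Mapping[str, float] | None = None,
    price_multipliers: Mapping[str, float] | None = None,
    apply_conversion_factor: bool = False,
    horizon_years: float | None = None,
    person_times: Mapping[str, PersonTime] | None = None,
) -> dict[str, StrategyOutcome]:
    """Evaluate every strategy's discounted outcome under modifications.

    With ``person_times`` supplied (state person-years already known, e.g.
    calibrated from a published cost decomposition), the survival layer is
    bypassed and only the accrual rates are re-derived — valid for price,
    cost and utility modifications but not for horizon changes, which are
    rejected.
    """
    strategies, econ = cfg.build(
        overrides=overrides,
        price_multipliers=price_multipliers,
        apply_conversion_factor=apply_conversion_factor,
        horizon_years=horizon_years,
    )
    out: dict[str, StrategyOutcome] = {}
    if person_times is not None:
        if horizon_years is not None:
            raise ValueError("horizon changes require re-running the survival layer")
        for s in strategies:
            out[s.name] = accrue_outcomes(person_times[s.name], s, econ)
    else:
        for s in strategies:
            out[s.name], _ = evaluate_strategy(s, econ)
    return out


@dataclass(frozen=True)
class ScenarioSpec:
    """One scenario: a kind plus its setting.

    kinds: ``base``; ``price_grid`` (setting = multiplier in (0, 1], applied
    to the intervention's medication cost only); ``conversion_factor``
    (setting unused; the configured factor multiplies PF non-medication and
    PP supportive-care rates); ``horizon`` (setting = years);
    ``ly_effectiveness`` (LY totals replace QALYs; costs unchanged).
    """

    kind: str
    setting: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in (
            "base", "price_grid", "conversion_factor", "horizon", "ly_effectiveness"
        ):
            raise ValueError(f"unknown scenario kind {self.kind!r}")
        if self.kind == "price_grid" and not (0 < (self.setting or 0) <= 1):
            raise ValueError("price multiplier must be in (0, 1]")


def default_scenarios(cfg: ModelConfig) -> list[ScenarioSpec]:
    out = [ScenarioSpec("base", label="base case")]
    out += [
        ScenarioSpec("price_grid", m, label=f"{int(m * 100)}% price of intervention")
        for m in PRICE_GRID
    ]
    out.append(ScenarioSpec("conversion_factor", label="conversion factor on non-medication costs"))
    out += [ScenarioSpec("horizon", h, label=f"time horizon: {h:g} years") for h in (5.0, 15.0)]
    out.append(ScenarioSpec("ly_effectiveness", label="life-year as effectiveness"))
    return out


def run_scenarios(
    cfg: ModelConfig,
    scenarios: Sequence[ScenarioSpec] | None = None,
    intervention: str | None = None,
    person_times: Mapping[str, PersonTime] | None = None,
) -> pd.DataFrame:
    """Re-run the base-case pipeline under each scenario.

    Returns one row per scenario with the ICER and INMB of the intervention
    (default: first configured strategy) against every other strategy.
    """
    if scenarios is None:
        scenarios = default_scenarios(cfg)
        if person_times is not None:
            # horizon changes need the survival layer, which fixed
            # person-times bypass
            scenarios = [s for s in scenarios if s.kind != "horizon"]
    scenarios = list(scenarios)
    inter = intervention or cfg.strategies[0].name
    comparators = [s.name for s in cfg.strategies if s.name != inter]
    rows = []
    for sc in scenarios:
        metric = "qaly"
        kw: dict = {}
        if sc.kind == "price_grid":
            kw["price_multipliers"] = {inter: float(sc.setting)}
        elif sc.kind == "conversion_factor":
            kw["apply_conversion_factor"] = True
        elif sc.kind == "horizon":
            kw["horizon_years"] = float(sc.setting)
        elif sc.kind == "ly_effectiveness":
            metric = "ly"
        outcomes = evaluate_all(cfg, person_times=person_times, **kw)
        row = {"scenario": sc.label or sc.kind, "kind": sc.kind, "setting": sc.setting}
        for comp in comparators:
            res = compare(outcomes[inter], outcomes[comp], cfg.econ.wtp_per_qaly, metric)
            row[f"icer_vs_{comp}"] = res.icer
            row[f"inmb_vs_{comp}"] = res.inmb
        rows.append(row)
    return pd.DataFrame(rows)
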