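"""Deterministic and probabilistic sensitivity analysis.

One-way DSA re-evaluates the ICER with each parameter pushed to the ends of
its deterministic range (survival parameters: 95% CI; most others: +/-25%),
all remaining parameters at base — the tornado diagram's input. PSA redraws
every parameter with a distribution jointly (normal for survival
parameters, gamma for costs, beta for utilities/disutility, uniform for the
exchange rate) in a seeded Monte Carlo, rebuilding curves and accrual each
iteration; the intervention's medication price, a currency conversion of a
foreign list price, varies only through the exchange-rate draw. CEAC and
per-person EVPI derive from the iteration table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cea import compare, evaluate_all
from .parameters import ModelConfig, UncertainParameter
from .psm import PersonTime

__all__ = [
    "TornadoEntry",
    "PSAResult",
    "run_dsa",
    "run_psa",
    "ceac",
    "evpi",
]


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    icer_low: float
    icer_high: float
    base_icer: float

    @property
    def width(self) -> float:
        return abs(self.icer_high - self.icer_low)


def run_dsa(
    cfg: ModelConfig,
    comparator: str,
    intervention: str | None = None,
    person_times: Mapping[str, PersonTime] | None = None,
    include: Sequence[str] | None = None,
) -> list[TornadoEntry]:
    """One-way sensitivity of the ICER to every ranged parameter.

    Parameters without a deterministic range (comparator medication costs,
    AE proportions) are skipped. ``include`` restricts the varied set.
    Entries come back sorted by bar width, widest first.
    """
    inter = intervention or cfg.strategies[0].name
    wtp = cfg.econ.wtp_per_qaly

    def icer_under(overrides):
        outcomes = evaluate_all(cfg, overrides=overrides, person_times=person_times)
        res = compare(outcomes[inter], outcomes[comparator], wtp)
        return res.icer if res.icer is not None else np.nan

    base = icer_under(None)
    entries = []
    for name, p in cfg.uncertain.items():
        if include is not None and name not in include:
            continue
        if not p.has_dsa_range:
            continue
        lo = icer_under({name: p.dsa_low})
        hi = icer_under({name: p.dsa_high})
        entries.append(TornadoEntry(name, icer_low=lo, icer_high=hi, base_icer=base))
    entries.sort(key=lambda e: e.width, reverse=True)
    return entries


@dataclass(frozen=True)
class PSAResult:
    """Per-iteration discounted (cost, QALY, LY) per strategy."""

    strategies: tuple[str, ...]
    costs: np.ndarray   # (n, n_strategies)
    qalys: np.ndarray
    lys: np.ndarray
    seed: int
    n: int
    n_redraws: int = 0

    def frame(self) -> pd.DataFrame:
        recs = []
        for j, s in enumerate(self.strategies):
            recs.append(
                pd.DataFrame(
                    {
                        "iteration": np.arange(self.n),
                        "strategy": s,
                        "cost": self.costs[:, j],
                        "qaly": self.qalys[:, j],
                        "ly": self.lys[:, j],
                    }
                )
            )
        return pd.concat(recs, ignore_index=True)

    def subset(self, names: Sequence[str]) -> "PSAResult":
        """Restrict the iteration table to a subset of strategies.

        Pairwise decision quantities (CEAC, EVPI against one comparator) are
        computed on the two-strategy subset.
        """
        idx = [self.strategies.index(n) for n in names]
        return PSAResult(
            strategies=tuple(names),
            costs=self.costs[:, idx],
            qalys=self.qalys[:, idx],
            lys=self.lys[:, idx],
            seed=self.seed,
            n=self.n,
            n_redraws=self.n_redraws,
        )

    def incremental(self, comparator: str, metric: str = "qaly"):
        """(dcost, deffect) arrays of strategy 0 versus a named comparator."""
        j0 = 0
        jc = self.strategies.index(comparator)
        eff = self.qalys if metric == "qaly" else self.lys
        return self.costs[:, j0] - self.costs[:, jc], eff[:, j0] - eff[:, jc]


def _draw(p: UncertainParameter, rng: np.random.Generator) -> float:
    fam = p.psa_family
    a, b = p.psa_params
    if fam == "normal":
        return float(rng.normal(a, b))
    if fam == "gamma":
        return float(rng.gamma(shape=a, scale=1.0 / b))
    if fam == "beta":
        return float(rng.beta(a, b))
    return float(rng.uniform(a, b))  # uniform


def run_psa(
    cfg: ModelConfig,
    n: int | None = None,
    seed: int | None = None,
    person_times: Mapping[str, PersonTime] | None = None,
    price_multipliers: Mapping[str, float] | None = None,
    apply_conversion_factor: bool = False,
    max_redraws: int = 100,
) -> PSAResult:
    """Seeded Monte Carlo over every parameter with a PSA distribution.

    Each iteration draws all non-fixed parameters independently, rebuilds
    the survival curves and the accrual, and records each strategy's
    discounted cost, QALYs and LYs. Draws producing an invalid model (e.g.
    a non-positive sdlog) are rejected and redrawn, with the count reported.
    """
    n = n if n is not None else cfg.psa_iterations
    seed = seed if seed is not None else cfg.rng_seed
    rng = np.random.default_rng(seed)
    names = [s.name for s in cfg.strategies]
    sampled = [
        name for name, p in cfg.uncertain.items() if p.psa_family != "fixed"
    ]
    # the conversion factor only enters the model in its scenario; leave it
    # out of the joint draw otherwise
    cf_name = cfg.econ_bindings.get("conversion_factor")
    if not apply_conversion_factor and cf_name in sampled:
        sampled.remove(cf_name)
    costs = np.empty((n, len(names)))
    qalys = np.empty((n, len(names)))
    lys = np.empty((n, len(names)))
    n_redraws = 0
    for i in range(n):
        for _ in range(max_redraws):
            overrides = {name: _draw(cfg.uncertain[name], rng) for name in sampled}
            try:
                outcomes = evaluate_all(
                    cfg,
                    overrides=overrides,
                    person_times=person_times,
                    price_multipliers=price_multipliers,
                    apply_conversion_factor=apply_conversion_factor,
                )
            except ValueError:
                n_redraws += 1
                continue
            break
        else:
            raise RuntimeError("PSA draw rejected repeatedly; check distributions")
        for j, name in enumerate(names):
            costs[i, j] = outcomes[name].cost_total
            qalys[i, j] = outcomes[name].qaly_total
            lys[i, j] = outcomes[name].ly_total
    return PSAResult(
        strategies=tuple(names), costs=costs, qalys=qalys, lys=lys,
        seed=seed, n=n, n_redraws=n_redraws,
    )


def ceac(psa: PSAResult, wtp_grid: Sequence[float], metric: str = "qaly") -> pd.DataFrame:
    """Probability each strategy has the highest NMB, per WTP.

    Ties split equally among the tied strategies, so columns sum to 1 at
    every WTP.
    """
    wtp_grid = np.asarray(list(wtp_grid), dtype=float)
    if wtp_grid.size == 0:
        raise ValueError("WTP grid must be non-empty")
    eff = psa.qalys if metric == "qaly" else psa.lys
    out = np.zeros((wtp_grid.size, len(psa.strategies)))
    for i, wtp in enumerate(wtp_grid):
        nmb = eff * wtp - psa.costs  # (n, S)
        best = nmb.max(axis=1, keepdims=True)
        winners = np.isclose(nmb, best, rtol=0.0, atol=1e-9)
        out[i] = (winners / winners.sum(axis=1, keepdims=True)).mean(axis=0)
    return pd.DataFrame(out, index=wtp_grid, columns=list(psa.strategies)).rename_axis("wtp")


def evpi(psa: PSAResult, wtp: float, metric: str = "qaly") -> float:
    """Per-person expected value of perfect information at a WTP.

    mean over iterations of the best NMB, minus the best over strategies of
    the mean NMB; non-negative by construction.
    """
    eff = psa.qalys if metric == "qaly" else psa.lys
    nmb = eff * wtp - psa.costs
    return float(max(nmb.max(axis=1).mean() - nmb.mean(axis=0).max(), 0.0))
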