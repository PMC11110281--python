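"""Model inputs for the partitioned-survival cost-effectiveness analysis.

Every quantity the model uses — survival distribution parameters, annual
costs, utilities, disutilities, the discount rate and the willingness-to-pay
threshold — is an :class:`UncertainParameter`: a base-case value optionally
annotated with a deterministic sensitivity range (for one-way/tornado
analysis) and a probabilistic sampling distribution (for Monte Carlo PSA).

A :class:`ModelConfig` bundles the parameter table with the three treatment
strategies (ivosidenib, mFOLFOX, 5-FU/LV) and the economic settings, and can
re-materialise the strategy/economic objects under parameter overrides —
which is how both sensitivity analyses are driven.

The package ships ``data/table1.cfg``, a YAML document carrying the full
published input set (2022 NT$; survival times in months).
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import yaml

from .survival import ParametricSurvival

__all__ = [
    "UncertainParameter",
    "StrategySpec",
    "EconomicSettings",
    "ModelConfig",
    "ConfigError",
    "load_model_config",
    "default_config",
    "distribution_mean",
]

PSA_FAMILIES = ("normal", "gamma", "beta", "uniform", "fixed")


class ConfigError(ValueError):
    """A configuration document is malformed or violates an invariant."""


@dataclass(frozen=True)
class UncertainParameter:
    """A model input with optional DSA range and PSA distribution.

    PSA parameterisations: normal = (mean, standard error);
    gamma = (shape alpha, rate lambda) so the mean is alpha/lambda;
    beta = (alpha, beta); uniform = (min, max); fixed = no sampling,
    draws always return ``value``.
    """

    name: str
    value: float
    dsa_low: float | None = None
    dsa_high: float | None = None
    psa_family: str = "fixed"
    psa_params: tuple[float, float] | None = None
    units: str = ""

    def __post_init__(self) -> None:
        if self.psa_family not in PSA_FAMILIES:
            raise ConfigError(
                f"{self.name}: unknown PSA distribution family {self.psa_family!r}"
            )
        if (self.dsa_low is None) != (self.dsa_high is None):
            raise ConfigError(f"{self.name}: DSA range must give both bounds")
        if self.dsa_low is not None:
            if not (self.dsa_low <= self.value <= self.dsa_high):
                raise ConfigError(
                    f"{self.name}: base value {self.value} outside DSA range "
                    f"[{self.dsa_low}, {self.dsa_high}]"
                )
        if self.psa_family != "fixed":
            if self.psa_params is None or len(self.psa_params) != 2:
                raise ConfigError(f"{self.name}: {self.psa_family} needs two parameters")
            a, b = self.psa_params
            if self.psa_family in ("gamma", "beta") and (a <= 0 or b <= 0):
                raise ConfigError(
                    f"{self.name}: {self.psa_family} parameters must be positive"
                )
            if self.psa_family == "uniform" and not a < b:
                raise ConfigError(f"{self.name}: uniform needs min < max")

    @property
    def has_dsa_range(self) -> bool:
        return self.dsa_low is not None


def distribution_mean(p: UncertainParameter) -> float:
    """Analytic mean of the parameter's PSA distribution.

    Raises :class:`ConfigError` for ``fixed`` parameters, which carry no
    distribution.
    """
    if p.psa_family == "fixed":
        raise ConfigError(f"{p.name}: fixed parameter has no PSA distribution")
    a, b = p.psa_params
    if p.psa_family == "normal":
        return a
    if p.psa_family == "gamma":
        return a / b
    if p.psa_family == "beta":
        return a / (a + b)
    return (a + b) / 2.0  # uniform


@dataclass(frozen=True)
class StrategySpec:
    """One treatment arm: survival curves, annual cost rates, AE burden."""

    name: str
    os: ParametricSurvival
    pfs: ParametricSurvival
    med_cost_per_year: float
    nonmed_cost_per_year: float
    ae_rate_per_cycle: float
    route: str  # "oral" | "intravenous"
    price_multiplier: float = 1.0
    price_from_exchange: bool = False

    def __post_init__(self) -> None:
        if self.route not in ("oral", "intravenous"):
            raise ConfigError(f"{self.name}: route must be oral or intravenous")
        if self.med_cost_per_year < 0 or self.nonmed_cost_per_year < 0:
            raise ConfigError(f"{self.name}: costs must be non-negative")
        if not 0.0 <= self.ae_rate_per_cycle <= 1.0:
            raise ConfigError(f"{self.name}: AE rate must be a probability")
        if not 0.0 < self.price_multiplier <= 1.0:
            raise ConfigError(f"{self.name}: price multiplier must be in (0, 1]")


@dataclass(frozen=True)
class EconomicSettings:
    """Utilities, cost rates and valuation settings shared across arms.

    Monetary values are 2022 NT$; the horizon and cycle length are years.
    """

    u_pf: float
    u_pp: float
    d_ae: float
    d_iv: float
    supportive_cost_per_year: float
    discount_rate_per_year: float
    wtp_per_qaly: float
    horizon_years: float
    cycle_length_years: float
    conversion_factor: float = 0.9
    exchange_rate: float = 29.81

    def __post_init__(self) -> None:
        # the u_pp <= u_pf ordering is a base-case validation (enforced at
        # config load): sensitivity excursions legitimately cross it — the
        # deterministic range of u_pf reaches below the base u_pp
        if not (0.0 <= self.u_pf <= 1.0 and 0.0 <= self.u_pp <= 1.0):
            raise ConfigError("utilities must lie in [0, 1]")
        if self.d_ae < 0 or self.d_iv < 0:
            raise ConfigError("disutilities must be non-negative")
        if not 0.0 <= self.discount_rate_per_year <= 0.05:
            raise ConfigError("discount rate outside supported range [0, 0.05]")
        if self.horizon_years <= 0 or self.cycle_length_years <= 0:
            raise ConfigError("horizon and cycle length must be positive")
        if self.supportive_cost_per_year < 0 or self.wtp_per_qaly < 0:
            raise ConfigError("costs and WTP must be non-negative")


# Fields of each section that are resolved through the uncertain-parameter
# table (the remaining fields are literals in the document).
_ECON_REFS = {
    "u_pf", "u_pp", "d_ae", "d_iv", "supportive_cost_per_year",
    "discount_rate_per_year", "conversion_factor", "exchange_rate",
}


@dataclass(frozen=True)
class ModelConfig:
    """Validated model configuration.

    ``strategies`` and ``econ`` hold the base case; :meth:`build` re-derives
    them under parameter overrides (sensitivity analyses) and scenario
    switches (price multiplier, conversion factor).
    """

    strategies: tuple[StrategySpec, ...]
    econ: EconomicSettings
    uncertain: Mapping[str, UncertainParameter]
    psa_iterations: int = 1000
    rng_seed: int = 0
    # name of the uncertain parameter behind each strategy field, used to
    # rebuild strategies under overrides: {strategy: {field: param name}}
    bindings: Mapping[str, Mapping[str, str]] = field(default_factory=dict)
    econ_bindings: Mapping[str, str] = field(default_factory=dict)

    def strategy(self, name: str) -> StrategySpec:
        for s in self.strategies:
            if s.name == name:
                return s
        raise KeyError(name)

    def build(
        self,
        overrides: Mapping[str, float] | None = None,
        price_multipliers: Mapping[str, float] | None = None,
        apply_conversion_factor: bool = False,
        horizon_years: float | None = None,
    ) -> tuple[tuple[StrategySpec, ...], EconomicSettings]:
        """Materialise strategies and settings under modifications.

        ``overrides`` maps uncertain-parameter names to replacement values.
        The medication cost of a strategy flagged ``price_from_exchange``
        scales proportionally with an overridden exchange rate (its price is
        a currency conversion of a foreign list price). When
        ``apply_conversion_factor`` is set, the point-value conversion factor
        multiplies every non-medication cost rate (PF non-medication and PP
        supportive care).
        """
        overrides = dict(overrides or {})
        unknown = set(overrides) - set(self.uncertain)
        if unknown:
            raise ConfigError(f"overrides name unknown parameters: {sorted(unknown)}")

        def val(pname: str) -> float:
            return overrides.get(pname, self.uncertain[pname].value)

        e_kw = {}
        for f in (
            "u_pf", "u_pp", "d_ae", "d_iv", "supportive_cost_per_year",
            "discount_rate_per_year", "conversion_factor", "exchange_rate",
        ):
            pname = self.econ_bindings.get(f)
            e_kw[f] = val(pname) if pname is not None else getattr(self.econ, f)
        e_kw.update(
            wtp_per_qaly=self.econ.wtp_per_qaly,
            horizon_years=horizon_years or self.econ.horizon_years,
            cycle_length_years=self.econ.cycle_length_years,
        )
        cf = e_kw["conversion_factor"] if apply_conversion_factor else 1.0
        e_kw["supportive_cost_per_year"] *= cf
        econ = EconomicSettings(**e_kw)

        strategies = []
        for s in self.strategies:
            b = self.bindings.get(s.name, {})
            med = val(b["med_cost"]) if "med_cost" in b else s.med_cost_per_year
            if s.price_from_exchange and "exchange_rate" in self.econ_bindings:
                xr_name = self.econ_bindings["exchange_rate"]
                if xr_name in overrides:
                    med *= overrides[xr_name] / self.uncertain[xr_name].value
            nonmed = val(b["nonmed_cost"]) if "nonmed_cost" in b else s.nonmed_cost_per_year
            nonmed *= cf
            os_p = tuple(
                val(b[f"os_{i}"]) if f"os_{i}" in b else s.os.params[i]
                for i in range(len(s.os.params))
            )
            pfs_p = tuple(
                val(b[f"pfs_{i}"]) if f"pfs_{i}" in b else s.pfs.params[i]
                for i in range(len(s.pfs.params))
            )
            pm = (price_multipliers or {}).get(s.name, s.price_multiplier)
            strategies.append(
                replace(
                    s,
                    os=replace(s.os, params=os_p),
                    pfs=replace(s.pfs, params=pfs_p),
                    med_cost_per_year=med,
                    nonmed_cost_per_year=nonmed,
                    price_multiplier=pm,
                )
            )
        return tuple(strategies), econ


def _require(mapping: Mapping, key: str, where: str):
    if key not in mapping:
        raise ConfigError(f"missing field {key!r} in {where}")
    return mapping[key]


def _parse_parameter(name: str, raw: Mapping) -> UncertainParameter:
    if not isinstance(raw, Mapping):
        raise ConfigError(f"parameter {name!r} must be a mapping")
    value = float(_require(raw, "value", f"parameter {name!r}"))
    dsa = raw.get("dsa")
    lo = hi = None
    if dsa is not None:
        if len(dsa) != 2:
            raise ConfigError(f"parameter {name!r}: dsa must be [low, high]")
        lo, hi = float(dsa[0]), float(dsa[1])
    psa = raw.get("psa")
    fam, pp = "fixed", None
    if psa is not None:
        fam = str(_require(psa, "family", f"parameter {name!r} psa"))
        params = _require(psa, "params", f"parameter {name!r} psa")
        pp = (float(params[0]), float(params[1]))
    return UncertainParameter(
        name=name, value=value, dsa_low=lo, dsa_high=hi,
        psa_family=fam, psa_params=pp, units=str(raw.get("units", "")),
    )


def load_model_config(source) -> ModelConfig:
    """Load and validate a model configuration.

    ``source`` is a path, an open text stream, or a YAML string. Errors name
    the offending key.
    """
    if hasattr(source, "read"):
        doc = yaml.safe_load(source.read())
    else:
        text = str(source)
        if "\n" not in text and not text.lstrip().startswith("{"):
            with open(text, "r") as fh:
                doc = yaml.safe_load(fh)
        else:
            doc = yaml.safe_load(text)
    if not isinstance(doc, Mapping):
        raise ConfigError("configuration document must be a mapping")

    raw_params = _require(doc, "parameters", "document")
    uncertain = {n: _parse_parameter(n, raw) for n, raw in raw_params.items()}

    def resolve(ref, where: str) -> float:
        if isinstance(ref, str):
            if ref not in uncertain:
                raise ConfigError(f"{where}: reference {ref!r} not in parameters")
            return uncertain[ref].value
        return float(ref)

    raw_settings = _require(doc, "settings", "document")
    econ_bindings: dict[str, str] = {}
    e_kw = {}
    for f in (
        "u_pf", "u_pp", "d_ae", "d_iv", "supportive_cost_per_year",
        "discount_rate_per_year", "wtp_per_qaly", "horizon_years",
        "cycle_length_years", "conversion_factor", "exchange_rate",
    ):
        ref = _require(raw_settings, f, "settings")
        if isinstance(ref, str):
            if f not in _ECON_REFS:
                raise ConfigError(f"settings.{f}: must be a literal")
            econ_bindings[f] = ref
        e_kw[f] = resolve(ref, f"settings.{f}")
    econ = EconomicSettings(**e_kw)
    if econ.u_pp > econ.u_pf:
        raise ConfigError("base-case utilities must satisfy u_pp <= u_pf")

    strategies = []
    bindings: dict[str, dict[str, str]] = {}
    for raw in _require(doc, "strategies", "document"):
        name = str(_require(raw, "name", "strategy"))
        b: dict[str, str] = {}

        def field_val(key: str, bind_as: str) -> float:
            ref = _require(raw, key, f"strategy {name!r}")
            if isinstance(ref, str):
                b[bind_as] = ref
            return resolve(ref, f"strategy {name!r}.{key}")

        def curve(key: str) -> ParametricSurvival:
            block = _require(raw, key, f"strategy {name!r}")
            fam = str(_require(block, "family", f"{name}.{key}"))
            refs = _require(block, "params", f"{name}.{key}")
            vals = []
            for i, ref in enumerate(refs):
                if isinstance(ref, str):
                    b[f"{key}_{i}"] = ref
                vals.append(resolve(ref, f"{name}.{key}[{i}]"))
            se = block.get("se")
            return ParametricSurvival(
                family=fam, params=tuple(vals),
                param_se=tuple(float(x) for x in se) if se else None,
            )

        strategies.append(
            StrategySpec(
                name=name,
                os=curve("os"),
                pfs=curve("pfs"),
                med_cost_per_year=field_val("med_cost_per_year", "med_cost"),
                nonmed_cost_per_year=field_val("nonmed_cost_per_year", "nonmed_cost"),
                ae_rate_per_cycle=float(_require(raw, "ae_rate_per_cycle", name)),
                route=str(_require(raw, "route", name)),
                price_from_exchange=bool(raw.get("price_from_exchange", False)),
            )
        )
        bindings[name] = b

    cfg = ModelConfig(
        strategies=tuple(strategies),
        econ=econ,
        uncertain=uncertain,
        psa_iterations=int(doc.get("psa_iterations", 1000)),
        rng_seed=int(doc.get("rng_seed", 0)),
        bindings=bindings,
        econ_bindings=econ_bindings,
    )
    # referenced parameters must resolve (they did, by construction) and the
    # rebuilt base case must equal the literals — catches binding typos
    rebuilt, _ = cfg.build()
    for a, bstrat in zip(cfg.strategies, rebuilt):
        if not math.isclose(a.med_cost_per_year, bstrat.med_cost_per_year):
            raise ConfigError(f"inconsistent binding for {a.name} medication cost")
    return cfg


def dump_model_config(cfg: ModelConfig) -> str:
    """Serialise a ModelConfig to the YAML document format of the loader.

    ``load_model_config(dump_model_config(cfg))`` reproduces every value to
    machine precision.
    """
    params = {}
    for name, p in cfg.uncertain.items():
        d: dict = {"value": p.value}
        if p.has_dsa_range:
            d["dsa"] = [p.dsa_low, p.dsa_high]
        if p.psa_family != "fixed":
            d["psa"] = {"family": p.psa_family, "params": list(p.psa_params)}
        if p.units:
            d["units"] = p.units
        params[name] = d

    settings = {}
    for f in (
        "u_pf", "u_pp", "d_ae", "d_iv", "supportive_cost_per_year",
        "discount_rate_per_year", "wtp_per_qaly", "horizon_years",
        "cycle_length_years", "conversion_factor", "exchange_rate",
    ):
        settings[f] = cfg.econ_bindings.get(f, getattr(cfg.econ, f))

    strategies = []
    for s in cfg.strategies:
        b = cfg.bindings.get(s.name, {})

        def curve_block(key, dist):
            return {
                "family": dist.family,
                "params": [
                    b.get(f"{key}_{i}", dist.params[i])
                    for i in range(len(dist.params))
                ],
                **({"se": list(dist.param_se)} if dist.param_se else {}),
            }

        strategies.append(
            {
                "name": s.name,
                "route": s.route,
                "ae_rate_per_cycle": s.ae_rate_per_cycle,
                "med_cost_per_year": b.get("med_cost", s.med_cost_per_year),
                "nonmed_cost_per_year": b.get("nonmed_cost", s.nonmed_cost_per_year),
                "price_from_exchange": s.price_from_exchange,
                "os": curve_block("os", s.os),
                "pfs": curve_block("pfs", s.pfs),
            }
        )
    doc = {
        "parameters": params,
        "settings": settings,
        "strategies": strategies,
        "psa_iterations": cfg.psa_iterations,
        "rng_seed": cfg.rng_seed,
    }
    return yaml.safe_dump(doc, sort_keys=False)


def default_config() -> ModelConfig:
    """The shipped published input set (``data/table1.cfg``)."""
    ref = importlib.resources.files("psmcea").joinpath("data/table1.cfg")
    return load_model_config(ref.read_text())
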