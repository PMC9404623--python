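"""Domain types, configuration loading/validation and bundled fixtures.

The model is parameterised entirely by a structured configuration with four
top-level sections:

``drugs``
    One entry per antipsychotic: dosing, pack pricing, six-weekly event
    probabilities (discontinuation due to adverse events / other reasons,
    relapse), one-off adverse-event probabilities (>=7% weight gain, EPS),
    a clozapine-style monitoring flag and a licensing age gate.
``populations``
    One entry per cohort: start age, time horizon, 6-week cycle length,
    the ordered (age-gated) treatment sequence for each arm, the no-treatment
    relapse probability, the schizophrenia standardised mortality ratio, and
    the population's cost inputs.
``options`` (optional)
    Structural switches of the pathway rules (age-gate overflow behaviour,
    re-initiation semantics).
``uncertainty`` (optional)
    Explicit per-parameter uncertainty overrides for DSA/PSA; when absent the
    analysis layer derives a default specification for every clinical and
    cost parameter.

All probabilities are per 6-week cycle unless stated otherwise; all costs are
GBP. Unknown keys anywhere in a config are rejected.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ConfigError",
    "DrugProfile",
    "CostInputs",
    "PopulationSpec",
    "LifeTable",
    "UncertaintySpec",
    "ModelOptions",
    "ModelConfig",
    "load_config",
    "save_config",
    "fixture_base_case",
    "load_life_table",
    "PROBABILITY_FIELDS",
    "COST_MONEY_FIELDS",
]

#: Per-drug six-weekly / one-off event probability fields, in registry order.
PROBABILITY_FIELDS = ("p_disc_ae", "p_disc_other", "p_relapse", "p_weight_gain", "p_eps")

#: CostInputs fields that carry money (eligible for DSA/PSA variation).
COST_MONEY_FIELDS = (
    "stable_state_cost",
    "relapse_state_cost",
    "ae_weight_gain_cost",
    "ae_eps_cost",
    "switching_cost",
    "monitoring_cost_per_cycle",
    "relapse_drug_daily_cost",
)


class ConfigError(ValueError):
    """Raised when a configuration violates the documented schema."""


@dataclass(frozen=True)
class DrugProfile:
    """One antipsychotic and the inputs the model needs for it.

    ``p_disc_ae`` (discontinuation due to intolerable adverse events) applies
    only in the first cycle a patient ever receives the drug; the remaining
    probabilities apply as documented in the engine. ``disc_ae_unavailable``
    records that the source reported no adverse-event discontinuation figure
    (stored as exactly 0 with this provenance flag set).
    """

    name: str
    daily_dose: float  # mg/day
    pack_price: float  # GBP per pack
    pack_total_mg: float  # total mg per pack (strength x count)
    p_disc_ae: float
    p_disc_other: float
    p_relapse: float
    p_weight_gain: float
    p_eps: float
    requires_monitoring: bool = False
    min_age: float = 0.0  # licensing gate, years
    disc_ae_unavailable: bool = False

    def validate(self) -> None:
        for f in PROBABILITY_FIELDS:
            v = getattr(self, f)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"drug {self.name!r}: {f}={v} outside [0, 1]")
        s = self.p_disc_ae + self.p_disc_other + self.p_relapse
        if s > 1.0 + 1e-12:
            raise ConfigError(
                f"drug {self.name!r}: p_disc_ae + p_disc_other + p_relapse = {s:.6g} > 1"
            )
        if self.daily_dose < 0:
            raise ConfigError(f"drug {self.name!r}: daily_dose must be >= 0")
        if self.pack_price < 0:
            raise ConfigError(f"drug {self.name!r}: pack_price must be >= 0")
        if self.pack_total_mg <= 0:
            raise ConfigError(f"drug {self.name!r}: pack_total_mg must be > 0")
        if self.disc_ae_unavailable and self.p_disc_ae != 0.0:
            raise ConfigError(
                f"drug {self.name!r}: disc_ae_unavailable requires p_disc_ae == 0"
            )


@dataclass(frozen=True)
class CostInputs:
    """Population-level cost inputs (GBP; state costs per 6-week cycle)."""

    stable_state_cost: float
    relapse_state_cost: float
    ae_weight_gain_cost: float
    ae_eps_cost: float
    switching_cost: float
    monitoring_cost_per_cycle: float
    relapse_drug_daily_cost: float
    discount_rate: float = 0.0  # per-year fraction
    inflation_factor: float = 1.0  # single multiplicative price adjustment

    def validate(self) -> None:
        for f in COST_MONEY_FIELDS:
            if getattr(self, f) < 0:
                raise ConfigError(f"costs: {f} must be >= 0")
        if not (0.0 <= self.discount_rate < 1.0):
            raise ConfigError("costs: discount_rate must be in [0, 1)")
        if self.inflation_factor < 0:
            raise ConfigError("costs: inflation_factor must be >= 0")


@dataclass(frozen=True)
class PopulationSpec:
    """A modelled cohort: entry age, horizon, arm sequences and costs."""

    label: str
    start_age: float  # years at model entry
    horizon_years: float
    sequence: tuple[str, ...]  # intervention arm, first line first
    no_treatment_relapse: float  # per cycle
    smr: float  # standardised mortality ratio vs general population
    costs: CostInputs
    cycle_length_days: float = 42.0
    comparator_sequence: tuple[str, ...] | None = None

    def validate(self, drugs: Mapping[str, DrugProfile]) -> None:
        if self.horizon_years <= 0:
            raise ConfigError(f"population {self.label!r}: horizon_years must be > 0")
        if self.cycle_length_days <= 0:
            raise ConfigError(f"population {self.label!r}: cycle_length_days must be > 0")
        if not (0.0 <= self.no_treatment_relapse <= 1.0):
            raise ConfigError(
                f"population {self.label!r}: no_treatment_relapse outside [0, 1]"
            )
        if self.smr <= 0:
            raise ConfigError(f"population {self.label!r}: smr must be > 0")
        seqs = [("sequence", self.sequence)]
        if self.comparator_sequence is not None:
            seqs.append(("comparator_sequence", self.comparator_sequence))
        for which, seq in seqs:
            if len(seq) == 0:
                raise ConfigError(f"population {self.label!r}: {which} is empty")
            for name in seq:
                if name not in drugs:
                    raise ConfigError(
                        f"population {self.label!r}: {which} drug {name!r} not in registry"
                    )
                if drugs[name].min_age > self.start_age + self.horizon_years:
                    raise ConfigError(
                        f"population {self.label!r}: {name!r} is never licensed within "
                        f"the horizon (min_age {drugs[name].min_age})"
                    )
        self.costs.validate()


class LifeTable:
    """Annual all-cause death probabilities by age (step lookup).

    Lookups below the first row clamp to the first row; beyond the last row
    they clamp to the last row.
    """

    def __init__(self, rows: Iterable[tuple[float, float]]):
        rows = sorted((float(a), float(q)) for a, q in rows)
        if not rows:
            raise ConfigError("life table has no rows")
        ages = [a for a, _ in rows]
        if len(set(ages)) != len(ages):
            raise ConfigError("life table ages must be strictly increasing")
        for a, q in rows:
            if not (0.0 <= q <= 1.0):
                raise ConfigError(f"life table q_annual={q} at age {a} outside [0, 1]")
        self.ages = np.array(ages)
        self.q_annual = np.array([q for _, q in rows])

    def annual_death_prob(self, age: float) -> float:
        i = int(np.searchsorted(self.ages, age, side="right")) - 1
        return float(self.q_annual[max(i, 0)])

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, LifeTable)
            and np.array_equal(self.ages, other.ages)
            and np.array_equal(self.q_annual, other.q_annual)
        )

    @classmethod
    def zero(cls) -> "LifeTable":
        """A no-mortality table (useful for toy models and tests)."""
        return cls([(0.0, 0.0)])


@dataclass(frozen=True)
class UncertaintySpec:
    """How one parameter varies in sensitivity analysis.

    ``family`` selects the PSA sampling distribution: ``lognormal`` for
    ratio-scale clinical parameters (probabilities are perturbed on the
    log-odds scale so they stay in [0, 1]), ``gamma`` for costs and resource
    quantities, ``fixed`` for no variation. When ``se`` is omitted it defaults
    to 25% of the central value; when DSA bounds are omitted they default to
    central +/- 20% (clamped to the parameter's domain).
    """

    parameter_id: str
    family: str  # lognormal | gamma | fixed
    central: float
    se: float | None = None
    ci95: tuple[float, float] | None = None
    dsa_low: float | None = None
    dsa_high: float | None = None

    def validate(self) -> None:
        if self.family not in ("lognormal", "gamma", "fixed"):
            raise ConfigError(
                f"uncertainty {self.parameter_id!r}: unknown family {self.family!r}"
            )
        if self.se is not None and self.se < 0:
            raise ConfigError(f"uncertainty {self.parameter_id!r}: se must be >= 0")
        if self.ci95 is not None and not self.ci95[0] <= self.central <= self.ci95[1]:
            raise ConfigError(
                f"uncertainty {self.parameter_id!r}: ci95 must bracket the central value"
            )
        lo = self.central * 0.8 if self.dsa_low is None else self.dsa_low
        hi = self.central * 1.2 if self.dsa_high is None else self.dsa_high
        if not lo <= self.central <= hi:
            raise ConfigError(
                f"uncertainty {self.parameter_id!r}: dsa bounds must bracket central"
            )


@dataclass(frozen=True)
class ModelOptions:
    """Structural switches for pathway rules the sources leave open.

    The defaults are the rule set under which the model reproduces the
    published base-case results; every alternative reading is kept available.

    gate_mode
        ``"strict"`` (default): lines are taken strictly in order; while the
        immediate next line's drug is not yet licensed for the cohort's age,
        patients needing it wait untreated (in the no-treatment state) until
        age catches up. ``"skip"``: advance past age-gated lines to the next
        licensed drug further down the sequence.
    relapse_resolution
        ``"within_cycle"`` (default): with all transitions occurring at
        mid-cycle, an acute relapse is a half-cycle episode — the patient
        starts the destination treatment at the next cycle boundary.
        ``"full_cycle"``: the relapse state occupies one whole 6-week cycle
        before resolving.
    nt_relapse_destination
        Where a patient relapsing from no treatment goes: ``"advance"``
        (default) moves to the next line; ``"return"`` re-initiates the drug
        they had stopped.
    first_cycle_other_disc
        Whether other-reason discontinuation can occur in a drug's first
        cycle. Default off (it applies from the second cycle of use onward;
        only adverse-event discontinuation acts in the first cycle).
    reapply_first_cycle_on_reinitiation
        Whether returning to a previously tolerated drug after a spell of no
        treatment re-applies first-cycle adverse-event discontinuation risk
        and one-off adverse-event costs. Default off: the patient already
        tolerated the drug. Only meaningful with ``nt_relapse_destination =
        "return"``.
    charge_switch_on_reinitiation
        Whether returning to the previous drug after no treatment incurs the
        medication-switching cost (three psychiatrist visits). Default on.
    """

    gate_mode: str = "strict"
    relapse_resolution: str = "within_cycle"
    nt_relapse_destination: str = "advance"
    first_cycle_other_disc: bool = False
    reapply_first_cycle_on_reinitiation: bool = False
    charge_switch_on_reinitiation: bool = True

    def validate(self) -> None:
        if self.gate_mode not in ("strict", "skip"):
            raise ConfigError(f"options: unknown gate_mode {self.gate_mode!r}")
        if self.relapse_resolution not in ("within_cycle", "full_cycle"):
            raise ConfigError(
                f"options: unknown relapse_resolution {self.relapse_resolution!r}"
            )
        if self.nt_relapse_destination not in ("advance", "return"):
            raise ConfigError(
                f"options: unknown nt_relapse_destination {self.nt_relapse_destination!r}"
            )


@dataclass
class ModelConfig:
    """A fully validated model configuration."""

    drugs: dict[str, DrugProfile]
    populations: dict[str, PopulationSpec]
    uncertainty: list[UncertaintySpec] = field(default_factory=list)
    options: ModelOptions = field(default_factory=ModelOptions)

    def validate(self) -> None:
        for d in self.drugs.values():
            d.validate()
        for p in self.populations.values():
            p.validate(self.drugs)
        for u in self.uncertainty:
            u.validate()
        self.options.validate()


# ---------------------------------------------------------------------------
# Schema-checked YAML loading


def _check_keys(section: str, mapping: Mapping, allowed: set[str], required: set[str]) -> None:
    if not isinstance(mapping, Mapping):
        raise ConfigError(f"{section}: expected a mapping")
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(f"{section}: unknown key(s) {sorted(unknown)}")
    missing = required - set(mapping)
    if missing:
        raise ConfigError(f"{section}: missing required key(s) {sorted(missing)}")


_DRUG_REQUIRED = {"daily_dose", "pack_price", "pack_total_mg", *PROBABILITY_FIELDS}
_DRUG_OPTIONAL = {"requires_monitoring", "min_age", "disc_ae_unavailable"}
_COST_REQUIRED = set(COST_MONEY_FIELDS)
_COST_OPTIONAL = {"discount_rate", "inflation_factor"}
_POP_REQUIRED = {"start_age", "horizon_years", "sequence", "no_treatment_relapse", "smr", "costs"}
_POP_OPTIONAL = {"cycle_length_days", "comparator_sequence"}
_UNC_REQUIRED = {"parameter_id", "family"}
_UNC_OPTIONAL = {"central", "se", "ci95", "dsa_low", "dsa_high"}
_OPT_ALLOWED = {
    "gate_mode",
    "relapse_resolution",
    "nt_relapse_destination",
    "first_cycle_other_disc",
    "reapply_first_cycle_on_reinitiation",
    "charge_switch_on_reinitiation",
}


def _parse_config(raw: Mapping) -> ModelConfig:
    _check_keys("config", raw, {"drugs", "populations", "options", "uncertainty"}, {"drugs", "populations"})

    drugs: dict[str, DrugProfile] = {}
    for name, entry in raw["drugs"].items():
        _check_keys(f"drugs.{name}", entry, _DRUG_REQUIRED | _DRUG_OPTIONAL, _DRUG_REQUIRED)
        drugs[name] = DrugProfile(name=name, **{k: entry[k] for k in entry})

    populations: dict[str, PopulationSpec] = {}
    for label, entry in raw["populations"].items():
        _check_keys(f"populations.{label}", entry, _POP_REQUIRED | _POP_OPTIONAL, _POP_REQUIRED)
        costs_raw = entry["costs"]
        _check_keys(
            f"populations.{label}.costs", costs_raw, _COST_REQUIRED | _COST_OPTIONAL, _COST_REQUIRED
        )
        costs = CostInputs(**costs_raw)
        kwargs = {k: v for k, v in entry.items() if k not in ("costs", "sequence", "comparator_sequence")}
        comp = entry.get("comparator_sequence")
        populations[label] = PopulationSpec(
            label=label,
            sequence=tuple(entry["sequence"]),
            comparator_sequence=None if comp is None else tuple(comp),
            costs=costs,
            **kwargs,
        )

    uncertainty: list[UncertaintySpec] = []
    for entry in raw.get("uncertainty", []) or []:
        _check_keys("uncertainty entry", entry, _UNC_REQUIRED | _UNC_OPTIONAL, _UNC_REQUIRED)
        entry = dict(entry)
        if "ci95" in entry and entry["ci95"] is not None:
            entry["ci95"] = tuple(entry["ci95"])
        if "central" not in entry:
            raise ConfigError(
                f"uncertainty {entry['parameter_id']!r}: explicit entries require 'central'"
            )
        uncertainty.append(UncertaintySpec(**entry))

    opts_raw = raw.get("options", {}) or {}
    _check_keys("options", opts_raw, _OPT_ALLOWED, set())
    options = ModelOptions(**opts_raw)

    cfg = ModelConfig(drugs=drugs, populations=populations, uncertainty=uncertainty, options=options)
    cfg.validate()
    return cfg


def load_config(path: str | Path) -> ModelConfig:
    """Load and validate a YAML (or JSON — a YAML subset) model configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return _parse_config(raw)


def _drug_to_dict(d: DrugProfile) -> dict:
    out = {k: getattr(d, k) for k in ("daily_dose", "pack_price", "pack_total_mg", *PROBABILITY_FIELDS)}
    if d.requires_monitoring:
        out["requires_monitoring"] = True
    if d.min_age:
        out["min_age"] = d.min_age
    if d.disc_ae_unavailable:
        out["disc_ae_unavailable"] = True
    return out


def save_config(cfg: ModelConfig, path: str | Path) -> None:
    """Write a config back to YAML; reloading reproduces every field exactly."""
    raw: dict = {"drugs": {}, "populations": {}}
    for name, d in cfg.drugs.items():
        raw["drugs"][name] = _drug_to_dict(d)
    for label, p in cfg.populations.items():
        entry: dict = {
            "start_age": p.start_age,
            "horizon_years": p.horizon_years,
            "cycle_length_days": p.cycle_length_days,
            "sequence": list(p.sequence),
            "no_treatment_relapse": p.no_treatment_relapse,
            "smr": p.smr,
            "costs": {k: getattr(p.costs, k) for k in (*COST_MONEY_FIELDS, "discount_rate", "inflation_factor")},
        }
        if p.comparator_sequence is not None:
            entry["comparator_sequence"] = list(p.comparator_sequence)
        raw["populations"][label] = entry
    if cfg.uncertainty:
        raw["uncertainty"] = [
            {k: v for k, v in dataclasses.asdict(u).items() if v is not None}
            for u in cfg.uncertainty
        ]
        for u in raw["uncertainty"]:
            if "ci95" in u:
                u["ci95"] = list(u["ci95"])
    if cfg.options != ModelOptions():
        raw["options"] = dataclasses.asdict(cfg.options)
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Bundled fixtures


def _data_path(name: str) -> Path:
    return Path(str(resources.files("apseq").joinpath("data", name)))


def fixture_base_case() -> ModelConfig:
    """The bundled base-case configuration (8 drugs, 3 populations)."""
    return load_config(_data_path("base_case.yaml"))


def load_life_table(path: str | Path | None = None) -> LifeTable:
    """Load a life table from CSV (columns ``age``, ``q_annual``).

    Without a path, loads the bundled synthetic UK-style abridged table.
    """
    path = _data_path("life_table_uk_synthetic.csv") if path is None else Path(path)
    df = pd.read_csv(path)
    if list(df.columns) != ["age", "q_annual"]:
        raise ConfigError("life table CSV must have columns age,q_annual")
    return LifeTable(zip(df["age"], df["q_annual"]))
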