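"""Random, structurally valid parameter sets for property testing.

The generator emulates the shape of the real inputs — a registry of drug
profiles with competing six-weekly event probabilities, a cohort definition
with an ordered sequence, and population cost inputs — while drawing every
value uniformly from configurable ranges. The ranges are chosen so any
generated set satisfies the model's structural constraints by construction
(in particular the competing discontinuation/relapse probabilities of a drug
can never sum above 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import (
    ConfigError,
    CostInputs,
    DrugProfile,
    ModelConfig,
    PopulationSpec,
)

__all__ = ["SyntheticSpec", "random_parameter_set"]

Range = tuple[float, float]


@dataclass(frozen=True)
class SyntheticSpec:
    """Ranges and sizes for random parameter-set generation."""

    seed: int
    n_drugs: int = 3
    horizon_years: float = 3.0
    start_age: float = 30.0
    cycle_length_days: float = 42.0
    smr: Range = (1.0, 3.0)
    # six-weekly event probabilities (ranges sum to < 1 by construction)
    p_disc_ae: Range = (0.0, 0.25)
    p_disc_other: Range = (0.0, 0.30)
    p_relapse: Range = (0.0, 0.30)
    p_weight_gain: Range = (0.0, 0.40)
    p_eps: Range = (0.0, 0.50)
    no_treatment_relapse: Range = (0.02, 0.30)
    # drug pricing
    pack_price: Range = (1.0, 150.0)
    daily_dose: Range = (1.0, 20.0)
    pack_days: Range = (7.0, 56.0)  # pack_total_mg = daily_dose * pack_days
    # costs (GBP)
    stable_state_cost: Range = (500.0, 3000.0)
    relapse_state_cost: Range = (5000.0, 30000.0)
    ae_weight_gain_cost: Range = (50.0, 500.0)
    ae_eps_cost: Range = (50.0, 500.0)
    switching_cost: Range = (0.0, 1000.0)
    monitoring_cost_per_cycle: Range = (0.0, 20.0)
    relapse_drug_daily_cost: Range = (0.0, 1.0)
    p_monitoring_flag: float = 0.2

    def validate(self) -> None:
        if self.n_drugs < 1:
            raise ConfigError("n_drugs must be >= 1")
        for name in (
            "smr", "p_disc_ae", "p_disc_other", "p_relapse", "p_weight_gain",
            "p_eps", "no_treatment_relapse", "pack_price", "daily_dose",
            "pack_days", "stable_state_cost", "relapse_state_cost",
            "ae_weight_gain_cost", "ae_eps_cost", "switching_cost",
            "monitoring_cost_per_cycle", "relapse_drug_daily_cost",
        ):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ConfigError(f"synthetic range {name} has min > max")
        for name in ("p_disc_ae", "p_disc_other", "p_relapse", "p_weight_gain",
                     "p_eps", "no_treatment_relapse"):
            lo, hi = getattr(self, name)
            if not (0.0 <= lo and hi <= 1.0):
                raise ConfigError(f"synthetic probability range {name} outside [0, 1]")
        s = self.p_disc_ae[1] + self.p_disc_other[1] + self.p_relapse[1]
        if s > 1.0:
            raise ConfigError(
                f"competing probability ranges can sum to {s:.3g} > 1"
            )


def _u(rng: np.random.Generator, r: Range) -> float:
    return float(rng.uniform(r[0], r[1]))


def random_parameter_set(spec: SyntheticSpec) -> ModelConfig:
    """Generate a validated single-population model configuration.

    The intervention sequence is the drugs in generated order; the comparator
    is the reversed order (so the two arms genuinely differ when n_drugs > 1).
    Deterministic in ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    drugs: dict[str, DrugProfile] = {}
    for k in range(spec.n_drugs):
        name = f"drug_{k}"
        dose = _u(rng, spec.daily_dose)
        drugs[name] = DrugProfile(
            name=name,
            daily_dose=dose,
            pack_price=_u(rng, spec.pack_price),
            pack_total_mg=dose * _u(rng, spec.pack_days),
            p_disc_ae=_u(rng, spec.p_disc_ae),
            p_disc_other=_u(rng, spec.p_disc_other),
            p_relapse=_u(rng, spec.p_relapse),
            p_weight_gain=_u(rng, spec.p_weight_gain),
            p_eps=_u(rng, spec.p_eps),
            requires_monitoring=bool(rng.random() < spec.p_monitoring_flag),
        )
    costs = CostInputs(
        stable_state_cost=_u(rng, spec.stable_state_cost),
        relapse_state_cost=_u(rng, spec.relapse_state_cost),
        ae_weight_gain_cost=_u(rng, spec.ae_weight_gain_cost),
        ae_eps_cost=_u(rng, spec.ae_eps_cost),
        switching_cost=_u(rng, spec.switching_cost),
        monitoring_cost_per_cycle=_u(rng, spec.monitoring_cost_per_cycle),
        relapse_drug_daily_cost=_u(rng, spec.relapse_drug_daily_cost),
    )
    names = tuple(drugs)
    population = PopulationSpec(
        label="synthetic",
        start_age=spec.start_age,
        horizon_years=spec.horizon_years,
        cycle_length_days=spec.cycle_length_days,
        sequence=names,
        comparator_sequence=names[::-1],
        no_treatment_relapse=_u(rng, spec.no_treatment_relapse),
        smr=_u(rng, spec.smr),
        costs=costs,
    )
    cfg = ModelConfig(drugs=drugs, populations={"synthetic": population})
    cfg.validate()
    return cfg
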