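import pytest

import apseq
from apseq.config import (
    CostInputs,
    DrugProfile,
    LifeTable,
    ModelConfig,
    PopulationSpec,
)


@pytest.fixture(scope="session")
def base_cfg() -> ModelConfig:
    return apseq.fixture_base_case()


@pytest.fixture(scope="session")
def lifetable() -> LifeTable:
    return apseq.load_life_table()


@pytest.fixture(scope="session")
def zero_lifetable() -> LifeTable:
    return LifeTable.zero()


def make_drug(name="d0", **kw) -> DrugProfile:
    """A quiet drug profile (no events) to be overridden per test."""
    defaults = dict(
        daily_dose=10.0,
        pack_price=28.0,
        pack_total_mg=280.0,
        p_disc_ae=0.0,
        p_disc_other=0.0,
        p_relapse=0.0,
        p_weight_gain=0.0,
        p_eps=0.0,
    )
    defaults.update(kw)
    return DrugProfile(name=name, **defaults)


def make_costs(**kw) -> CostInputs:
    defaults = dict(
        stable_state_cost=2000.0,
        relapse_state_cost=27906.0,
        ae_weight_gain_cost=92.0,
        ae_eps_cost=220.0,
        switching_cost=687.0,
        monitoring_cost_per_cycle=9.0,
        relapse_drug_daily_cost=0.0,
    )
    defaults.update(kw)
    return CostInputs(**defaults)


def make_population(sequence, *, n_cycles=None, horizon_years=5.0, **kw) -> PopulationSpec:
    """A toy cohort; ``n_cycles`` sets the horizon to yield exactly that many
    42-day cycles."""
    if n_cycles is not None:
        horizon_years = n_cycles * 42.0 / 365.25
    defaults = dict(
        label="toy",
        start_age=30.0,
        no_treatment_relapse=0.071,
        smr=2.6,
        costs=make_costs(),
    )
    defaults.update(kw)
    return PopulationSpec(
        sequence=tuple(sequence), horizon_years=horizon_years, **defaults
    )
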