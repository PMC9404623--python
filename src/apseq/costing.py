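"""Attach costs to a cohort trace.

Four cost types are captured: treatment acquisition (daily drug cost over the
cycle, plus clozapine-style monitoring), medication switching (a fixed cost
per line advance or re-initiation), health-state costs (stable vs relapse
six-weekly aggregates) and one-off adverse-event management costs applied to
first-ever drug initiations.

State costs follow the mid-cycle rule: with all transitions occurring halfway
through a cycle, a mover accrues half a cycle at the origin state's rates and
half at the destination's. For per-cycle rates this reduces to costing each
cycle at the average of its start- and end-of-cycle occupancy, which is how it
is computed here. The relapse state replaces the prior drug's acquisition cost
with the acute-episode drug (olanzapine 10 mg/day); the no-treatment state
carries the stable-state resource cost with zero drug cost.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .config import CostInputs, DrugProfile
from .derive import DAYS_PER_YEAR, cycle_drug_cost
from .engine import CohortTrace, StateKind

__all__ = [
    "COST_CATEGORIES",
    "CostLedger",
    "state_cost_rates",
    "accumulate_costs",
    "one_off_event_costs",
    "switching_costs",
]

COST_CATEGORIES = (
    "drug",
    "monitoring",
    "stable_state",
    "no_treatment_state",
    "relapse_state",
    "switching",
    "ae_weight_gain",
    "ae_eps",
)


@dataclass
class CostLedger:
    """Per-cycle cost components and their per-patient totals (GBP)."""

    per_cycle: pd.DataFrame  # index: cycle; columns: COST_CATEGORIES

    @property
    def totals(self) -> pd.Series:
        return self.per_cycle.sum(axis=0)

    @property
    def grand_total(self) -> float:
        return float(self.per_cycle.to_numpy().sum())

    def export(self, outdir: str | Path, stem: str = "costs") -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        tidy = self.per_cycle.reset_index().melt(
            id_vars="cycle", var_name="category", value_name="cost"
        )
        tidy.to_csv(outdir / f"{stem}_per_cycle.csv", index=False)
        summary = {"total": self.grand_total, "by_category": self.totals.to_dict()}
        (outdir / f"{stem}_summary.json").write_text(json.dumps(summary, indent=1))


def state_cost_rates(
    trace: CohortTrace, drugs: Mapping[str, DrugProfile], costs: CostInputs
) -> dict[str, np.ndarray]:
    """Per-cycle cost rate of each state, split by category."""
    seq = trace.population.sequence
    cl = trace.population.cycle_length_days
    S = len(trace.states)
    rates = {c: np.zeros(S) for c in ("drug", "monitoring", "stable_state", "no_treatment_state", "relapse_state")}
    relapse_drug = costs.relapse_drug_daily_cost * cl
    for k, s in enumerate(trace.states):
        if s.kind in (StateKind.STABLE_FIRST, StateKind.STABLE_CONT):
            d = drugs[seq[s.line]]
            rates["drug"][k] = cycle_drug_cost(d, cl)  # acquisition only
            if d.requires_monitoring:
                rates["monitoring"][k] = costs.monitoring_cost_per_cycle
            rates["stable_state"][k] = costs.stable_state_cost
        elif s.kind is StateKind.NO_TREATMENT:
            rates["no_treatment_state"][k] = costs.stable_state_cost
        elif s.kind in (StateKind.RELAPSE_FROM_STABLE, StateKind.RELAPSE_FROM_NT):
            rates["relapse_state"][k] = costs.relapse_state_cost
            rates["drug"][k] = relapse_drug
        # DEAD: all zero
    return rates


def _discount_factors(trace: CohortTrace, costs: CostInputs) -> np.ndarray:
    t = np.arange(trace.n_cycles)
    r = costs.discount_rate
    if r == 0.0:
        return np.ones_like(t, dtype=float)
    years = t * trace.population.cycle_length_days / DAYS_PER_YEAR
    return (1.0 + r) ** (-years)


def accumulate_costs(
    trace: CohortTrace,
    drugs: Mapping[str, DrugProfile],
    costs: CostInputs | None = None,
) -> CostLedger:
    """Full per-cycle cost ledger for a trace (``costs`` defaults to the
    population's own cost inputs)."""
    costs = costs if costs is not None else trace.population.costs
    rates = state_cost_rates(trace, drugs, costs)
    disc = _discount_factors(trace, costs)
    # Mid-cycle rule: average of start- and end-of-cycle occupancy, plus the
    # engine's adjustment for half-cycle relapse episodes that resolve before
    # the next boundary.
    mid = 0.5 * (trace.occupancy[:-1] + trace.occupancy[1:]) + trace.cost_basis_delta
    table = pd.DataFrame(
        0.0, index=pd.RangeIndex(trace.n_cycles, name="cycle"), columns=list(COST_CATEGORIES)
    )
    for cat, rate in rates.items():
        table[cat] = (mid @ rate) * disc

    charge = trace.flows["switch"].copy()
    if trace.options.charge_switch_on_reinitiation:
        charge = charge + trace.flows["reinit"]
    table["switching"] = charge * costs.switching_cost * disc

    wg = np.zeros(trace.n_cycles)
    eps = np.zeros(trace.n_cycles)
    for name, flow in trace.initiations.items():
        d = drugs[name]
        wg += flow * d.p_weight_gain * costs.ae_weight_gain_cost
        eps += flow * d.p_eps * costs.ae_eps_cost
    table["ae_weight_gain"] = wg * disc
    table["ae_eps"] = eps * disc

    if costs.inflation_factor != 1.0:
        table *= costs.inflation_factor
    return CostLedger(per_cycle=table)


def one_off_event_costs(
    trace: CohortTrace, drugs: Mapping[str, DrugProfile], costs: CostInputs | None = None
) -> float:
    """Total one-off adverse-event cost per patient (weight gain + EPS)."""
    costs = costs if costs is not None else trace.population.costs
    ledger = accumulate_costs(trace, drugs, costs)
    return float(ledger.totals["ae_weight_gain"] + ledger.totals["ae_eps"])


def switching_costs(trace: CohortTrace, costs: CostInputs | None = None) -> float:
    """Total medication-switching cost per patient."""
    costs = costs if costs is not None else trace.population.costs
    charge = trace.flows["switch"].copy()
    if trace.options.charge_switch_on_reinitiation:
        charge = charge + trace.flows["reinit"]
    disc = _discount_factors(trace, costs)
    return float((charge * costs.switching_cost * disc).sum() * costs.inflation_factor)
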