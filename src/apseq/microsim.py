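"""Individual-level microsimulation oracle.

Simulates one patient at a time through the same treatment-pathway rules as
the cohort engine — first-cycle adverse-event discontinuation, other-reason
discontinuation to no treatment, acute relapse with line advance (or drug
re-initiation), age-gated sequences, mortality applied before the competing
events, mid-cycle cost accrual and one-off event costs — using categorical
draws per patient-cycle. It is deliberately written as straight-line
per-patient code with its own bookkeeping, sharing no transition-matrix
machinery with the engine, so that agreement between the two is a genuine
cross-check of the pathway rules rather than of one shared implementation.

Monte-Carlo means of relapse counts, total cost and time in state converge to
the cohort engine's deterministic expectations; standard errors are computed
from the patient-level sample.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .config import CostInputs, DrugProfile, LifeTable, ModelOptions, PopulationSpec

__all__ = ["MicrosimResult", "microsimulate"]

_DAYS_PER_YEAR = 365.25

# patient phases (local to the oracle on purpose)
_FIRST, _CONT, _NT, _RELS, _RELNT, _DEAD = range(6)
_PHASE_NAMES = {
    _FIRST: "STABLE_FIRST",
    _CONT: "STABLE_CONT",
    _NT: "NO_TREATMENT",
    _RELS: "RELAPSE_FROM_STABLE",
    _RELNT: "RELAPSE_FROM_NT",
    _DEAD: "DEAD",
}


@dataclass
class MicrosimResult:
    n_patients: int
    mean_relapses: float
    se_relapses: float
    mean_cost: float
    se_cost: float
    time_in_state: dict[str, tuple[float, float]]  # kind -> (mean, se)


def microsimulate(
    population: PopulationSpec,
    drugs: Mapping[str, DrugProfile],
    lifetable: LifeTable,
    n_patients: int,
    seed: int,
    options: ModelOptions | None = None,
    costs: CostInputs | None = None,
) -> MicrosimResult:
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    options = options or ModelOptions()
    costs = costs if costs is not None else population.costs

    seq = population.sequence
    L = len(seq)
    cl = population.cycle_length_days
    N = int((_DAYS_PER_YEAR * population.horizon_years) // cl)
    frac = cl / _DAYS_PER_YEAR

    # per-cycle mortality and discount factors
    q = [0.0] * N
    disc = [1.0] * N
    r = costs.discount_rate
    for t in range(N):
        age = population.start_age + t * frac
        qa = min(lifetable.annual_death_prob(age) * population.smr, 1.0)
        q[t] = 1.0 - (1.0 - qa) ** frac
        if r:
            disc[t] = (1.0 + r) ** (-(t * frac))

    # per-line event probabilities and cycle cost rates
    p_ae = [drugs[s].p_disc_ae for s in seq]
    p_other = [drugs[s].p_disc_other for s in seq]
    p_rel = [drugs[s].p_relapse for s in seq]
    p_wg = [drugs[s].p_weight_gain for s in seq]
    p_eps = [drugs[s].p_eps for s in seq]
    stable_rate = []
    for s in seq:
        d = drugs[s]
        c = d.pack_price * d.daily_dose / d.pack_total_mg * cl
        if d.requires_monitoring:
            c += costs.monitoring_cost_per_cycle
        stable_rate.append(c + costs.stable_state_cost)
    nt_rate = costs.stable_state_cost
    rel_rate = costs.relapse_state_cost + costs.relapse_drug_daily_cost * cl
    wg_cost = costs.ae_weight_gain_cost
    eps_cost = costs.ae_eps_cost
    switch_cost = costs.switching_cost
    ntr = population.no_treatment_relapse
    charge_reinit = options.charge_switch_on_reinitiation
    reapply = options.reapply_first_cycle_on_reinitiation
    first_other = options.first_cycle_other_disc
    nt_return = options.nt_relapse_destination == "return"
    within = options.relapse_resolution == "within_cycle"
    last = L - 1

    # next eligible line per cycle (age gates move with the cohort's age)
    next_line: list[list[int | None]] = []
    for t in range(N):
        age = population.start_age + t * frac
        row: list[int | None] = []
        for i in range(L):
            dest: int | None = None
            if options.gate_mode == "strict":
                j = i + 1
                if j < L and age >= drugs[seq[j]].min_age:
                    dest = j
            else:
                for j in range(i + 1, L):
                    if age >= drugs[seq[j]].min_age:
                        dest = j
                        break
            row.append(dest)
        next_line.append(row)

    def rate(line: int, phase: int) -> float:
        if phase == _FIRST or phase == _CONT:
            return stable_rate[line]
        if phase == _NT:
            return nt_rate
        if phase == _RELS or phase == _RELNT:
            return rel_rate
        return 0.0

    rng = random.Random(seed)
    rnd = rng.random

    relapse_counts = np.empty(n_patients)
    patient_costs = np.empty(n_patients)
    times = np.zeros((n_patients, 6))

    for p in range(n_patients):
        line, phase = 0, _FIRST
        relapses = 0
        cost = 0.0
        tis = [0.0] * 6
        # model entry: initiation of the first drug
        if rnd() < p_wg[0]:
            cost += wg_cost * disc[0]
        if rnd() < p_eps[0]:
            cost += eps_cost * disc[0]
        for t in range(N):
            tis[phase] += 1.0
            cur_rate = rate(line, phase)
            df = disc[t]
            if q[t] > 0.0 and rnd() < q[t]:
                cost += 0.5 * cur_rate * df
                tis[_DEAD] += N - 1 - t
                break

            def resolve_relapse(kind_nt: bool) -> tuple[int, int]:
                """Where the current relapse episode ends; charges event costs."""
                nonlocal cost
                if kind_nt and nt_return:
                    if charge_reinit:
                        cost += switch_cost * df
                    if reapply:
                        if rnd() < p_wg[line]:
                            cost += wg_cost * df
                        if rnd() < p_eps[line]:
                            cost += eps_cost * df
                        return line, _FIRST
                    return line, _CONT
                j = next_line[t][line]
                if j is not None:
                    cost += switch_cost * df
                    if rnd() < p_wg[j]:
                        cost += wg_cost * df
                    if rnd() < p_eps[j]:
                        cost += eps_cost * df
                    return j, _FIRST
                if line == last or options.gate_mode == "skip":
                    if kind_nt and charge_reinit:
                        cost += switch_cost * df
                    return line, _CONT
                return line, _NT  # wait untreated for the gated next line

            nline, nphase = line, phase
            relapse_kind_nt: bool | None = None
            if phase == _FIRST or phase == _CONT:
                pa = p_ae[line] if phase == _FIRST else 0.0
                po = p_other[line] if (phase == _CONT or first_other) else 0.0
                v = rnd()
                if v < pa:
                    j = next_line[t][line]
                    if j is None:
                        nphase = _NT
                    else:
                        cost += switch_cost * df
                        if rnd() < p_wg[j]:
                            cost += wg_cost * df
                        if rnd() < p_eps[j]:
                            cost += eps_cost * df
                        nline, nphase = j, _FIRST
                elif v < pa + po:
                    nphase = _NT
                elif v < pa + po + p_rel[line]:
                    relapses += 1
                    relapse_kind_nt = False
                    nphase = _RELS
                else:
                    nphase = _CONT
            elif phase == _NT:
                if rnd() < ntr:
                    relapses += 1
                    relapse_kind_nt = True
                    nphase = _RELNT
            elif phase == _RELS:  # full_cycle resolution
                nline, nphase = resolve_relapse(False)
            else:  # _RELNT, full_cycle resolution
                nline, nphase = resolve_relapse(True)

            if within and relapse_kind_nt is not None:
                # half-cycle episode: half at origin, half at relapse rates,
                # destination treatment starts at the next boundary
                cost += 0.5 * (cur_rate + rel_rate) * df
                line, phase = resolve_relapse(relapse_kind_nt)
                continue
            if nline == line and nphase == phase:
                cost += cur_rate * df
            else:
                cost += 0.5 * (cur_rate + rate(nline, nphase)) * df
                line, phase = nline, nphase
        relapse_counts[p] = relapses
        patient_costs[p] = cost * costs.inflation_factor
        times[p] = tis

    def mse(x: np.ndarray) -> tuple[float, float]:
        m = float(x.mean())
        se = float(x.std(ddof=1) / np.sqrt(len(x))) if len(x) > 1 else 0.0
        return m, se

    mr, ser = mse(relapse_counts)
    mc, sec = mse(patient_costs)
    tstats = {_PHASE_NAMES[k]: mse(times[:, k]) for k in range(6)}
    return MicrosimResult(
        n_patients=n_patients,
        mean_relapses=mr,
        se_relapses=ser,
        mean_cost=mc,
        se_cost=sec,
        time_in_state=tstats,
    )
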