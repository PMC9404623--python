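"""Sequence-based Markov cohort engine.

The cohort moves through an ordered sequence of antipsychotic lines. Each line
``i`` contributes five states:

* ``STABLE_FIRST``: first cycle ever on the line's drug — adverse-event (AE)
  discontinuation risk applies only here, and by default other-reason
  discontinuation does not act yet;
* ``STABLE_CONT``: stable on the drug after the first cycle;
* ``NO_TREATMENT``: off treatment after other-reason discontinuation (or
  while waiting, untreated, for an age-gated next line), bound to line ``i``;
* ``RELAPSE_FROM_STABLE`` / ``RELAPSE_FROM_NT``: acute relapse episodes,
  distinguished by where they began.

plus one absorbing ``DEAD`` state. Death is applied first each cycle; event
probabilities act on survivors. All transitions occur mid-cycle.

A relapse while on treatment resolves by switching to the next line; a relapse
while untreated by default also advances to the next line (the stopped drug is
deemed unsuccessful; ``nt_relapse_destination="return"`` restores the
re-initiation reading instead). On the last line, or while the next line is
age-gated under strict ordering, relapse falls back to restarting the current
drug or waiting untreated, respectively. Under the default
``relapse_resolution="within_cycle"`` the relapse episode occupies the half
cycle between the mid-cycle transition and the next boundary, so the
destination treatment starts at the next cycle; ``"full_cycle"`` instead holds
the cohort in the relapse state for one whole cycle.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .config import DrugProfile, LifeTable, ModelOptions, PopulationSpec
from .derive import DAYS_PER_YEAR, cycle_death_prob

__all__ = [
    "StateKind",
    "State",
    "CohortTrace",
    "EngineError",
    "build_state_space",
    "transition_distribution",
    "run_cohort",
    "expected_relapses",
    "n_cycles_for",
    "FLOW_NAMES",
]

#: Per-cycle event-flow categories recorded on the trace.
FLOW_NAMES = ("relapse", "ae_disc", "other_disc", "switch", "reinit", "death")

_RELAPSE_KINDS = None  # set below


class EngineError(RuntimeError):
    """Raised when a model cannot be constructed from its inputs."""


class StateKind(enum.IntEnum):
    STABLE_FIRST = 0
    STABLE_CONT = 1
    NO_TREATMENT = 2
    RELAPSE_FROM_STABLE = 3
    RELAPSE_FROM_NT = 4
    DEAD = 5


_RELAPSE_KINDS = (StateKind.RELAPSE_FROM_STABLE, StateKind.RELAPSE_FROM_NT)


@dataclass(frozen=True)
class State:
    kind: StateKind
    line: int  # -1 for DEAD

    def __str__(self) -> str:  # e.g. "L2:STABLE_CONT", "DEAD"
        return "DEAD" if self.kind is StateKind.DEAD else f"L{self.line}:{self.kind.name}"


def build_state_space(population: PopulationSpec) -> list[State]:
    """Deterministically ordered state list: five states per line, DEAD last."""
    if len(population.sequence) == 0:
        raise EngineError("population sequence is empty")
    states = [
        State(kind, line)
        for line in range(len(population.sequence))
        for kind in (
            StateKind.STABLE_FIRST,
            StateKind.STABLE_CONT,
            StateKind.NO_TREATMENT,
            StateKind.RELAPSE_FROM_STABLE,
            StateKind.RELAPSE_FROM_NT,
        )
    ]
    states.append(State(StateKind.DEAD, -1))
    return states


def n_cycles_for(population: PopulationSpec) -> int:
    """Number of whole cycles in the horizon: floor(365.25 * years / cycle)."""
    return math.floor(DAYS_PER_YEAR * population.horizon_years / population.cycle_length_days)


def _next_line(
    seq: tuple[str, ...],
    drugs: Mapping[str, DrugProfile],
    i: int,
    age: float,
    gate_mode: str,
) -> int | None:
    """Destination line for an advance out of line ``i`` at cohort ``age``.

    ``strict``: the immediate next line, or None while it is age-gated (or
    does not exist). ``skip``: the first later line licensed at this age.
    """
    if gate_mode == "strict":
        j = i + 1
        if j < len(seq) and age >= drugs[seq[j]].min_age:
            return j
        return None
    for j in range(i + 1, len(seq)):
        if age >= drugs[seq[j]].min_age:
            return j
    return None


def _resolve_relapse(
    kind: StateKind,
    i: int,
    population: PopulationSpec,
    drugs: Mapping[str, DrugProfile],
    age: float,
    options: ModelOptions,
) -> tuple[State, tuple[str, ...]]:
    """Destination (and cost tags) when a relapse episode at line ``i`` ends."""
    seq = population.sequence
    last = len(seq) - 1
    if kind is StateKind.RELAPSE_FROM_NT and options.nt_relapse_destination == "return":
        if options.reapply_first_cycle_on_reinitiation:
            return State(StateKind.STABLE_FIRST, i), ("reinit", f"init:{seq[i]}")
        return State(StateKind.STABLE_CONT, i), ("reinit",)
    j = _next_line(seq, drugs, i, age, options.gate_mode)
    if j is not None:
        return State(StateKind.STABLE_FIRST, j), ("switch", f"init:{seq[j]}")
    if i == last or options.gate_mode == "skip":
        # no further licensed line exists: restart the current drug
        if kind is StateKind.RELAPSE_FROM_NT:
            return State(StateKind.STABLE_CONT, i), ("reinit",)
        return State(StateKind.STABLE_CONT, i), ()
    # strict ordering with the next line age-gated: wait untreated
    return State(StateKind.NO_TREATMENT, i), ()


def _state_transitions(
    state: State,
    q: float,
    population: PopulationSpec,
    drugs: Mapping[str, DrugProfile],
    age: float,
    options: ModelOptions,
    index: Mapping[State, int],
) -> list[tuple[int, float, tuple[str, ...]]]:
    """Outgoing transitions of one state as (dest index, probability, tags).

    Tags classify the flow for bookkeeping and costing: the event-flow names
    in :data:`FLOW_NAMES` plus ``init:<drug>`` marking a drug initiation.
    Relapse events are directed into the relapse states; how and when they
    resolve onward is governed by ``options.relapse_resolution``.
    """
    seq = population.sequence
    dead = index[State(StateKind.DEAD, -1)]
    if state.kind is StateKind.DEAD:
        return [(dead, 1.0, ())]

    i = state.line
    drug = drugs[seq[i]]
    surv = 1.0 - q
    out: list[tuple[int, float, tuple[str, ...]]] = []
    if q > 0:
        out.append((dead, q, ("death",)))

    if state.kind in (StateKind.STABLE_FIRST, StateKind.STABLE_CONT):
        first = state.kind is StateKind.STABLE_FIRST
        p_ae = drug.p_disc_ae if first else 0.0
        p_other = drug.p_disc_other if (not first or options.first_cycle_other_disc) else 0.0
        p_rel = drug.p_relapse
        stay = 1.0 - p_ae - p_other - p_rel
        if stay < -1e-12:
            raise EngineError(f"competing probabilities exceed 1 in state {state}")
        if p_ae > 0:
            j = _next_line(seq, drugs, i, age, options.gate_mode)
            if j is not None:
                out.append((index[State(StateKind.STABLE_FIRST, j)], surv * p_ae,
                            ("ae_disc", "switch", f"init:{seq[j]}")))
            else:  # no licensed onward line: abrupt stop to no treatment
                out.append((index[State(StateKind.NO_TREATMENT, i)], surv * p_ae, ("ae_disc",)))
        if p_other > 0:
            out.append((index[State(StateKind.NO_TREATMENT, i)], surv * p_other, ("other_disc",)))
        if p_rel > 0:
            out.append((index[State(StateKind.RELAPSE_FROM_STABLE, i)], surv * p_rel, ("relapse",)))
        if stay > 0:
            out.append((index[State(StateKind.STABLE_CONT, i)], surv * stay, ()))
    elif state.kind is StateKind.NO_TREATMENT:
        p_rel = population.no_treatment_relapse
        if p_rel > 0:
            out.append((index[State(StateKind.RELAPSE_FROM_NT, i)], surv * p_rel, ("relapse",)))
        if p_rel < 1:
            out.append((index[State(StateKind.NO_TREATMENT, i)], surv * (1.0 - p_rel), ()))
    elif state.kind in _RELAPSE_KINDS:
        # only reachable as a source state under full_cycle resolution
        dest, tags = _resolve_relapse(state.kind, i, population, drugs, age, options)
        out.append((index[dest], surv, tags))
    else:  # pragma: no cover
        raise EngineError(f"unhandled state {state}")
    return out


def transition_distribution(
    state: State,
    cycle: int,
    population: PopulationSpec,
    drugs: Mapping[str, DrugProfile],
    lifetable: LifeTable,
    options: ModelOptions | None = None,
) -> dict[State, float]:
    """The one-cycle transition distribution out of ``state`` at ``cycle``.

    Relapse events appear as mass entering the relapse states regardless of
    the resolution mode (under ``within_cycle`` that mass resolves onward
    before the next cycle boundary).
    """
    options = options or ModelOptions()
    states = build_state_space(population)
    index = {s: k for k, s in enumerate(states)}
    age = population.start_age + cycle * population.cycle_length_days / DAYS_PER_YEAR
    q = cycle_death_prob(age, lifetable, population.smr, population.cycle_length_days)
    dist: dict[State, float] = {}
    for dest, p, _tags in _state_transitions(state, q, population, drugs, age, options, index):
        dist[states[dest]] = dist.get(states[dest], 0.0) + p
    return dist


@dataclass
class CohortTrace:
    """Cycle-by-cycle cohort occupancy and event flows.

    ``occupancy[t]`` is the state distribution at the start of cycle ``t``
    (``n_cycles + 1`` rows; the last row is the end of the horizon).
    ``flows[name][t]`` is the fraction of the cohort making a transition of
    that class during cycle ``t``; ``initiations[drug][t]`` the fraction
    starting the drug during cycle ``t`` (model entry counts as an initiation
    at cycle 0). ``cost_basis_delta`` adjusts the mid-cycle costing basis for
    half-cycle relapse episodes that never appear in boundary occupancy.
    """

    population: PopulationSpec
    options: ModelOptions
    states: list[State]
    occupancy: np.ndarray  # (n_cycles + 1, n_states)
    flows: dict[str, np.ndarray]  # name -> (n_cycles,)
    initiations: dict[str, np.ndarray]  # drug -> (n_cycles,)
    cost_basis_delta: np.ndarray  # (n_cycles, n_states)
    ages: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    def occupancy_by_kind(self, kind: StateKind) -> np.ndarray:
        cols = [k for k, s in enumerate(self.states) if s.kind is kind]
        return self.occupancy[:, cols].sum(axis=1)

    def time_in_state(self) -> dict[str, float]:
        """Expected cycles spent per state kind (start-of-cycle convention)."""
        return {
            kind.name: float(self.occupancy_by_kind(kind)[:-1].sum())
            for kind in StateKind
        }

    def to_frame(self) -> pd.DataFrame:
        """Tidy (cycle, state, occupancy) table, deterministic row order."""
        rows = [
            {"cycle": t, "state": str(s), "occupancy": self.occupancy[t, k]}
            for t in range(self.occupancy.shape[0])
            for k, s in enumerate(self.states)
        ]
        return pd.DataFrame(rows, columns=["cycle", "state", "occupancy"])

    def export(self, outdir: str | Path, stem: str = "trace") -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(outdir / f"{stem}_occupancy.csv", index=False)
        payload = {name: arr.tolist() for name, arr in self.flows.items()}
        payload["initiations"] = {d: arr.tolist() for d, arr in self.initiations.items()}
        (outdir / f"{stem}_flows.json").write_text(json.dumps(payload, indent=1))


def run_cohort(
    population: PopulationSpec,
    drugs: Mapping[str, DrugProfile],
    lifetable: LifeTable,
    options: ModelOptions | None = None,
    sequence: tuple[str, ...] | None = None,
) -> CohortTrace:
    """Run the cohort over the full horizon and return its trace.

    ``sequence`` overrides the population's intervention sequence (used to run
    the comparator arm without redefining the population).
    """
    options = options or ModelOptions()
    options.validate()
    if sequence is not None:
        population = dataclasses.replace(population, sequence=tuple(sequence))
    population.validate(dict(drugs))
    states = build_state_space(population)
    index = {s: k for k, s in enumerate(states)}
    S = len(states)
    N = n_cycles_for(population)
    cl = population.cycle_length_days
    within = options.relapse_resolution == "within_cycle"

    occ = np.zeros((N + 1, S))
    occ[0, index[State(StateKind.STABLE_FIRST, 0)]] = 1.0
    flows = {name: np.zeros(N) for name in FLOW_NAMES}
    initiations = {name: np.zeros(N) for name in population.sequence}
    initiations[population.sequence[0]][0] = 1.0  # model entry
    delta = np.zeros((N, S))
    ages = population.start_age + np.arange(N + 1) * cl / DAYS_PER_YEAR

    # Transition tables only change when the death probability or an age gate
    # does; cache them by that key.
    cache: dict[tuple, list] = {}
    for t in range(N):
        age = float(ages[t])
        q = cycle_death_prob(age, lifetable, population.smr, cl)
        gates = tuple(
            _next_line(population.sequence, drugs, i, age, options.gate_mode)
            for i in range(len(population.sequence))
        )
        key = (q, gates)
        if key not in cache:
            table = [
                _state_transitions(s, q, population, drugs, age, options, index)
                for s in states
            ]
            # map relapse-state index -> (destination index, tags)
            res_map = {}
            if within:
                for k, s in enumerate(states):
                    if s.kind in _RELAPSE_KINDS:
                        dest, tags = _resolve_relapse(
                            s.kind, s.line, population, drugs, age, options
                        )
                        res_map[k] = (index[dest], tags)
            cache[key] = (table, res_map)
        table, res_map = cache[key]

        cur = occ[t]
        nxt = occ[t + 1]
        for src in range(S):
            mass = cur[src]
            if mass == 0.0:
                continue
            for dest, p, tags in table[src]:
                f = mass * p
                nxt[dest] += f
                for tag in tags:
                    if tag.startswith("init:"):
                        initiations[tag[5:]][t] += f
                    else:
                        flows[tag][t] += f
        if within:
            # resolve half-cycle relapse episodes before the next boundary
            for rel_idx, (dest, tags) in res_map.items():
                m = nxt[rel_idx]
                if m == 0.0:
                    continue
                nxt[rel_idx] = 0.0
                nxt[dest] += m
                delta[t, rel_idx] += 0.5 * m
                delta[t, dest] -= 0.5 * m
                for tag in tags:
                    if tag.startswith("init:"):
                        initiations[tag[5:]][t] += m
                    else:
                        flows[tag][t] += m
    trace = CohortTrace(
        population=population,
        options=options,
        states=states,
        occupancy=occ,
        flows=flows,
        initiations=initiations,
        cost_basis_delta=delta,
        ages=ages,
    )
    _check_trace(trace)
    return trace


def _check_trace(trace: CohortTrace, tol: float = 1e-10) -> None:
    sums = trace.occupancy.sum(axis=1)
    if not np.allclose(sums, 1.0, atol=tol, rtol=0.0):
        raise EngineError("occupancy does not sum to 1 in every cycle")
    dead = trace.occupancy_by_kind(StateKind.DEAD)
    if np.any(np.diff(dead) < -tol):
        raise EngineError("dead fraction decreased")


def expected_relapses(trace: CohortTrace) -> float:
    """Expected relapses per patient: total flow into the relapse states."""
    return float(trace.flows["relapse"].sum())
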