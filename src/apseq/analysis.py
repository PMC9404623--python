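"""Incremental comparison of treatment sequences, one-way DSA and PSA.

The headline analysis runs the cohort engine once per arm (intervention and
comparator sequence) and reports per-patient total costs, expected relapse
counts, and their differences (intervention minus comparator; negative
incremental cost = intervention is cost-saving).

Deterministic sensitivity analysis varies one parameter at a time between its
bounds (95% intervals when supplied, otherwise +/-20%) and ranks parameters by
the induced range in incremental cost (a tornado ordering). Probabilistic
sensitivity analysis jointly resamples all uncertain parameters — log-normal
on the log-odds scale for probabilities (so draws stay in [0, 1]), gamma
moment-matched to (mean, SE) for costs — with SE defaulting to 25% of the
central value, and reports the distribution of incremental cost and the
proportion of draws in which the intervention is cost-saving.

Each parameter draws from its own deterministically derived random substream,
so adding or removing a parameter never perturbs the draws of the others.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import (
    COST_MONEY_FIELDS,
    PROBABILITY_FIELDS,
    ConfigError,
    LifeTable,
    ModelConfig,
    PopulationSpec,
    UncertaintySpec,
    load_life_table,
)
from .costing import CostLedger, accumulate_costs
from .engine import expected_relapses, run_cohort

__all__ = [
    "IncrementalResult",
    "DSAEntry",
    "PSAResult",
    "compare_sequences",
    "run_base_case",
    "build_uncertainty",
    "get_parameter",
    "apply_parameters",
    "one_way_dsa",
    "run_psa",
    "summarize",
]

_Z95 = 1.959963984540054


@dataclass
class IncrementalResult:
    """Per-patient totals for both arms of one population, and differences."""

    population: str
    cost_intervention: float
    cost_comparator: float
    cost_difference: float
    relapses_intervention: float
    relapses_comparator: float
    relapse_difference: float
    category_differences: pd.Series  # intervention minus comparator, by category
    ledger_intervention: CostLedger | None = None
    ledger_comparator: CostLedger | None = None


@dataclass(frozen=True)
class DSAEntry:
    parameter_id: str
    low: float
    high: float
    out_low: float
    out_high: float

    @property
    def range(self) -> float:
        return abs(self.out_high - self.out_low)


@dataclass
class PSAResult:
    population: str
    n_draws: int
    seed: int
    base_cost_difference: float
    cost_difference_draws: np.ndarray
    relapse_difference_draws: np.ndarray
    samples: dict[str, np.ndarray]  # parameter_id -> sampled values (audit)

    @property
    def proportion_cost_saving(self) -> float:
        return float(np.mean(self.cost_difference_draws < 0.0))


def compare_sequences(
    population: PopulationSpec,
    drugs: Mapping,
    lifetable: LifeTable,
    intervention: Sequence[str] | None = None,
    comparator: Sequence[str] | None = None,
    options=None,
    keep_ledgers: bool = False,
) -> IncrementalResult:
    """Run both arms and return the incremental comparison."""
    intervention = tuple(intervention) if intervention is not None else population.sequence
    if comparator is None:
        if population.comparator_sequence is None:
            raise ConfigError(
                f"population {population.label!r} has no comparator sequence"
            )
        comparator = population.comparator_sequence
    comparator = tuple(comparator)

    arm = {}
    for name, seq in (("intervention", intervention), ("comparator", comparator)):
        trace = run_cohort(population, drugs, lifetable, options=options, sequence=seq)
        ledger = accumulate_costs(trace, drugs)
        arm[name] = (trace, ledger)
    li, lc = arm["intervention"][1], arm["comparator"][1]
    return IncrementalResult(
        population=population.label,
        cost_intervention=li.grand_total,
        cost_comparator=lc.grand_total,
        cost_difference=li.grand_total - lc.grand_total,
        relapses_intervention=expected_relapses(arm["intervention"][0]),
        relapses_comparator=expected_relapses(arm["comparator"][0]),
        relapse_difference=expected_relapses(arm["intervention"][0])
        - expected_relapses(arm["comparator"][0]),
        category_differences=li.totals - lc.totals,
        ledger_intervention=li if keep_ledgers else None,
        ledger_comparator=lc if keep_ledgers else None,
    )


def run_base_case(
    cfg: ModelConfig,
    lifetable: LifeTable | None = None,
    populations: Sequence[str] | None = None,
    keep_ledgers: bool = False,
) -> dict[str, IncrementalResult]:
    lifetable = lifetable if lifetable is not None else load_life_table()
    labels = list(populations) if populations is not None else list(cfg.populations)
    return {
        label: compare_sequences(
            cfg.populations[label], cfg.drugs, lifetable, options=cfg.options,
            keep_ledgers=keep_ledgers,
        )
        for label in labels
    }


# ---------------------------------------------------------------------------
# Parameter registry


def _parse_pid(pid: str) -> tuple[str, str, str]:
    parts = pid.split(".")
    if len(parts) != 3 or parts[0] not in ("drug", "costs", "population"):
        raise ConfigError(f"unknown parameter_id {pid!r}")
    return parts[0], parts[1], parts[2]


def parameter_kind(pid: str) -> str:
    """``"probability"`` or ``"money"`` — governs sampling and clamping."""
    domain, _, field = _parse_pid(pid)
    if domain == "drug" and field in PROBABILITY_FIELDS:
        return "probability"
    if domain == "population" and field == "no_treatment_relapse":
        return "probability"
    return "money"


def get_parameter(cfg: ModelConfig, pid: str) -> float:
    domain, name, field = _parse_pid(pid)
    if domain == "drug":
        if name not in cfg.drugs or not hasattr(cfg.drugs[name], field):
            raise ConfigError(f"unknown parameter_id {pid!r}")
        return float(getattr(cfg.drugs[name], field))
    if domain == "costs":
        if name not in cfg.populations or field not in COST_MONEY_FIELDS:
            raise ConfigError(f"unknown parameter_id {pid!r}")
        return float(getattr(cfg.populations[name].costs, field))
    if name not in cfg.populations or field != "no_treatment_relapse":
        raise ConfigError(f"unknown parameter_id {pid!r}")
    return float(cfg.populations[name].no_treatment_relapse)


def apply_parameters(cfg: ModelConfig, values: Mapping[str, float]) -> ModelConfig:
    """Return a new config with the given parameter values applied.

    Probabilities are clamped to [0, 1]; if a drug's competing
    discontinuation/relapse probabilities then sum above 1 the triple is
    rescaled proportionally to keep the row feasible.
    """
    drugs = dict(cfg.drugs)
    populations = dict(cfg.populations)
    for pid, value in values.items():
        domain, name, field = _parse_pid(pid)
        get_parameter(cfg, pid)  # existence check with a helpful error
        if parameter_kind(pid) == "probability":
            value = min(max(float(value), 0.0), 1.0)
        else:
            value = max(float(value), 0.0)
        if domain == "drug":
            drugs[name] = dataclasses.replace(drugs[name], **{field: value})
        elif domain == "costs":
            pop = populations[name]
            populations[name] = dataclasses.replace(
                pop, costs=dataclasses.replace(pop.costs, **{field: value})
            )
        else:
            populations[name] = dataclasses.replace(populations[name], **{field: value})
    for name, d in drugs.items():
        s = d.p_disc_ae + d.p_disc_other + d.p_relapse
        if s > 1.0:
            f = (1.0 - 1e-12) / s
            drugs[name] = dataclasses.replace(
                d,
                p_disc_ae=d.p_disc_ae * f,
                p_disc_other=d.p_disc_other * f,
                p_relapse=d.p_relapse * f,
            )
    out = ModelConfig(
        drugs=drugs, populations=populations, uncertainty=cfg.uncertainty, options=cfg.options
    )
    out.validate()
    return out


def build_uncertainty(cfg: ModelConfig) -> list[UncertaintySpec]:
    """Default uncertainty specification covering every clinical and cost
    parameter: log-normal for probabilities, gamma for money; explicit entries
    in ``cfg.uncertainty`` override the defaults for their parameter ids."""
    overrides = {u.parameter_id: u for u in cfg.uncertainty}
    specs: list[UncertaintySpec] = []

    def add(pid: str, family: str, central: float) -> None:
        if pid in overrides:
            specs.append(overrides[pid])
        else:
            specs.append(UncertaintySpec(parameter_id=pid, family=family, central=central))

    for name, d in cfg.drugs.items():
        for f in PROBABILITY_FIELDS:
            if f == "p_disc_ae" and d.disc_ae_unavailable:
                continue  # no source estimate exists; held fixed
            add(f"drug.{name}.{f}", "lognormal", getattr(d, f))
        add(f"drug.{name}.pack_price", "gamma", d.pack_price)
    for label, pop in cfg.populations.items():
        for f in COST_MONEY_FIELDS:
            add(f"costs.{label}.{f}", "gamma", getattr(pop.costs, f))
        add(f"population.{label}.no_treatment_relapse", "lognormal", pop.no_treatment_relapse)
    return specs


def relevant_specs(
    specs: Sequence[UncertaintySpec], population_label: str
) -> list[UncertaintySpec]:
    """Specs that can influence the given population's result."""
    keep = []
    for u in specs:
        domain, name, _ = _parse_pid(u.parameter_id)
        if domain == "drug" or name == population_label:
            keep.append(u)
    return keep


# ---------------------------------------------------------------------------
# Samplers


def _lognormal_sigma(spec: UncertaintySpec) -> float:
    if spec.ci95 is not None:
        lo, hi = spec.ci95
        if lo <= 0:
            raise ConfigError(
                f"uncertainty {spec.parameter_id!r}: lognormal ci95 must be positive"
            )
        return (math.log(hi) - math.log(lo)) / (2.0 * _Z95)
    se = spec.se if spec.se is not None else 0.25 * spec.central
    if spec.central == 0:
        return 0.0
    cv = se / spec.central
    return math.sqrt(math.log(1.0 + cv * cv))


def sample_lognormal_multiplier(spec: UncertaintySpec, rng: np.random.Generator, n: int) -> np.ndarray:
    """Median-1 log-normal multipliers encoding the requested spread."""
    sigma = _lognormal_sigma(spec)
    if sigma == 0.0:
        return np.ones(n)
    return np.exp(rng.normal(0.0, sigma, size=n))


def sample_gamma(spec: UncertaintySpec, rng: np.random.Generator, n: int) -> np.ndarray:
    """Gamma draws moment-matched to (central, SE); SE defaults to 25% of central."""
    se = spec.se if spec.se is not None else 0.25 * spec.central
    if spec.central <= 0 or se <= 0:
        return np.full(n, spec.central)
    shape = (spec.central / se) ** 2
    scale = se * se / spec.central
    return rng.gamma(shape, scale, size=n)


def _spec_rng(master_seed: int, pid: str) -> np.random.Generator:
    h = int.from_bytes(hashlib.sha256(pid.encode()).digest()[:4], "big") % (2**31 - 1)
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), h]))


def sample_parameter(spec: UncertaintySpec, master_seed: int, n: int) -> np.ndarray:
    """``n`` PSA draws for one parameter from its own substream."""
    if spec.family == "fixed":
        return np.full(n, spec.central)
    rng = _spec_rng(master_seed, spec.parameter_id)
    if spec.family == "gamma":
        return sample_gamma(spec, rng, n)
    m = sample_lognormal_multiplier(spec, rng, n)
    if parameter_kind(spec.parameter_id) == "probability":
        p = spec.central
        if p <= 0.0:
            return np.zeros(n)
        if p >= 1.0:
            return np.ones(n)
        odds = m * p / (1.0 - p)
        return odds / (1.0 + odds)
    return spec.central * m


# ---------------------------------------------------------------------------
# DSA / PSA


def _dsa_bounds(spec: UncertaintySpec) -> tuple[float, float]:
    lo = spec.dsa_low if spec.dsa_low is not None else spec.central * 0.8
    hi = spec.dsa_high if spec.dsa_high is not None else spec.central * 1.2
    if parameter_kind(spec.parameter_id) == "probability":
        lo, hi = max(lo, 0.0), min(hi, 1.0)
    return lo, hi


def one_way_dsa(
    cfg: ModelConfig,
    population_label: str,
    specs: Sequence[UncertaintySpec] | None = None,
    lifetable: LifeTable | None = None,
) -> list[DSAEntry]:
    """One-way sensitivity of the incremental cost; tornado-ordered
    (descending range, ties broken lexicographically by parameter id)."""
    lifetable = lifetable if lifetable is not None else load_life_table()
    specs = relevant_specs(
        specs if specs is not None else build_uncertainty(cfg), population_label
    )
    pop = cfg.populations[population_label]

    def incremental(cfg_mod: ModelConfig) -> float:
        return compare_sequences(
            cfg_mod.populations[population_label], cfg_mod.drugs, lifetable,
            options=cfg_mod.options,
        ).cost_difference

    entries = []
    for u in specs:
        lo, hi = _dsa_bounds(u)
        out_lo = incremental(apply_parameters(cfg, {u.parameter_id: lo}))
        out_hi = incremental(apply_parameters(cfg, {u.parameter_id: hi}))
        entries.append(
            DSAEntry(parameter_id=u.parameter_id, low=lo, high=hi, out_low=out_lo, out_high=out_hi)
        )
    entries.sort(key=lambda e: (-e.range, e.parameter_id))
    return entries


def run_psa(
    cfg: ModelConfig,
    population_label: str,
    n_draws: int = 1000,
    seed: int = 0,
    specs: Sequence[UncertaintySpec] | None = None,
    lifetable: LifeTable | None = None,
) -> PSAResult:
    """Probabilistic sensitivity analysis for one population."""
    if n_draws < 1:
        raise ConfigError("n_draws must be >= 1")
    lifetable = lifetable if lifetable is not None else load_life_table()
    specs = relevant_specs(
        specs if specs is not None else build_uncertainty(cfg), population_label
    )
    base = compare_sequences(
        cfg.populations[population_label], cfg.drugs, lifetable, options=cfg.options
    )
    samples = {u.parameter_id: sample_parameter(u, seed, n_draws) for u in specs}
    cost_d = np.empty(n_draws)
    rel_d = np.empty(n_draws)
    for k in range(n_draws):
        cfg_k = apply_parameters(cfg, {pid: vals[k] for pid, vals in samples.items()})
        res = compare_sequences(
            cfg_k.populations[population_label], cfg_k.drugs, lifetable, options=cfg_k.options
        )
        cost_d[k] = res.cost_difference
        rel_d[k] = res.relapse_difference
    return PSAResult(
        population=population_label,
        n_draws=n_draws,
        seed=seed,
        base_cost_difference=base.cost_difference,
        cost_difference_draws=cost_d,
        relapse_difference_draws=rel_d,
        samples=samples,
    )


# ---------------------------------------------------------------------------
# Reporting


def summarize(
    results: Mapping[str, IncrementalResult],
    outdir: str | Path,
    dsa: Mapping[str, Sequence[DSAEntry]] | None = None,
    psa: Mapping[str, PSAResult] | None = None,
) -> None:
    """Write base-case, tornado and PSA outputs as CSV + JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    cost_rows, relapse_rows = [], []
    for label, r in results.items():
        cost_rows.append(
            {"population": label, "intervention": r.cost_intervention,
             "comparator": r.cost_comparator, "difference": r.cost_difference}
        )
        relapse_rows.append(
            {"population": label, "intervention": r.relapses_intervention,
             "comparator": r.relapses_comparator, "difference": r.relapse_difference}
        )
    pd.DataFrame(cost_rows).to_csv(outdir / "base_case_costs.csv", index=False)
    pd.DataFrame(relapse_rows).to_csv(outdir / "base_case_relapses.csv", index=False)
    payload = {
        label: {
            "cost": {"intervention": r.cost_intervention, "comparator": r.cost_comparator,
                     "difference": r.cost_difference},
            "relapses": {"intervention": r.relapses_intervention,
                         "comparator": r.relapses_comparator,
                         "difference": r.relapse_difference},
            "category_differences": r.category_differences.to_dict(),
        }
        for label, r in results.items()
    }
    (outdir / "base_case.json").write_text(json.dumps(payload, indent=1))

    if dsa is not None:
        for label, entries in dsa.items():
            df = pd.DataFrame(
                [
                    {"parameter_id": e.parameter_id, "low": e.low, "high": e.high,
                     "out_low": e.out_low, "out_high": e.out_high, "range": e.range}
                    for e in entries
                ],
                columns=["parameter_id", "low", "high", "out_low", "out_high", "range"],
            )
            df.to_csv(outdir / f"tornado_{label}.csv", index=False)
            (outdir / f"tornado_{label}.json").write_text(df.to_json(orient="records"))

    if psa is not None:
        for label, r in psa.items():
            pd.DataFrame(
                {"cost_difference": r.cost_difference_draws,
                 "relapse_difference": r.relapse_difference_draws}
            ).to_csv(outdir / f"psa_draws_{label}.csv", index_label="draw")
            summary = {
                "population": label,
                "n_draws": r.n_draws,
                "seed": r.seed,
                "base_cost_difference": r.base_cost_difference,
                "mean_cost_difference": float(r.cost_difference_draws.mean()),
                "proportion_cost_saving": r.proportion_cost_saving,
            }
            (outdir / f"psa_summary_{label}.json").write_text(json.dumps(summary, indent=1))
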