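"""Probability and cost calculus for deriving per-cycle model inputs.

Published comparative-effectiveness evidence arrives as odds ratios (treatment
discontinuation) or relative risks (relapse) against placebo, and as annual
rates; the Markov engine needs per-cycle probabilities. These converters follow
the standard decision-modelling conventions: odds ratios act on the reference
odds, relative risks scale the reference probability, and annual-to-cycle
conversion assumes a constant event rate within the year (exponential
equivalence, 365.25-day years).

Drug acquisition costs are linear in milligrams: a daily cost is
``pack_price * daily_dose / pack_total_mg``, i.e. fractional tablets are
priced pro rata.
"""

from __future__ import annotations

from .config import DrugProfile, LifeTable

__all__ = [
    "DAYS_PER_YEAR",
    "or_to_probability",
    "rr_to_probability",
    "annual_prob_to_cycle",
    "cycle_prob_to_annual",
    "cycle_death_prob",
    "daily_drug_cost",
    "cycle_drug_cost",
]

DAYS_PER_YEAR = 365.25


def or_to_probability(odds_ratio: float, p_ref: float) -> float:
    """Convert an odds ratio and a reference probability to a probability.

    The reference odds ``p_ref / (1 - p_ref)`` are multiplied by the odds
    ratio and converted back: ``odds / (1 + odds)``.
    """
    if odds_ratio <= 0:
        raise ValueError("odds_ratio must be > 0")
    if not (0.0 <= p_ref < 1.0):
        raise ValueError("p_ref must be in [0, 1)")
    odds = odds_ratio * p_ref / (1.0 - p_ref)
    return odds / (1.0 + odds)


def rr_to_probability(rr: float, p_ref: float) -> float:
    """Scale a reference probability by a relative risk, capped at 1."""
    if rr <= 0:
        raise ValueError("rr must be > 0")
    if not (0.0 <= p_ref <= 1.0):
        raise ValueError("p_ref must be in [0, 1]")
    return min(rr * p_ref, 1.0)


def annual_prob_to_cycle(p_annual: float, cycle_days: float) -> float:
    """Annual probability -> per-cycle probability at constant event rate."""
    if not (0.0 <= p_annual <= 1.0):
        raise ValueError("p_annual must be in [0, 1]")
    if cycle_days <= 0:
        raise ValueError("cycle_days must be > 0")
    return 1.0 - (1.0 - p_annual) ** (cycle_days / DAYS_PER_YEAR)


def cycle_prob_to_annual(p_cycle: float, cycle_days: float) -> float:
    """Inverse of :func:`annual_prob_to_cycle`."""
    if not (0.0 <= p_cycle <= 1.0):
        raise ValueError("p_cycle must be in [0, 1]")
    if cycle_days <= 0:
        raise ValueError("cycle_days must be > 0")
    return 1.0 - (1.0 - p_cycle) ** (DAYS_PER_YEAR / cycle_days)


def cycle_death_prob(age: float, lifetable: LifeTable, smr: float, cycle_days: float) -> float:
    """Per-cycle death probability at a given age.

    The general-population annual death probability is multiplied by the
    standardised mortality ratio (capped at 1) before cycle conversion.
    """
    if smr <= 0:
        raise ValueError("smr must be > 0")
    q = min(lifetable.annual_death_prob(age) * smr, 1.0)
    return annual_prob_to_cycle(q, cycle_days)


def daily_drug_cost(pack_price: float, pack_total_mg: float, daily_dose: float) -> float:
    """Daily acquisition cost under linear-in-mg pricing (unrounded).

    Round to 2 decimals only for display; the model carries the exact value.
    """
    if pack_total_mg <= 0:
        raise ValueError("pack_total_mg must be > 0")
    if daily_dose < 0:
        raise ValueError("daily_dose must be >= 0")
    return pack_price * daily_dose / pack_total_mg


def cycle_drug_cost(
    profile: DrugProfile, cycle_days: float, monitoring_cost_per_cycle: float = 0.0
) -> float:
    """Acquisition cost per cycle, plus monitoring when the drug requires it."""
    if cycle_days <= 0:
        raise ValueError("cycle_days must be > 0")
    cost = daily_drug_cost(profile.pack_price, profile.pack_total_mg, profile.daily_dose) * cycle_days
    if profile.requires_monitoring:
        cost += monitoring_cost_per_cycle
    return cost
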