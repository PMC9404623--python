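import numpy as np
import pytest

from apseq.config import ModelOptions
from apseq.engine import (
    State,
    StateKind,
    build_state_space,
    expected_relapses,
    n_cycles_for,
    run_cohort,
    transition_distribution,
)

from conftest import make_drug, make_population

FULL = ModelOptions(relapse_resolution="full_cycle")


class TestStateSpace:
    @pytest.mark.parametrize("n_drugs,expected", [(1, 6), (4, 21), (5, 26)])
    def test_counts(self, n_drugs, expected):
        pop = make_population([f"d{i}" for i in range(n_drugs)])
        assert len(build_state_space(pop)) == expected

    def test_deterministic_order_ends_with_dead(self):
        pop = make_population(["a", "b"])
        states = build_state_space(pop)
        assert states[-1] == State(StateKind.DEAD, -1)
        assert states[0] == State(StateKind.STABLE_FIRST, 0)
        assert [s.line for s in states[:-1]] == [0] * 5 + [1] * 5


class TestTransitionDistribution:
    def test_stable_continuing_matches_published_row(self, base_cfg, zero_lifetable):
        """Adult lurasidone, no mortality: 18.2% stop for other reasons, 2.1%
        relapse, remainder stay stable."""
        pop = base_cfg.populations["adult"]
        dist = transition_distribution(
            State(StateKind.STABLE_CONT, 0), 0, pop, base_cfg.drugs, zero_lifetable
        )
        assert dist[State(StateKind.NO_TREATMENT, 0)] == pytest.approx(0.182)
        assert dist[State(StateKind.RELAPSE_FROM_STABLE, 0)] == pytest.approx(0.021)
        assert dist[State(StateKind.STABLE_CONT, 0)] == pytest.approx(1 - 0.182 - 0.021)
        assert sum(dist.values()) == pytest.approx(1.0, abs=1e-12)

    def test_first_cycle_exits_via_adverse_events_only_by_default(
        self, base_cfg, zero_lifetable
    ):
        pop = base_cfg.populations["adult"]
        dist = transition_distribution(
            State(StateKind.STABLE_FIRST, 0), 0, pop, base_cfg.drugs, zero_lifetable
        )
        # AE discontinuation switches to the next line's first cycle
        assert dist[State(StateKind.STABLE_FIRST, 1)] == pytest.approx(0.076)
        assert State(StateKind.NO_TREATMENT, 0) not in dist
        dist2 = transition_distribution(
            State(StateKind.STABLE_FIRST, 0), 0, pop, base_cfg.drugs, zero_lifetable,
            ModelOptions(first_cycle_other_disc=True),
        )
        assert dist2[State(StateKind.NO_TREATMENT, 0)] == pytest.approx(0.182)

    def test_dead_is_absorbing(self, base_cfg, lifetable):
        pop = base_cfg.populations["adult"]
        dist = transition_distribution(
            State(StateKind.DEAD, -1), 10, pop, base_cfg.drugs, lifetable
        )
        assert dist == {State(StateKind.DEAD, -1): 1.0}

    def test_no_events_means_identity(self, zero_lifetable):
        drugs = {"q": make_drug("q")}
        pop = make_population(["q"])
        dist = transition_distribution(
            State(StateKind.STABLE_CONT, 0), 0, pop, drugs, zero_lifetable
        )
        assert dist == {State(StateKind.STABLE_CONT, 0): 1.0}


class TestRelapseDynamics:
    def toy(self):
        return {"d0": make_drug("d0", p_relapse=0.5)}, make_population(["d0"], n_cycles=2)

    def test_full_cycle_relapse_occupies_one_cycle(self, zero_lifetable):
        """Half the cohort relapses in cycle 1; they sit out cycle 2 in the
        relapse state so only the stable half is at risk again."""
        drugs, pop = self.toy()
        trace = run_cohort(pop, drugs, zero_lifetable, options=FULL)
        assert trace.flows["relapse"] == pytest.approx([0.5, 0.25])
        assert expected_relapses(trace) == pytest.approx(0.75)

    def test_within_cycle_relapse_resolves_by_next_boundary(self, zero_lifetable):
        drugs, pop = self.toy()
        trace = run_cohort(pop, drugs, zero_lifetable)
        # episodes end mid-cycle: the whole cohort is back at risk next cycle
        assert trace.flows["relapse"] == pytest.approx([0.5, 0.5])
        assert trace.occupancy_by_kind(StateKind.RELAPSE_FROM_STABLE).sum() == 0.0

    def test_last_line_relapse_restarts_same_drug(self, zero_lifetable):
        drugs, pop = self.toy()
        trace = run_cohort(pop, drugs, zero_lifetable)
        # single line: no switches, no initiations beyond entry
        assert trace.flows["switch"].sum() == 0.0
        assert trace.initiations["d0"].sum() == 1.0

    def test_nt_relapse_advances_by_default_and_returns_when_asked(self, zero_lifetable):
        drugs = {
            "d0": make_drug("d0", p_disc_other=0.3),
            "d1": make_drug("d1"),
        }
        pop = make_population(["d0", "d1"], n_cycles=12)
        adv = run_cohort(pop, drugs, zero_lifetable)
        ret = run_cohort(
            pop, drugs, zero_lifetable, options=ModelOptions(nt_relapse_destination="return")
        )
        assert adv.initiations["d1"].sum() > 0.0  # untreated relapsers move on
        assert ret.initiations["d1"].sum() == 0.0  # they re-initiate d0 instead
        assert ret.flows["reinit"].sum() > 0.0


class TestCohortInvariants:
    @pytest.mark.parametrize("label", ["adolescent_13_17", "adolescent_15_17", "adult"])
    @pytest.mark.parametrize("arm", ["sequence", "comparator_sequence"])
    def test_conservation_and_monotone_death(self, base_cfg, lifetable, label, arm):
        pop = base_cfg.populations[label]
        trace = run_cohort(
            pop, base_cfg.drugs, lifetable, sequence=getattr(pop, arm)
        )
        sums = trace.occupancy.sum(axis=1)
        assert np.abs(sums - 1.0).max() < 1e-10
        dead = trace.occupancy_by_kind(StateKind.DEAD)
        assert (np.diff(dead) >= -1e-12).all()
        for arr in trace.flows.values():
            assert (arr >= -1e-12).all()

    def test_cycle_counts(self, base_cfg):
        assert n_cycles_for(base_cfg.populations["adult"]) == 43
        assert n_cycles_for(base_cfg.populations["adolescent_15_17"]) == 26
        assert n_cycles_for(base_cfg.populations["adolescent_13_17"]) == 43

    def test_no_events_stays_stable_forever(self, zero_lifetable):
        drugs = {"q": make_drug("q")}
        pop = make_population(["q"], n_cycles=10)
        trace = run_cohort(pop, drugs, zero_lifetable)
        stable = trace.occupancy_by_kind(StateKind.STABLE_FIRST) + trace.occupancy_by_kind(
            StateKind.STABLE_CONT
        )
        assert stable == pytest.approx(np.ones(11))

    def test_sequence_prefix_property(self, base_cfg, lifetable):
        """Silencing every event on lines 2+ cannot change line-0 occupancy."""
        import dataclasses

        pop = base_cfg.populations["adult"]
        base = run_cohort(pop, base_cfg.drugs, lifetable)
        silenced = dict(base_cfg.drugs)
        for name in pop.sequence[1:]:
            silenced[name] = dataclasses.replace(
                silenced[name],
                p_disc_ae=0.0, p_disc_other=0.0, p_relapse=0.0,
                disc_ae_unavailable=False,
            )
        alt = run_cohort(pop, silenced, lifetable)
        cols = [k for k, s in enumerate(base.states) if s.line == 0]
        assert base.occupancy[:, cols] == pytest.approx(alt.occupancy[:, cols], abs=1e-12)

    def test_doubling_mortality_does_not_increase_relapses(self, base_cfg, lifetable):
        import dataclasses

        pop = base_cfg.populations["adult"]
        base = expected_relapses(run_cohort(pop, base_cfg.drugs, lifetable))
        harsher = dataclasses.replace(pop, smr=2 * pop.smr)
        assert expected_relapses(run_cohort(harsher, base_cfg.drugs, lifetable)) <= base


class TestAgeGating:
    def test_gated_drugs_not_initiated_before_licensing_age(self, base_cfg, lifetable):
        pop = base_cfg.populations["adolescent_13_17"]
        trace = run_cohort(pop, base_cfg.drugs, lifetable)
        cl_years = pop.cycle_length_days / 365.25
        for name in ("aripiprazole", "paliperidone"):
            flows = trace.initiations[name]
            for t in np.nonzero(flows)[0]:
                assert pop.start_age + t * cl_years >= base_cfg.drugs[name].min_age
        assert trace.initiations["aripiprazole"].sum() > 0.0

    def test_strict_gate_holds_patients_untreated(self, base_cfg, lifetable):
        """Under strict ordering a 13-year-old cohort cannot jump past the
        gated lines to clozapine; under skip it can."""
        pop = base_cfg.populations["adolescent_13_17"]
        strict = run_cohort(pop, base_cfg.drugs, lifetable)
        skip = run_cohort(
            pop, base_cfg.drugs, lifetable, options=ModelOptions(gate_mode="skip")
        )
        cl_years = pop.cycle_length_days / 365.25
        first_15 = int(np.ceil((15.0 - pop.start_age) / cl_years))
        assert strict.initiations["clozapine"][:first_15].sum() == 0.0
        assert skip.initiations["clozapine"][:first_15].sum() > 0.0
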