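import dataclasses

import numpy as np
import pytest

from apseq.analysis import (
    apply_parameters,
    build_uncertainty,
    compare_sequences,
    get_parameter,
    one_way_dsa,
    run_base_case,
    run_psa,
    sample_gamma,
    sample_lognormal_multiplier,
    summarize,
)
from apseq.config import ConfigError, UncertaintySpec


class TestCompareSequences:
    def test_identical_sequences_cancel(self, base_cfg, lifetable):
        pop = base_cfg.populations["adult"]
        res = compare_sequences(
            pop, base_cfg.drugs, lifetable, comparator=pop.sequence
        )
        assert res.cost_difference == 0.0
        assert res.relapse_difference == 0.0
        assert (res.category_differences == 0.0).all()

    def test_differences_are_armwise_subtractions(self, base_cfg, lifetable):
        res = run_base_case(base_cfg, lifetable)["adolescent_15_17"]
        assert res.cost_difference == pytest.approx(
            res.cost_intervention - res.cost_comparator, abs=1e-8
        )
        assert res.relapse_difference == pytest.approx(
            res.relapses_intervention - res.relapses_comparator, abs=1e-8
        )
        assert res.category_differences.sum() == pytest.approx(res.cost_difference, abs=1e-8)


class TestParameterRegistry:
    def test_get_and_apply_roundtrip(self, base_cfg):
        pid = "drug.lurasidone_adult.p_disc_other"
        assert get_parameter(base_cfg, pid) == 0.182
        cfg2 = apply_parameters(base_cfg, {pid: 0.2})
        assert get_parameter(cfg2, pid) == 0.2
        assert get_parameter(base_cfg, pid) == 0.182  # original untouched

    def test_unknown_parameter_errors(self, base_cfg):
        for pid in ("drug.quetiapine.p_relapse", "costs.adult.nonsense", "weird.id"):
            with pytest.raises(ConfigError):
                get_parameter(base_cfg, pid)

    def test_probabilities_clamped_and_row_rescaled(self, base_cfg):
        cfg2 = apply_parameters(base_cfg, {"drug.cariprazine.p_disc_other": 1.5})
        d = cfg2.drugs["cariprazine"]
        assert d.p_disc_ae + d.p_disc_other + d.p_relapse <= 1.0
        cfg3 = apply_parameters(base_cfg, {"drug.cariprazine.p_relapse": -0.3})
        assert cfg3.drugs["cariprazine"].p_relapse == 0.0

    def test_default_uncertainty_covers_clinical_and_cost_parameters(self, base_cfg):
        specs = build_uncertainty(base_cfg)
        ids = {u.parameter_id for u in specs}
        assert "drug.lurasidone_adult.p_disc_other" in ids
        assert "costs.adult.relapse_state_cost" in ids
        assert "population.adult.no_treatment_relapse" in ids
        # the unestimated clozapine AE-discontinuation stays fixed
        assert "drug.clozapine.p_disc_ae" not in ids
        families = {u.parameter_id: u.family for u in specs}
        assert families["drug.haloperidol.p_relapse"] == "lognormal"
        assert families["costs.adult.stable_state_cost"] == "gamma"


class TestSamplers:
    def test_gamma_moments_match_requested_mean_and_se(self):
        spec = UncertaintySpec(parameter_id="costs.adult.stable_state_cost",
                               family="gamma", central=2000.0)
        rng = np.random.default_rng(11)
        x = sample_gamma(spec, rng, 100_000)
        assert x.mean() == pytest.approx(2000.0, rel=0.01)
        assert x.std() == pytest.approx(0.25 * 2000.0, rel=0.01)
        assert (x > 0).all()

    def test_lognormal_median_is_central(self):
        spec = UncertaintySpec(parameter_id="drug.haloperidol.p_relapse",
                               family="lognormal", central=0.049)
        rng = np.random.default_rng(13)
        m = sample_lognormal_multiplier(spec, rng, 100_000)
        assert np.median(m) == pytest.approx(1.0, rel=0.02)

    def test_probability_draws_stay_in_unit_interval(self, base_cfg):
        from apseq.analysis import sample_parameter

        spec = UncertaintySpec(parameter_id="drug.aripiprazole.p_disc_other",
                               family="lognormal", central=0.257, se=0.257)
        x = sample_parameter(spec, master_seed=5, n=20_000)
        assert ((x >= 0) & (x <= 1)).all()
        assert np.median(x) == pytest.approx(0.257, rel=0.05)


class TestDSA:
    def test_zero_width_bounds_give_zero_range(self, base_cfg, lifetable):
        spec = UncertaintySpec(
            parameter_id="drug.lurasidone_adult.p_relapse", family="lognormal",
            central=0.021, dsa_low=0.021, dsa_high=0.021,
        )
        entries = one_way_dsa(base_cfg, "adult", specs=[spec], lifetable=lifetable)
        assert entries[0].range == 0.0

    def test_unreached_drug_has_zero_range(self, base_cfg, lifetable):
        # paliperidone is not in either adult sequence
        spec = UncertaintySpec(
            parameter_id="drug.paliperidone.p_relapse", family="lognormal", central=0.019,
        )
        entries = one_way_dsa(base_cfg, "adult", specs=[spec], lifetable=lifetable)
        assert entries[0].range == 0.0

    def test_sorted_descending_with_lexicographic_ties(self, base_cfg, lifetable):
        entries = one_way_dsa(base_cfg, "adult", lifetable=lifetable)
        ranges = [e.range for e in entries]
        assert ranges == sorted(ranges, reverse=True)
        for a, b in zip(entries, entries[1:]):
            if a.range == b.range:
                assert a.parameter_id < b.parameter_id

    def test_raising_first_line_relapse_raises_intervention_relapses(
        self, base_cfg, lifetable
    ):
        pop = base_cfg.populations["adult"]
        values = []
        for p in (0.015, 0.021, 0.03):
            cfg = apply_parameters(base_cfg, {"drug.lurasidone_adult.p_relapse": p})
            res = compare_sequences(cfg.populations["adult"], cfg.drugs, lifetable)
            values.append(res.relapses_intervention)
        assert values[0] <= values[1] <= values[2]


class TestPSA:
    def test_same_seed_reproduces_draws(self, base_cfg, lifetable):
        a = run_psa(base_cfg, "adolescent_15_17", n_draws=20, seed=9, lifetable=lifetable)
        b = run_psa(base_cfg, "adolescent_15_17", n_draws=20, seed=9, lifetable=lifetable)
        assert np.array_equal(a.cost_difference_draws, b.cost_difference_draws)
        for pid in a.samples:
            assert np.array_equal(a.samples[pid], b.samples[pid])

    def test_substreams_independent_of_parameter_set(self, base_cfg, lifetable):
        """Dropping one parameter leaves every other parameter's draws
        untouched."""
        specs = build_uncertainty(base_cfg)
        full = run_psa(base_cfg, "adult", n_draws=10, seed=3,
                       specs=specs, lifetable=lifetable)
        reduced = run_psa(base_cfg, "adult", n_draws=10, seed=3,
                          specs=specs[1:], lifetable=lifetable)
        for pid in reduced.samples:
            assert np.array_equal(full.samples[pid], reduced.samples[pid])

    def test_degenerate_psa_equals_base_case(self, base_cfg, lifetable):
        specs = [
            dataclasses.replace(u, family="fixed") for u in build_uncertainty(base_cfg)
        ]
        res = run_psa(base_cfg, "adult", n_draws=5, seed=1, specs=specs, lifetable=lifetable)
        assert (res.cost_difference_draws == res.base_cost_difference).all()

    def test_vanishing_uncertainty_converges_to_base(self, base_cfg, lifetable):
        specs = [
            dataclasses.replace(u, se=1e-6 * u.central)
            for u in build_uncertainty(base_cfg)
        ]
        res = run_psa(base_cfg, "adolescent_15_17", n_draws=25, seed=2,
                      specs=specs, lifetable=lifetable)
        assert abs(res.cost_difference_draws.mean() - res.base_cost_difference) < (
            1e-3 * abs(res.base_cost_difference)
        )


def test_summarize_writes_all_outputs(base_cfg, lifetable, tmp_path):
    results = run_base_case(base_cfg, lifetable, populations=["adult"])
    dsa = {"adult": one_way_dsa(
        base_cfg, "adult",
        specs=[UncertaintySpec(parameter_id="drug.lurasidone_adult.p_relapse",
                               family="lognormal", central=0.021)],
        lifetable=lifetable,
    )}
    psa = {"adult": run_psa(base_cfg, "adult", n_draws=5, seed=4, lifetable=lifetable)}
    summarize(results, tmp_path, dsa=dsa, psa=psa)
    for name in (
        "base_case_costs.csv", "base_case_relapses.csv", "base_case.json",
        "tornado_adult.csv", "tornado_adult.json",
        "psa_draws_adult.csv", "psa_summary_adult.json",
    ):
        assert (tmp_path / name).exists()


def test_summarize_empty_dsa_writes_header_only(tmp_path):
    summarize({}, tmp_path, dsa={"adult": []})
    text = (tmp_path / "tornado_adult.csv").read_text().strip()
    assert text == "parameter_id,low,high,out_low,out_high,range"
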