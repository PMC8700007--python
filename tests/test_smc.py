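"""Packaged SMC model tests: conditions, ratios, phenotype and activity
scoring, and the knock-out / rapamycin response patterns."""

import math

import numpy as np
import pytest

from smcnet.smc import (ALIASES, CONDITIONS, DEFAULT_PANEL, PhenotypePanel,
                        activation_ratio, activity_scores, apply_condition,
                        canonical_name, load_smc_model, phenotype_scores,
                        run_conditions)
from smcnet.network import steady_state


class TestModelAsset:
    def test_parse_counts(self, smc_model):
        assert len(smc_model.species) == 81
        assert len(smc_model.reactions) == 138

    def test_exactly_seven_receptor_reactions(self, smc_model):
        roles = {s.name: s.role for s in smc_model.species}
        receptor_rx = [r for r in smc_model.reactions
                       if roles[r.target] == "receptor"]
        assert len(receptor_rx) == 7
        assert all(r.weight == 0.85 for r in receptor_rx)

    def test_input_weights_by_class(self, smc_model):
        inputs = {r.target: r.weight for r in smc_model.reactions
                  if r.is_input}
        assert inputs["Stress"] == inputs["ShearStress"] == 0.24054
        assert inputs["AngII_ex"] == inputs["IFNg_ex"] == 0.0
        assert inputs["Oxygen"] == inputs["Energy"] == 0.5
        assert inputs["Glucose"] == inputs["Leucine"] == \
            inputs["Fibrillin"] == 0.25

    def test_uniform_hill_parameterization(self, smc_model):
        assert smc_model.defaults.n == 1.4
        assert smc_model.defaults.ec50 == 0.52
        assert all(r.hill is None for r in smc_model.reactions)

    def test_subnetwork_wiring_matches_reduced_model(self, smc_model):
        # the embedded PI3K/AKT/mTOR axis must be exactly the sub-network
        # analyzed by the bifurcation module
        akt_in = smc_model.incoming("AKT")
        assert sorted(tuple(t.source for t in r.terms) for r in akt_in) == \
            [("PDK1",), ("mTORC2",)]
        assert [t.source for r in smc_model.incoming("mTOR")
                for t in r.terms] == ["AKT"]
        assert [t.source for r in smc_model.incoming("mTORC2")
                for t in r.terms] == ["mTOR"]
        assert [t.source for r in smc_model.incoming("PDK1")
                for t in r.terms] == ["PI3K"]


class TestConditions:
    def test_baseline_is_identity(self, smc_model):
        assert apply_condition(smc_model, "Baseline") == smc_model

    def test_ko_zeroes_tsc(self, smc_model):
        ko = apply_condition(smc_model, "KO")
        assert ko.species_by_name("TSC1_2").y_max == 0.0
        assert ko.species_by_name("mTORC1").y_max == 1.0

    def test_rapa_zeroes_tsc_and_mtorc1(self, smc_model):
        rapa = apply_condition(smc_model, "Rapa")
        assert rapa.species_by_name("TSC1_2").y_max == 0.0
        assert rapa.species_by_name("mTORC1").y_max == 0.0

    def test_unknown_override_species_rejected(self, smc_model):
        from smcnet.smc import Condition
        with pytest.raises(KeyError):
            apply_condition(smc_model, Condition("bad", y_max={"Nope": 0.0}))

    def test_removing_overrides_restores_baseline_bitwise(self, smc_model):
        ko = apply_condition(smc_model, "KO")
        restored = ko.with_y_max({"TSC1_2": 1.0})
        a = steady_state(smc_model)
        b = steady_state(restored)
        assert np.array_equal(a, b)


class TestRatios:
    def test_identical_states_give_unit_ratios(self, condition_states):
        st = condition_states["KO"]
        report = activation_ratio(st, st)
        for sp, val in report.ratios.items():
            if report.flags.get(sp) is None and st[sp] > 1e-9:
                assert val == pytest.approx(1.0)

    def test_zero_denominator_flagged_not_fabricated(self):
        report = activation_ratio({"A": 0.5, "B": 0.0}, {"A": 0.0, "B": 0.0})
        assert math.isinf(report["A"])
        assert report.flag("A") == "zero-denominator"
        assert math.isnan(report["B"])
        assert report.flag("B") == "indeterminate"

    def test_missing_species_raises(self, condition_states):
        with pytest.raises(KeyError):
            activation_ratio(condition_states["KO"],
                             condition_states["Baseline"], ["NotASpecies"])

    def test_alias_lookup(self, condition_states):
        assert canonical_name("p-S6") == "S6"
        report = activation_ratio(condition_states["KO"],
                                  condition_states["Baseline"],
                                  ["p-S6", "β-catenin"])
        assert "S6" in report.ratios and "bCatenin" in report.ratios
        assert report["p-S6"] == report["S6"]
        assert report["β-catenin"] > 0


class TestScores:
    def test_all_ones_state(self, smc_model):
        state = {s.name: 1.0 for s in smc_model.species}
        ph = phenotype_scores(state)
        assert (ph.contractile, ph.synthetic, ph.degradative) == (1, 1, 1)

    def test_all_zero_activities(self, smc_model):
        state = {s.name: 0.0 for s in smc_model.species}
        act = activity_scores(state)
        assert (act.proliferation, act.apoptosis,
                act.degradative_activity) == (0, 0, 0)

    def test_scores_equal_brute_force_means(self, condition_states):
        st = condition_states["Baseline"]
        ph = phenotype_scores(st)
        assert ph.contractile == pytest.approx(
            (st["SMMHC"] + st["SMA"] + st["SM22"]) / 3)
        assert ph.degradative == pytest.approx(
            (st["LAMP2"] + st["MMP2"] + st["S6"] + st["MITF"]
             + st["bCatenin"]) / 5)

    def test_panel_order_invariance(self, condition_states):
        st = condition_states["KO"]
        shuffled = PhenotypePanel(contractile=("SM22", "SMMHC", "SMA"))
        assert phenotype_scores(st, shuffled).contractile == \
            pytest.approx(phenotype_scores(st).contractile)

    def test_alternative_lamp_panel(self, condition_states):
        st = condition_states["KO"]
        alt = phenotype_scores(st, PhenotypePanel.lamp12())
        assert alt.degradative > 0

    def test_empty_panel_rejected(self, condition_states):
        with pytest.raises(ValueError):
            phenotype_scores(condition_states["KO"],
                             PhenotypePanel(contractile=()))


class TestConditionResponses:
    """Knock-out and rapamycin response patterns of the packaged model."""

    def test_mtorc1_axis_hyperactivated_by_ko(self, condition_states):
        base, ko = condition_states["Baseline"], condition_states["KO"]
        for sp in ("S6K", "S6", "E4EBP1"):
            assert ko[sp] > base[sp]

    def test_rapamycin_abolishes_mtorc1_output(self, condition_states):
        rapa = condition_states["Rapa"]
        assert rapa["S6K"] == pytest.approx(0.0, abs=1e-6)
        assert rapa["S6"] == pytest.approx(0.0, abs=1e-6)

    def test_activities_rise_in_ko_and_fall_under_rapamycin(
            self, condition_states):
        scores = {c: activity_scores(condition_states[c])
                  for c in ("Baseline", "KO", "Rapa")}
        for attr in ("proliferation", "apoptosis", "degradative_activity"):
            assert getattr(scores["KO"], attr) > getattr(scores["Baseline"],
                                                         attr)
            assert getattr(scores["Rapa"], attr) < getattr(scores["KO"], attr)

    def test_phenotype_shift_toward_degradative_in_ko(self, condition_states):
        base = phenotype_scores(condition_states["Baseline"])
        ko = phenotype_scores(condition_states["KO"])
        assert ko.degradative > base.degradative
        assert ko.contractile < base.contractile
        assert ko.synthetic < base.synthetic
        # a healthy cell shows little degradative character
        assert base.degradative < min(base.contractile, base.synthetic)
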