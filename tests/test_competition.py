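"""Survival and growth competition: scenario classifier, perturbation
screens, relative fitness, and the two-step community LP."""

import itertools

import numpy as np
import pytest

import endoflux as ef
from endoflux.competition import Scenario, classify_scenario
from endoflux.core import ModelError


class TestScenarioClassifier:
    def test_total_exhaustive_partition(self):
        """All 8 outcome classes are produced and partition the boolean cube."""
        seen = set()
        for triple in itertools.product([True, False], repeat=3):
            seen.add(classify_scenario(*triple))
        assert seen == set(Scenario)

    def test_unanimous_and_mixed_labels(self):
        assert classify_scenario(True, True, True) is Scenario.ALL_VIABLE
        assert classify_scenario(False, False, False) is Scenario.ALL_NONVIABLE
        assert classify_scenario(False, False, True) is Scenario.ONLY_ENDO_SURVIVES
        assert classify_scenario(True, True, False) is Scenario.ONLY_ENDO_DIES


class TestPerturbations:
    def test_enumerate_lists_consumables_once(self):
        env = ef.Environment({"A": (-20.0, 0.0), "N": (-10.0, 0.0)})
        assert ef.enumerate_perturbations(env) == ["A", "N"]

    def test_secretion_only_compound_excluded(self):
        env = ef.Environment({"W": (0.0, 5.0)})
        assert ef.enumerate_perturbations(env) == []
        assert ef.enumerate_perturbations(ef.Environment()) == []

    def test_removal_zeroes_uptake_keeps_secretion(self):
        env = ef.Environment({"A": (-20.0, 3.0)})
        out = ef.perturb(env, "A")
        assert out.bounds["A"] == (0.0, 3.0)
        assert ef.perturb(out, "A").bounds == out.bounds  # idempotent

    def test_unknown_compound_fatal(self):
        with pytest.raises(ModelError, match="not present"):
            ef.perturb(ef.Environment({"A": (-1.0, 0.0)}), "Z")


class TestSurvivalScreen:
    def test_repaired_pair_loses_either_way(self, toy):
        """Removing either substrate of the repaired cross-feeding pair kills
        the pair but spares the ancestor that does not need it."""
        fx = toy("TOY-PAIR-T-FIXED")
        records, scores = ef.survival_screen(fx.pair, fx.host, fx.endo)
        by_compound = {r.removed_compound: r.scenario for r in records}
        assert by_compound == {
            "A": Scenario.ONLY_ENDO_SURVIVES,
            "N": Scenario.ONLY_HOST_SURVIVES,
        }
        assert scores["pair"].proportion == 0.0
        assert scores["host"].proportion == 0.5
        assert scores["endo"].proportion == 0.5

    def test_sole_substrate_removal_kills_all(self, toy):
        fx = toy("TOY-PAIR-V")
        records, _ = ef.survival_screen(fx.pair, fx.host, fx.endo)
        assert [r.scenario for r in records] == [Scenario.ALL_NONVIABLE]

    def test_unused_compound_inert(self, toy):
        fx = toy("TOY-PAIR-V")
        env = ef.Environment(dict(fx.pair.joint_env.bounds, U=(-5.0, 0.0)))
        records, _ = ef.survival_screen(fx.pair, fx.host, fx.endo, env)
        by_compound = {r.removed_compound: r.scenario for r in records}
        assert by_compound["U"] is Scenario.ALL_VIABLE

    def test_order_invariant_robustness(self, toy):
        fx = toy("TOY-PAIR-T-FIXED")
        _, s1 = ef.survival_screen(fx.pair, fx.host, fx.endo)
        shuffled = ef.Environment(dict(reversed(list(fx.pair.joint_env.bounds.items()))))
        _, s2 = ef.survival_screen(fx.pair, fx.host, fx.endo, shuffled)
        assert {k: v.proportion for k, v in s1.items()} == {
            k: v.proportion for k, v in s2.items()
        }

    def test_nonviable_precondition_fatal(self, toy):
        fx = toy("TOY-PAIR-T")
        with pytest.raises(ModelError, match="viable"):
            ef.survival_screen(fx.pair, fx.host, fx.endo)


class TestRelativeFitness:
    @pytest.mark.parametrize(
        "pair,host,advantage,cls",
        [
            (10.0, 10.0, 0.0, "equal"),
            (5.0, 10.0, -0.5, "slower"),
            (11.89, 10.0, 0.189, "faster"),
        ],
    )
    def test_advantage_and_classification(self, pair, host, advantage, cls):
        fit = ef.pairwise_relative_fitness(pair, host)
        assert fit.advantage == pytest.approx(advantage)
        assert fit.classification == cls

    def test_equal_pair_fixture(self, toy):
        fx = toy("TOY-PAIR-V")
        pair_growth = ef.maximize_pair_growth(fx.pair).growth
        host_growth = ef.maximize_growth(fx.host, fx.pair.joint_env).growth
        fit = ef.pairwise_relative_fitness(pair_growth, host_growth)
        # host alone gets the doubled pool (20), the pair shares it (10)
        assert fit.classification == "slower"
        assert fit.advantage == pytest.approx(-0.5)

    def test_dead_reference_flagged(self):
        fit = ef.pairwise_relative_fitness(1.0, 0.0)
        assert not fit.defined and fit.advantage is None


class TestCommunityGrowth:
    def test_complementary_entities_unique(self, toy):
        fx = toy("TOY-COMM-U")
        res = ef.community_growth(fx.host, fx.endo, fx.pair, fx.shared_env)
        assert res.z == pytest.approx(40.0)
        assert res.entity_max["host"] == pytest.approx(20.0)
        assert res.entity_max["endo"] == pytest.approx(20.0)
        assert res.entity_max["pair"] == pytest.approx(0.0, abs=1e-9)
        assert res.unique

    def test_competing_entities_not_unique(self, toy):
        fx = toy("TOY-COMM-N")
        res = ef.community_growth(fx.host, fx.endo, fx.pair, fx.shared_env)
        assert res.z == pytest.approx(20.0)
        assert res.entity_max["host"] == pytest.approx(20.0)
        assert res.entity_min["host"] == pytest.approx(0.0, abs=1e-9)
        assert not res.unique

    def test_step2_bounded_by_z_and_witnesses_reach_z(self, toy):
        for name in ("TOY-COMM-U", "TOY-COMM-N"):
            fx = ef.make_fixture(name)
            res = ef.community_growth(fx.host, fx.endo, fx.pair, fx.shared_env)
            for entity in ("host", "endo", "pair"):
                assert res.entity_min[entity] <= res.entity_max[entity] + 1e-9
                assert res.entity_max[entity] <= res.z + 1e-9
                total = float(res.objective @ res.witnesses[entity])
                assert total == pytest.approx(res.z, rel=1e-9)

    def test_infeasible_community_flagged(self, toy):
        fx = toy("TOY-COMM-U")
        empty = ef.Environment({"A": (0.0, 0.0), "N": (0.0, 0.0)})
        res = ef.community_growth(fx.host, fx.endo, fx.pair, empty)
        assert res.z == pytest.approx(0.0, abs=1e-9)
        assert res.unique

    def test_pair_never_beats_both_ancestors(self, toy):
        """Across the shipped community fixtures the pair entity never takes
        a strictly larger share than both ancestors."""
        for name in ("TOY-COMM-U", "TOY-COMM-N"):
            fx = ef.make_fixture(name)
            res = ef.community_growth(fx.host, fx.endo, fx.pair, fx.shared_env)
            assert not (
                res.entity_max["pair"] > res.entity_max["host"] + 1e-9
                and res.entity_max["pair"] > res.entity_max["endo"] + 1e-9
            )
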