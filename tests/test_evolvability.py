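"""Bound-relaxation mutation scans: the relaxation formula, no-harm law,
reset integrity, tightening, and cross-entity comparison."""

import numpy as np
import pytest

import endoflux as ef
from endoflux.core import Compound, MetabolicModel, ModelError, Reaction
from endoflux.evolvability import MutationContext


class TestMutateBounds:
    @pytest.mark.parametrize(
        "bounds,factor,expected",
        [
            ((0.0, 5.0), 1000.0, (0.0, 5000.0)),
            ((-2.0, 3.0), 1000.0, (-2000.0, 3000.0)),
            ((-2.0, 3.0), 1.0, (-2.0, 3.0)),
        ],
    )
    def test_relaxation_formula(self, bounds, factor, expected):
        rxn = Reaction("r", {Compound("A", "c"): -1.0}, *bounds)
        out = ef.mutate_bounds(rxn, factor)
        assert (out.lower_bound, out.upper_bound) == expected
        assert (rxn.lower_bound, rxn.upper_bound) == bounds  # original untouched

    def test_factor_below_one_fatal(self):
        rxn = Reaction("r", {Compound("A", "c"): -1.0}, 0.0, 1.0)
        with pytest.raises(ModelError):
            ef.mutate_bounds(rxn, 0.5)


class TestScan:
    def test_bottleneck_beneficial_others_neutral(self, toy):
        effects = {
            e.reaction_id: e
            for e in ef.scan_mutations(toy("TOY-MUT").model, MutationContext.ANCESTRAL_HOST)
        }
        assert effects["T_M"].beneficial
        assert effects["T_M"].mutated_growth == pytest.approx(10.0)
        assert not effects["R_M"].beneficial
        assert effects["R_M"].mutated_growth == pytest.approx(5.0)

    def test_environment_limited_model_has_no_beneficial(self, toy):
        effects = ef.scan_mutations(toy("TOY-A").model, MutationContext.ANCESTRAL_HOST)
        assert not any(e.beneficial for e in effects)

    def test_pair_contexts_and_ancestor_cap(self, toy):
        """The transport mutation helps the pair too, but the mutated pair
        never outgrows the mutated ancestor."""
        mut = toy("TOY-MUT").model
        endo = mut.copy(new_id="TOY-MUT2")
        hh, eh = ef.harmonize_namespace([mut, endo])
        pair = ef.build_pair(hh, eh)
        anc = {e.reaction_id: e for e in ef.scan_mutations(hh, MutationContext.ANCESTRAL_HOST, pair.joint_env)}
        par = {e.reaction_id: e for e in ef.scan_mutations(pair, MutationContext.PAIR_HOST_REACTION)}
        assert par["T_M"].beneficial
        for rid in par:
            assert par[rid].mutated_growth <= anc[rid].mutated_growth + 1e-9

    def test_wrong_context_fatal(self, toy):
        with pytest.raises(ModelError, match="context"):
            ef.scan_mutations(toy("TOY-A").model, MutationContext.PAIR_HOST_REACTION)

    @pytest.mark.parametrize("seed", range(5))
    def test_no_harm_law(self, seed):
        """Relaxing bounds never decreases growth (ancestral and pair scans)."""
        host, endo, _ = ef.generate_pair_with_defect(
            ef.GeneratorParams.bound_limited(seed=seed), ef.Defect.NONE,
            host_id=f"h{seed}", endo_id=f"e{seed}",
        )
        hh, eh = ef.harmonize_namespace([host, endo])
        pair = ef.build_pair(hh, eh)
        for effects in (
            ef.scan_mutations(hh, MutationContext.ANCESTRAL_HOST),
            ef.scan_mutations(pair, MutationContext.PAIR_ENDO_REACTION),
        ):
            for e in effects:
                assert e.mutated_growth >= e.baseline_growth * (1 - 1e-6)

    def test_reset_integrity(self, toy):
        """After a full scan, bounds and baseline optimum are bit-identical."""
        model = toy("TOY-MUT").model
        before = [(r.lower_bound, r.upper_bound) for r in model.reactions]
        g_before = ef.maximize_growth(model).growth
        ef.scan_mutations(model, MutationContext.ANCESTRAL_HOST)
        assert [(r.lower_bound, r.upper_bound) for r in model.reactions] == before
        assert ef.maximize_growth(model).growth == g_before


class TestTighten:
    def test_divides_bounds_and_growth(self, toy):
        a = toy("TOY-A").model
        tight = ef.tighten_all_bounds(a, 100.0)
        assert ef.maximize_growth(tight).growth == pytest.approx(1.0)
        assert tight.reactions[0].upper_bound == pytest.approx(1.0)
        assert ef.maximize_growth(a).growth == pytest.approx(10.0)  # untouched

    def test_factor_one_disallowed(self, toy):
        with pytest.raises(ModelError):
            ef.tighten_all_bounds(toy("TOY-A").model, 1.0)

    def test_tighten_then_mutate_restores_single_binding_chain(self):
        """With one binding reaction, tighten(xk) then mutate(xk) on it
        restores the original optimum."""
        A_e = Compound("A", "e")
        model = MetabolicModel(
            id="ONE",
            compounds=[A_e],
            reactions=[Reaction("BIO", {A_e: -1.0}, 0.0, 100.0, is_biomass=True)],
            env_lower=np.array([-10.0]),
            env_upper=np.array([0.0]),
            biomass_index=0,
            collection_tag="toy",
        )
        base = ef.maximize_growth(model).growth
        tight = ef.tighten_all_bounds(model, 100.0)
        # the reaction bound (100 -> 1) now binds instead of the environment
        assert ef.maximize_growth(tight).growth == pytest.approx(1.0)
        tight.reactions[0] = ef.mutate_bounds(tight.reactions[0], 100.0)
        tight._S = None
        assert ef.maximize_growth(tight).growth >= base - 1e-9


class TestCompare:
    def test_bookkeeping_counts(self, toy):
        mut = toy("TOY-MUT").model
        endo = mut.copy(new_id="TOY-MUT2")
        hh, eh = ef.harmonize_namespace([mut, endo])
        pair = ef.build_pair(hh, eh)
        comp = ef.compare_evolvability(pair, hh, eh)
        assert len(comp.effects["pair_host_reaction"]) == len(hh.reactions)
        assert len(comp.paired_diff_host) == len(hh.reactions)
        assert set(comp.n_beneficial) == {
            "ancestral_host", "ancestral_endo", "pair_host_reaction", "pair_endo_reaction",
        }

    def test_identical_models_neutral_scans_symmetric(self, toy):
        """With identical, environment-limited host and endosymbiont every
        mutation is neutral in both contexts and the scans agree exactly."""
        a = toy("TOY-A").model
        endo = a.copy(new_id="TOY-A2")
        hh, eh = ef.harmonize_namespace([a, endo])
        pair = ef.build_pair(hh, eh)
        comp = ef.compare_evolvability(pair, hh, eh)
        host_side = {e.reaction_id: e.mutated_growth for e in comp.effects["pair_host_reaction"]}
        endo_side = {e.reaction_id: e.mutated_growth for e in comp.effects["pair_endo_reaction"]}
        assert host_side.keys() == endo_side.keys()
        for rid in host_side:
            assert host_side[rid] == pytest.approx(endo_side[rid], abs=1e-8)

    def test_identical_models_host_context_dominates(self, toy):
        """The roles are structurally asymmetric even for identical models:
        the host's transport serves both organisms, so relaxing it in the
        host context helps at least as much as in the endosymbiont context."""
        mut = toy("TOY-MUT").model
        endo = mut.copy(new_id="TOY-MUT2")
        hh, eh = ef.harmonize_namespace([mut, endo])
        pair = ef.build_pair(hh, eh)
        comp = ef.compare_evolvability(pair, hh, eh)
        host_side = {e.reaction_id: e.mutated_growth for e in comp.effects["pair_host_reaction"]}
        endo_side = {e.reaction_id: e.mutated_growth for e in comp.effects["pair_endo_reaction"]}
        for rid in host_side:
            assert host_side[rid] >= endo_side[rid] - 1e-9
        # the shared-bottleneck mutation is beneficial only in the host context
        assert host_side["T_M"] == pytest.approx(5.0)
        assert endo_side["T_M"] == pytest.approx(2.5)

    def test_exceed_flags_never_set_for_capped_pair(self, toy):
        mut = toy("TOY-MUT").model
        endo = mut.copy(new_id="TOY-MUT2")
        hh, eh = ef.harmonize_namespace([mut, endo])
        pair = ef.build_pair(hh, eh)
        comp = ef.compare_evolvability(pair, hh, eh)
        for ctx in ("pair_host_reaction", "pair_endo_reaction"):
            assert not any(e.exceeds_host_ancestor for e in comp.effects[ctx])
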