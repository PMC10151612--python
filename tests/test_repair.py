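"""Repair: candidate enumeration, cause diagnosis, minimal transport sets
(greedy vs exhaustive oracle), strip-and-repair recovery."""

import itertools

import pytest

import endoflux as ef
from endoflux.core import ModelError
from endoflux.repair import _viable_with
from endoflux.fba import VIABILITY_TOLERANCE


def _brute_force_minimum(pair, candidates):
    """Smallest viable transport subset by exhaustive enumeration over
    increasing subset sizes (independent oracle for the greedy search)."""
    for size in range(0, len(candidates) + 1):
        for subset in itertools.combinations(sorted(candidates), size):
            if _viable_with(pair, list(subset), VIABILITY_TOLERANCE):
                return set(subset)
    return None


class TestCandidates:
    def test_endosymbiont_requirement_only(self, toy):
        # A is available with both compartments but unused by the endosymbiont
        assert ef.candidate_transport_compounds(toy("TOY-PAIR-T").pair) == {"N"}

    def test_self_pair_candidate(self, toy):
        assert ef.candidate_transport_compounds(toy("TOY-PAIR-V").pair) == {"A"}

    def test_orphan_excluded(self, toy):
        # D has no cytoplasmic compartment anywhere -> criterion 2 fails
        assert "D" not in ef.candidate_transport_compounds(toy("TOY-PAIR-X").pair)


class TestAddTransport:
    def test_rescues_missing_route(self, toy):
        pair = ef.add_universal_transport(toy("TOY-PAIR-T").pair, ["N"])
        assert ef.maximize_pair_growth(pair).growth == pytest.approx(10.0)

    def test_redundant_route_no_change(self, toy):
        pair = toy("TOY-PAIR-V").pair
        augmented = ef.add_universal_transport(pair, ["A"])
        assert ef.maximize_pair_growth(augmented).growth == pytest.approx(
            ef.maximize_pair_growth(pair).growth
        )

    def test_empty_set_identity(self, toy):
        pair = toy("TOY-PAIR-T").pair
        assert ef.maximize_pair_growth(
            ef.add_universal_transport(pair, [])
        ).growth == pytest.approx(ef.maximize_pair_growth(pair).growth, abs=1e-9)

    def test_outside_candidates_fatal(self, toy):
        with pytest.raises(ModelError, match="candidate"):
            ef.add_universal_transport(toy("TOY-PAIR-T").pair, ["D"])

    def test_original_untouched(self, toy):
        pair = toy("TOY-PAIR-T").pair
        ef.add_universal_transport(pair, ["N"])
        assert pair.extra_columns == []

    @pytest.mark.parametrize("seed", range(5))
    def test_monotone(self, seed):
        """Adding any transport never decreases pair growth."""
        host, endo, gt = ef.generate_pair_with_defect(
            ef.GeneratorParams(seed=seed), ef.Defect.TRANSPORT,
            host_id=f"h{seed}", endo_id=f"e{seed}",
        )
        hh, eh = ef.harmonize_namespace([host, endo])
        pair = ef.build_pair(hh, eh)
        base = ef.maximize_pair_growth(pair).growth
        grown = base
        for c in sorted(ef.candidate_transport_compounds(pair)):
            pair = ef.add_universal_transport(pair, [c])
            new = ef.maximize_pair_growth(pair).growth
            assert new >= grown - 1e-9
            grown = new


class TestDiagnosis:
    def test_transport_cause(self, toy):
        res = ef.diagnose_nonviability(toy("TOY-PAIR-T").pair)
        assert res.cause_transport and not res.cause_access

    def test_access_cause(self, toy):
        res = ef.diagnose_nonviability(toy("TOY-PAIR-X").pair)
        assert res.cause_access and not res.cause_transport
        assert res.fixable

    def test_both_causes_resolve_in_combination(self):
        host, endo, _ = ef.generate_pair_with_defect(
            ef.GeneratorParams(seed=11), ef.Defect.BOTH
        )
        hh, eh = ef.harmonize_namespace([host, endo])
        res = ef.diagnose_nonviability(ef.build_pair(hh, eh))
        assert not res.cause_transport
        assert res.cause_access
        assert res.fixable

    def test_viable_pair_fatal(self, toy):
        with pytest.raises(ModelError, match="viable"):
            ef.diagnose_nonviability(toy("TOY-PAIR-V").pair)


class TestMinimalSet:
    @pytest.mark.parametrize("seed", [0, 1, 17, 99])
    def test_unique_rescuer_any_seed(self, toy, seed):
        assert ef.minimal_transport_set(toy("TOY-PAIR-T").pair, seed) == {"N"}

    def test_redundant_rescuers_singleton_each_valid(self, toy):
        pair = toy("TOY-PAIR-R").pair
        seen = set()
        for seed in range(8):
            s = ef.minimal_transport_set(pair, seed)
            assert len(s) == 1
            assert _viable_with(pair, sorted(s), VIABILITY_TOLERANCE)
            seen |= s
        assert seen == {"N1", "N2"}  # both singletons occur across seeds

    def test_joint_requirement_returns_pair(self, toy):
        assert ef.minimal_transport_set(toy("TOY-PAIR-J").pair, 3) == {"N1", "N2"}

    @pytest.mark.parametrize("seed", range(6))
    def test_irreducible_and_matches_oracle(self, seed):
        """Greedy result is viable and irreducible; on these instances it
        also matches the exhaustive-enumeration minimum cardinality."""
        host, endo, gt = ef.generate_pair_with_defect(
            ef.GeneratorParams(seed=seed, n_env_substrates=2),
            ef.Defect.TRANSPORT,
            n_deficits=1 + seed % 3,
        )
        hh, eh = ef.harmonize_namespace([host, endo])
        pair = ef.build_pair(hh, eh)
        got = ef.minimal_transport_set(pair, order_seed=seed)
        assert _viable_with(pair, sorted(got), VIABILITY_TOLERANCE)
        for member in got:
            assert not _viable_with(pair, sorted(got - {member}), VIABILITY_TOLERANCE)
        oracle = _brute_force_minimum(pair, ef.candidate_transport_compounds(pair))
        assert len(got) == len(oracle)
        assert got == gt.rescuing_compounds

    def test_precondition_breach_fatal(self, toy):
        with pytest.raises(ModelError, match="transport"):
            ef.minimal_transport_set(toy("TOY-PAIR-X").pair, 0)


class TestStripAndRepair:
    @pytest.mark.parametrize("seed", range(5))
    def test_recovers_deleted_transport(self, seed):
        """Deleting one essential host transport from a viable pair, the
        minimal-set search returns exactly the deleted compound."""
        host, endo, _ = ef.generate_pair_with_defect(
            ef.GeneratorParams(seed=seed), ef.Defect.NONE,
            host_id=f"h{seed}", endo_id=f"e{seed}",
        )
        target = f"S{seed % 3}"
        host = host.without_reaction(f"T_{target}.h{seed}")
        hh, eh = ef.harmonize_namespace([host, endo])
        pair = ef.build_pair(hh, eh)
        assert ef.maximize_pair_growth(pair).growth < VIABILITY_TOLERANCE
        assert ef.minimal_transport_set(pair, order_seed=seed) == {target}


class TestSingleSpecificity:
    def test_specific_and_redundant(self, toy):
        assert ef.single_specificity(toy("TOY-PAIR-T").pair) is True
        assert ef.single_specificity(toy("TOY-PAIR-R").pair) is False
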