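"""Model restructuring: namespace harmonization, environment
externalization, endosymbiont partitioning, environment merging."""

import numpy as np
import pytest
from scipy import sparse

import endoflux as ef
from endoflux.core import Compound, MetabolicModel, ModelError, Reaction


class TestHarmonize:
    def test_shared_namespace_and_shared_rows(self, toy):
        a, b = toy("TOY-A").model, toy("TOY-B").model
        ah, bh = ef.harmonize_namespace([a, b])
        assert ah.compounds == bh.compounds
        assert len(ah.compounds) == 6  # A@e A@c B@c + N@e N@c M@c
        assert ah.row_of(Compound("A", "e")) == bh.row_of(Compound("A", "e"))

    def test_growth_preserved_and_idempotent(self, toy):
        a, b = toy("TOY-A").model, toy("TOY-B").model
        before = [ef.maximize_growth(m).growth for m in (a, b)]
        once = ef.harmonize_namespace([a, b])
        after = [ef.maximize_growth(m).growth for m in once]
        assert after == pytest.approx(before, rel=1e-9)
        twice = ef.harmonize_namespace(once)
        assert [m.compounds for m in twice] == [m.compounds for m in once]

    def test_order_independent(self, toy):
        a, b, c = (toy(n).model for n in ("TOY-A", "TOY-B", "TOY-C"))
        ns1 = ef.harmonize_namespace([a, b, c])[0].compounds
        ns2 = ef.harmonize_namespace([c, a, b])[0].compounds
        assert ns1 == ns2

    def test_single_model_content_unchanged(self, toy):
        a = toy("TOY-A").model
        (h,) = ef.harmonize_namespace([a])
        assert sorted(h.compounds) == sorted(a.compounds)
        assert (h.S.toarray() != 0).sum() == (a.S.toarray() != 0).sum()

    def test_mixed_collections_fatal(self, toy):
        a = toy("TOY-A").model
        b = toy("TOY-B").model
        b.collection_tag = "other"
        with pytest.raises(ModelError, match="collection"):
            ef.harmonize_namespace([a, b])


class TestExternalize:
    def test_sink_bounds_become_env_bounds(self, raw_toy_a):
        ext = ef.externalize_environment(raw_toy_a)
        assert ext.environment.bounds == {"A": (-10.0, 0.0)}
        assert not ext.is_raw

    def test_growth_unchanged(self, raw_toy_a):
        raw_growth = ef.maximize_growth(raw_toy_a).growth
        ext_growth = ef.maximize_growth(ef.externalize_environment(raw_toy_a)).growth
        assert raw_growth == pytest.approx(10.0, rel=1e-9)
        assert ext_growth == pytest.approx(raw_growth, rel=1e-9)

    def test_no_exchanges_means_nothing_consumable(self, raw_toy_a):
        raw_toy_a.reactions = raw_toy_a.reactions[:3]
        ext = ef.externalize_environment(raw_toy_a)
        assert np.all(ext.env_lower == 0) and np.all(ext.env_upper == 0)
        assert not ef.is_viable(ext).viable

    def test_duplicate_exchanges_summed(self, raw_toy_a):
        raw_toy_a.reactions.append(
            Reaction("EX_A2", {Compound("A", "e"): -1.0}, -5.0, 0.0, is_exchange=True)
        )
        ext = ef.externalize_environment(raw_toy_a)
        assert ext.environment.bounds == {"A": (-15.0, 0.0)}

    def test_multi_compound_exchange_fatal(self, raw_toy_a):
        raw_toy_a.reactions[3].stoichiometry[Compound("B", "c")] = 1.0
        with pytest.raises(ModelError, match="exactly one compound"):
            ef.externalize_environment(raw_toy_a)

    @pytest.mark.parametrize("seed", range(6))
    def test_random_models_growth_preserved(self, seed):
        from conftest import de_externalize

        model, _ = ef.generate_model(
            ef.GeneratorParams(seed=seed, pathway_depth=3, redundancy=2),
            f"m{seed}",
        )
        raw = de_externalize(model)
        re_ext = ef.externalize_environment(raw)
        g_raw = ef.maximize_growth(raw).growth
        g_ext = ef.maximize_growth(re_ext).growth
        assert g_ext == pytest.approx(g_raw, rel=1e-9)


class TestPartition:
    def test_e_rows_remap_to_host_cytoplasm(self, toy):
        a = toy("TOY-A").model
        part = ef.partition_for_endosymbiont(a)
        assert part.e_row_targets == {Compound("A", "e"): Compound("A", "c")}
        assert not part.has_orphans
        assert [c.base_id for c in part.internal_compounds] == ["A", "B"]

    def test_orphan_flagged(self, toy):
        a, c = toy("TOY-A").model, toy("TOY-C").model
        ah, ch = ef.harmonize_namespace([a, c])
        part = ef.partition_for_endosymbiont(ch)
        assert part.orphan_base_ids == ["D"]

    def test_column_conservation(self, toy):
        """Reassembling S_E, S_EtoH and orphan rows recovers every original
        coefficient exactly."""
        a, c = toy("TOY-A").model, toy("TOY-C").model
        ah, ch = ef.harmonize_namespace([a, c])
        part = ef.partition_for_endosymbiont(ch)
        internal_index = {cc: i for i, cc in enumerate(part.internal_compounds)}
        orphan_index = {b: i for i, b in enumerate(part.orphan_base_ids)}
        S = ch.S.toarray()
        SE = part.S_E.toarray()
        SH = part.S_EtoH.toarray()
        SO = part.S_orphan.toarray()
        for j, rxn in enumerate(ch.reactions):
            for compound, coef in rxn.stoichiometry.items():
                if compound.compartment in ("c", "p"):
                    assert SE[internal_index[compound], j] == coef
                elif compound.base_id in orphan_index:
                    assert SO[orphan_index[compound.base_id], j] == coef
                else:
                    assert SH[ch.row_of(Compound(compound.base_id, "c")), j] == coef
            assert np.count_nonzero(S[:, j]) == (
                np.count_nonzero(SE[:, j])
                + np.count_nonzero(SH[:, j])
                + np.count_nonzero(SO[:, j])
            )


class TestMergeEnvironments:
    def test_disjoint_union_and_sum(self):
        e1 = ef.Environment({"A": (-10.0, 0.0)})
        e2 = ef.Environment({"N": (-10.0, 0.0)})
        assert ef.merge_environments(e1, e2).bounds == {
            "A": (-10.0, 0.0),
            "N": (-10.0, 0.0),
        }
        assert ef.merge_environments(e1, e1).bounds == {"A": (-20.0, 0.0)}

    def test_commutative_associative(self):
        envs = [
            ef.Environment({"A": (-10.0, 0.0), "B": (-1.0, 2.0)}),
            ef.Environment({"A": (-5.0, 1.0)}),
            ef.Environment({"C": (-3.0, 0.0)}),
        ]
        ab = ef.merge_environments(envs[0], envs[1])
        ba = ef.merge_environments(envs[1], envs[0])
        assert ab.bounds == ba.bounds
        left = ef.merge_environments(ab, envs[2])
        right = ef.merge_environments(envs[0], ef.merge_environments(envs[1], envs[2]))
        assert left.bounds == right.bounds

    def test_each_ancestor_viable_in_merged(self, toy):
        a, b = toy("TOY-A").model, toy("TOY-B").model
        ah, bh = ef.harmonize_namespace([a, b])
        joint = ef.merge_environments(ah.environment, bh.environment)
        assert ef.is_viable(ah, joint).viable
        assert ef.is_viable(bh, joint).viable


class TestSharedReactionFraction:
    def test_identity_disjoint_and_partial(self, toy):
        a = toy("TOY-A").model
        b = toy("TOY-B").model
        assert ef.shared_reaction_fraction(a, a) == 1.0
        assert ef.shared_reaction_fraction(a, b) == 0.0
        a2 = a.copy(new_id="A2")
        a2.reactions[0].id = "somewhere_else"
        # a: {T_A, R_A, BIO_A}; a2: {somewhere_else, R_A, BIO_A} -> 2/4
        assert ef.shared_reaction_fraction(a, a2) == 0.5
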