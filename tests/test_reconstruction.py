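import itertools

import pytest
from hypothesis import given, strategies as st

import mycoflux as mf
from mycoflux.reconstruction import (GapFillError, OrthologHit,
                                     UniversalReactionSet,
                                     add_exchange_reactions,
                                     apply_gap_fill, draft_from_references,
                                     filter_orthologs, gap_fill)
from mycoflux.minimodel import (MiniModelSpec, generate_mini_model,
                                generate_ortholog_hits, mini_universal_set)

from _oracles import gpr_truth


class TestFilterOrthologs:
    def test_inclusive_thresholds(self):
        keep = OrthologHit("q1", "s1", 40.0, 1e-30)
        drop_ident = OrthologHit("q2", "s2", 39.9, 1e-40)
        drop_eval = OrthologHit("q3", "s3", 80.0, 1e-20)
        mapping = filter_orthologs([keep, drop_ident, drop_eval])
        assert mapping == {"q1": {"s1"}}

    def test_multi_hits_preserved_as_sets(self):
        hits = [OrthologHit("q1", "s1", 60.0, 1e-50),
                OrthologHit("q1", "s2", 55.0, 1e-45)]
        assert filter_orthologs(hits) == {"q1": {"s1", "s2"}}

    def test_generated_table_passes_by_construction(self):
        hits = generate_ortholog_hits(seed=1, n_pass=37, n_fail=63)
        assert len(hits) == 100
        mapping = filter_orthologs(hits)
        assert len(mapping) == 37

    def test_empty_pass_set_gives_empty_mapping(self):
        hits = generate_ortholog_hits(seed=1, n_pass=0, n_fail=10)
        assert filter_orthologs(hits) == {}

    def test_generator_is_deterministic(self):
        assert (generate_ortholog_hits(7, 12, 8)
                == generate_ortholog_hits(7, 12, 8))

    @given(st.permutations(range(6)))
    def test_result_invariant_to_row_order(self, order):
        hits = generate_ortholog_hits(seed=3, n_pass=3, n_fail=3)
        baseline = filter_orthologs(hits)
        assert filter_orthologs([hits[i] for i in order]) == baseline


def _reference(model_id, rows, genes):
    model = mf.MetabolicModel(model_id)
    mets = set()
    for _, stoich, _ in rows:
        mets |= set(stoich)
    for mid in sorted(mets):
        comp = mid[mid.index("[") + 1] if "[" in mid else "c"
        model.add_metabolite(mf.Metabolite(mid, compartment=comp))
    model.genes |= set(genes)
    for rid, stoich, gpr in rows:
        model.add_reaction(mf.Reaction(rid, stoichiometry=stoich, gpr=gpr))
    return model


@pytest.fixture()
def two_references():
    ref_a = _reference("refA", [
        ("R1", {"a[c]": -1, "b[c]": 1}, "sA1"),
        ("R2", {"b[c]": -1, "c[c]": 1}, "sA2 and sA3"),
        ("R3", {"c[c]": -1, "d[c]": 1}, "sA4 or sA5"),
        ("R4", {"d[c]": -1, "e[c]": 1}, ""),
    ], ["sA1", "sA2", "sA3", "sA4", "sA5"])
    ref_b = _reference("refB", [
        ("R1", {"a[c]": -1, "b[c]": 1}, "sB1"),       # same stoichiometry
        ("R5", {"e[c]": -1, "f[c]": 1}, "sB2"),
    ], ["sB1", "sB2"])
    return ref_a, ref_b


class TestDraftFromReferences:
    def test_unsatisfied_and_rule_blocks_import(self, two_references):
        ref_a, _ = two_references
        draft = draft_from_references({"q1": {"sA2"}}, [ref_a])
        assert "R2" not in draft.reactions

    def test_shared_reaction_appears_once_with_merged_gpr(
            self, two_references):
        mapping = {"q1": {"sA1"}, "q2": {"sB1"}}
        draft = draft_from_references(mapping, list(two_references))
        assert "R1" in draft.reactions
        assert len([r for r in draft.reactions
                    if r.startswith("R1")]) == 1
        assert draft.reactions["R1"].gpr.genes() == {"q1", "q2"}

    def test_gpr_rewritten_in_query_ids(self, two_references):
        ref_a, _ = two_references
        draft = draft_from_references(
            {"q1": {"sA4"}, "q2": {"sA5"}}, [ref_a])
        assert draft.reactions["R3"].gpr.genes() == {"q1", "q2"}

    def test_geneless_reactions_always_import(self, two_references):
        ref_a, _ = two_references
        draft = draft_from_references({}, [ref_a])
        assert list(draft.reactions) == ["R4"]

    def test_draft_matches_set_logic_enumeration(self, two_references):
        """Import decisions equal a brute-force enumeration over every
        subset of mapped subject genes (independent GPR evaluator)."""
        refs = list(two_references)
        subjects = ["sA1", "sA2", "sA3", "sA4", "sA5", "sB1", "sB2"]
        for size in (0, 2, 4, len(subjects)):
            for chosen in itertools.islice(
                    itertools.combinations(subjects, size), 12):
                mapping = {f"q{i}": {s} for i, s in enumerate(chosen)}
                draft = draft_from_references(mapping, refs)
                expected = set()
                for ref in refs:
                    present = set(chosen) & ref.genes
                    absent = ref.genes - present
                    for rxn in ref.reactions.values():
                        if gpr_truth(rxn.gpr.to_string(), absent):
                            expected.add(
                                tuple(sorted(rxn.stoichiometry.items())))
                got = {tuple(sorted(r.stoichiometry.items()))
                       for r in draft.reactions.values()}
                assert got == expected

    def test_never_imports_unsatisfiable_gpr(self, two_references):
        refs = list(two_references)
        mapping = {"q1": {"sA2"}, "q2": {"sA4"}, "q3": {"sB2"}}
        draft = draft_from_references(mapping, refs)
        for rxn in draft.reactions.values():
            assert rxn.gpr.is_empty or rxn.gpr.evaluate(())


class TestAddExchanges:
    def test_one_exchange_per_extracellular_metabolite(self):
        model = mf.MetabolicModel("m")
        for base in ("glc", "xyl", "ara", "man", "fru"):
            model.add_metabolite(mf.Metabolite(f"{base}[e]", compartment="e"))
        add_exchange_reactions(model, [f"{b}[e]"
                                       for b in ("glc", "xyl", "ara", "man",
                                                 "fru")])
        assert len(model.exchanges()) == 5
        ex = model.reactions["EX_glc"]
        assert ex.stoichiometry == {"glc[e]": -1}
        assert (ex.lower_bound, ex.upper_bound) == (0.0, 1000.0)

    def test_cytosolic_metabolite_rejected(self):
        model = mf.MetabolicModel("m")
        model.add_metabolite(mf.Metabolite("glc[c]", compartment="c"))
        with pytest.raises(mf.ModelError):
            add_exchange_reactions(model, ["glc[c]"])

    def test_duplicate_exchange_rejected(self):
        model = mf.MetabolicModel("m")
        model.add_metabolite(mf.Metabolite("glc[e]", compartment="e"))
        add_exchange_reactions(model, ["glc[e]"])
        with pytest.raises(mf.ModelError):
            add_exchange_reactions(model, ["glc[e]"])


class TestGapFill:
    def test_growing_model_needs_nothing(self, glucose_minimal):
        assert gap_fill(glucose_minimal, mini_universal_set(),
                        "BIOMASS", 1e-3) == []

    def test_rhamnose_gap_restored_by_transport_and_dehydrogenase(self):
        model = generate_mini_model(
            MiniModelSpec(include_rhamnose_pathway=False))
        model = mf.set_medium(model, mf.minimal_medium("EX_rmn"))
        added = gap_fill(model, mini_universal_set(), "BIOMASS", 1e-3)
        assert sorted(added) == ["RMND", "RMNt"]
        filled = apply_gap_fill(model, mini_universal_set(), added)
        assert mf.solve_fba(filled).objective_value >= 1e-3

    def test_pfk_gap_restored_by_single_addition(self):
        model = generate_mini_model(MiniModelSpec(knockouts=("PFK",)))
        model = mf.set_medium(model, mf.minimal_medium())
        added = gap_fill(model, mini_universal_set(), "BIOMASS", 1e-3)
        assert added == ["PFK"]

    def test_returned_set_is_minimal(self):
        model = generate_mini_model(
            MiniModelSpec(include_rhamnose_pathway=False))
        model = mf.set_medium(model, mf.minimal_medium("EX_rmn"))
        universal = mini_universal_set()
        added = gap_fill(model, universal, "BIOMASS", 1e-3)
        for rid in added:
            subset = [r for r in added if r != rid]
            partial = apply_gap_fill(model, universal, subset)
            state = mf.solve_fba(partial)
            assert (not state.optimal) or state.objective_value < 1e-3

    def test_unfillable_reports_blocked_precursors(self):
        model = generate_mini_model(
            MiniModelSpec(include_rhamnose_pathway=False))
        model = mf.set_medium(model, mf.minimal_medium("EX_rmn"))
        empty = UniversalReactionSet()
        with pytest.raises(GapFillError) as err:
            gap_fill(model, empty, "BIOMASS", 1e-3)
        assert len(err.value.blocked_precursors) > 0
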