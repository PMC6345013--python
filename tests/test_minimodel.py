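import json

import pytest

import mycoflux as mf
from mycoflux.core import check_balance
from mycoflux.minimodel import (GENOME_GC_CONTENT, MiniModelSpec,
                                composition_fixture, generate_mini_model,
                                generate_ortholog_hits, table3_fixture)


class TestGeneratorContract:
    def test_model_satisfies_all_structural_invariants(self, mini_model):
        mini_model.validate()  # raises on violation
        assert set(mini_model.compartments) == {"c", "e"}

    def test_internal_reactions_mass_and_charge_balanced(self, mini_model):
        for report in check_balance(mini_model):
            assert report.skipped or report.balanced, report.reaction_id

    def test_network_size(self, mini_model):
        internal = [r for r in mini_model.reactions.values()
                    if r.kind in ("metabolic", "spontaneous")]
        assert 40 <= len(internal) <= 60
        assert len(mini_model.reactions) < 110

    def test_required_pathway_content_present(self, mini_model):
        for rid in ("PFK", "PPP_OX", "DDPA", "DHQS", "DHQD", "SHKDH", "SHKK",
                    "PSCVT", "CHORS", "CHORM", "PTAL_TYR", "PTAL_PHE", "C4H",
                    "4CL", "ACC", "CHS", "CHS_NAR", "ROMT", "P450_PICE",
                    "g0770", "FAS160", "BIOMASS"):
            assert rid in mini_model.reactions, rid
        for ex in ("EX_glc", "EX_suc", "EX_rmn", "EX_etoh", "EX_resv",
                   "EX_ptsb", "EX_pice", "EX_co2", "EX_o2", "EX_nh4",
                   "EX_pi", "EX_so3", "EX_h2o", "EX_h"):
            assert ex in mini_model.reactions, ex

    def test_g0770_equation_matches_printed_string(self, mini_model):
        rxn = mini_model.reactions["g0770"]
        consumed = {m for m, c in rxn.stoichiometry.items() if c < 0}
        produced = {m for m, c in rxn.stoichiometry.items() if c > 0}
        assert consumed == {"ac[c]", "coa[c]", "atp[c]"}
        assert produced == {"h[c]", "accoa[c]", "ppi[c]", "amp[c]"}
        assert all(abs(c) == 1 for c in rxn.stoichiometry.values())

    def test_default_generation_is_bit_reproducible(self, tmp_path):
        a, b = tmp_path / "a.json", tmp_path / "b.json"
        mf.write_model(generate_mini_model(), a)
        mf.write_model(generate_mini_model(), b)
        assert a.read_text() == b.read_text()

    def test_seed_only_matters_with_jitter(self, tmp_path):
        plain = generate_mini_model(MiniModelSpec(seed=123))
        default = generate_mini_model()
        assert {r: plain.reactions[r].upper_bound for r in plain.reactions} \
            == {r: default.reactions[r].upper_bound for r in default.reactions}
        jittered = generate_mini_model(
            MiniModelSpec(seed=123, bound_jitter=0.1))
        again = generate_mini_model(MiniModelSpec(seed=123, bound_jitter=0.1))
        assert any(
            jittered.reactions[r].upper_bound != default.reactions[r].upper_bound
            for r in jittered.reactions)
        assert all(
            jittered.reactions[r].upper_bound == again.reactions[r].upper_bound
            for r in jittered.reactions)

    def test_knockout_of_absent_reaction_rejected(self):
        with pytest.raises(mf.ModelError):
            generate_mini_model(MiniModelSpec(knockouts=("NOT_A_REACTION",)))


class TestGrowthAndProduction:
    def test_glucose_growth_and_resveratrol_capacity(self, glucose_minimal,
                                                     study_model):
        growth = mf.solve_fba(glucose_minimal)
        assert growth.optimal and growth.objective_value > 1e-6
        fixed = mf.fix_growth(study_model, 0.055)
        resv = mf.solve_fba(fixed, objective="EX_resv")
        assert resv.optimal and resv.objective_value > 1e-6

    def test_removing_chs_zeroes_resveratrol_export(self, study_model):
        model = generate_mini_model(MiniModelSpec(knockouts=("CHS",)))
        study = mf.set_medium(model, mf.stilbene_study_medium())
        state = mf.solve_fba(study, objective="EX_resv")
        assert state.optimal
        assert state.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_resveratrol_limited_by_precursor_bottleneck(self, study_model):
        """Maximum stilbene export cannot exceed either precursor supply:
        one p-coumaroyl-CoA and three malonyl-CoA per resveratrol."""
        fixed = mf.fix_growth(study_model, 0.055)
        resv_max = mf.solve_fba(fixed, objective="EX_resv").objective_value
        blocked = fixed.copy()
        for rid in ("CHS", "CHS_NAR"):
            blocked.reactions[rid].upper_bound = 0.0
        bounds = {}
        for mid, label in (("4cmcoa[c]", "coumaroyl"), ("malcoa[c]", "malonyl")):
            probe = blocked.copy()
            # the probe returns the CoA carrier so the conserved moiety
            # is not drained along with the acyl group
            probe.add_reaction(mf.Reaction(
                "DM_probe", stoichiometry={mid: -1, "coa[c]": 1},
                kind="demand"))
            bounds[label] = mf.solve_fba(
                probe, objective="DM_probe").objective_value
        assert resv_max > 1e-6
        assert resv_max <= bounds["coumaroyl"] + 1e-6
        assert resv_max <= bounds["malonyl"] / 3.0 + 1e-6

    def test_acetate_activation_engages_with_ethanol(self, study_model):
        """With ethanol closed the acetyl-CoA synthetase step is idle; as
        ethanol uptake opens, its flux follows the assimilated ethanol."""
        fixed = mf.fix_growth(study_model, 0.055)
        points = mf.robustness_scan(fixed, "EX_etoh", [-0.05, 0.0],
                                    objective="EX_resv")
        closed = next(p for p in points if p.value == 0.0)
        opened = next(p for p in points if p.value == -0.05)
        assert abs(closed.fluxes["g0770"]) <= 1e-6
        assert opened.fluxes["g0770"] > 0.01

    def test_ethanol_option_removes_assimilation_route(self):
        model = generate_mini_model(
            MiniModelSpec(include_ethanol_assimilation=False))
        for rid in ("EX_etoh", "ETOHt", "ALCD2x", "ALDD2y"):
            assert rid not in model.reactions
        model.validate()


class TestOrthologGenerator:
    def test_pass_and_fail_rows_by_construction(self):
        hits = generate_ortholog_hits(seed=11, n_pass=20, n_fail=30)
        passing = [h for h in hits
                   if h.identity >= 40.0 and h.evalue <= 1e-30]
        assert len(passing) == 20
        failing = [h for h in hits
                   if h.identity < 40.0 or h.evalue > 1e-30]
        assert len(failing) == 30

    def test_queries_are_unique(self):
        hits = generate_ortholog_hits(seed=2, n_pass=15, n_fail=15)
        assert len({h.query for h in hits}) == 30

    def test_different_seeds_shuffle_differently(self):
        a = generate_ortholog_hits(seed=1, n_pass=10, n_fail=10)
        b = generate_ortholog_hits(seed=2, n_pass=10, n_fail=10)
        assert [h.query for h in a] != [h.query for h in b]


class TestTranscribedFixtures:
    def test_carbon_and_nitrogen_row_counts(self):
        records = table3_fixture()
        assert sum(r.role == "carbon" for r in records) == 20
        assert sum(r.role == "nitrogen" for r in records) == 12

    def test_gap_filled_substrates_flagged(self):
        flagged = {r.substrate for r in table3_fixture() if r.gap_filled}
        assert flagged == {"Starch", "Sucrose", "Rhamnose", "Dextrin"}

    def test_composition_fractions_sum_to_one(self):
        comp, masses = composition_fixture()
        assert sum(comp.macro_fractions.values()) == pytest.approx(1.0)
        assert comp.macro_fractions["cell_wall"] == 0.32
        assert comp.macro_fractions["nucleic_acid"] == 0.04
        for table in comp.monomer_fractions.values():
            assert sum(table.values()) == pytest.approx(1.0)
        assert len(comp.monomer_fractions["protein"]) == 20
        assert set(masses) >= set().union(
            *(set(t) for t in comp.monomer_fractions.values()))

    def test_nucleic_acid_fractions_follow_genomic_gc(self):
        comp, _ = composition_fixture()
        na = comp.monomer_fractions["nucleic_acid"]
        # GC-derived mole fractions weight G+C above A+T here because the
        # GC content exceeds 50% and dGMP/dCMP are at least as heavy
        assert na["dGMP"] > na["dAMP"]
        assert GENOME_GC_CONTENT == pytest.approx(0.5096)
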