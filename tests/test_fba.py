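import numpy as np
import pytest

import mycoflux as mf
from mycoflux.fba import (FLUX_ZERO_TOL, MediumSpec, flux_variability,
                          metabolite_connectivity, robustness_scan,
                          set_medium, solve_fba)

from _oracles import cobra_fba, cobra_fva


class TestMedium:
    def test_uptake_becomes_negative_lower_bound(self, mini_model):
        model = set_medium(mini_model, MediumSpec(uptakes={"EX_glc": 2.0}))
        assert model.reactions["EX_glc"].lower_bound == -2.0

    def test_unlisted_exchanges_are_closed(self, mini_model):
        model = set_medium(mini_model, MediumSpec(uptakes={"EX_glc": 2.0}))
        assert model.reactions["EX_etoh"].lower_bound == 0.0
        assert model.reactions["EX_o2"].lower_bound == 0.0

    def test_unlimited_set_opens_to_default_bound(self, mini_model):
        model = set_medium(mini_model, mf.minimal_medium())
        assert model.reactions["EX_o2"].lower_bound == -1000.0

    def test_empty_medium_gives_no_growth(self, mini_model):
        model = set_medium(mini_model, MediumSpec())
        state = solve_fba(model)
        assert state.status == "infeasible" or (
            state.objective_value <= FLUX_ZERO_TOL)

    def test_minimal_medium_supports_growth(self, glucose_minimal):
        state = solve_fba(glucose_minimal)
        assert state.optimal and state.objective_value > FLUX_ZERO_TOL

    def test_unknown_exchange_rejected(self, mini_model):
        with pytest.raises(mf.ModelError):
            set_medium(mini_model, MediumSpec(uptakes={"EX_ghost": 1.0}))

    def test_negative_uptake_rate_rejected(self):
        with pytest.raises(ValueError):
            MediumSpec(uptakes={"EX_glc": -2.0})


class TestSolveFBA:
    def test_linear_chain_conserves_uptake(self, toy_chain):
        state = solve_fba(toy_chain)
        assert state.objective_value == pytest.approx(5.0, abs=1e-9)

    def test_steady_state_and_bounds_hold(self, glucose_minimal):
        state = solve_fba(glucose_minimal)
        S, met_index, rxn_index = mf.stoichiometric_matrix(glucose_minimal)
        v = np.array([state.fluxes[r] for r in rxn_index])
        assert np.max(np.abs(S @ v)) < 1e-6
        for rid, j in rxn_index.items():
            rxn = glucose_minimal.reactions[rid]
            assert rxn.lower_bound - 1e-9 <= v[j] <= rxn.upper_bound + 1e-9

    def test_growth_objective_matches_second_backend(self, glucose_minimal):
        ours = solve_fba(glucose_minimal).objective_value
        status, theirs = cobra_fba(glucose_minimal)
        assert status == "optimal"
        assert ours == pytest.approx(theirs, abs=1e-6)

    def test_product_objective_at_fixed_growth_matches_backend(
            self, study_model):
        fixed = mf.fix_growth(study_model, 0.055)
        ours = solve_fba(fixed, objective="EX_resv").objective_value
        status, theirs = cobra_fba(fixed, objective="EX_resv")
        assert status == "optimal"
        assert ours == pytest.approx(theirs, abs=1e-6)

    def test_infeasible_is_reported_not_silent(self, mini_model):
        model = mini_model.copy()
        model.reactions["ATPM"].lower_bound = 1e6
        model.reactions["ATPM"].upper_bound = 1e6
        assert solve_fba(model).status == "infeasible"

    def test_scaling_invariance(self, glucose_minimal):
        base = solve_fba(glucose_minimal).objective_value
        for k in (0.5, 2.0):
            scaled = glucose_minimal.copy()
            for rxn in scaled.reactions.values():
                rxn.lower_bound *= k
                rxn.upper_bound *= k
            assert solve_fba(scaled).objective_value == pytest.approx(
                k * base, rel=1e-9)

    def test_duplicating_a_reaction_leaves_optimum_unchanged(
            self, glucose_minimal):
        base = solve_fba(glucose_minimal).objective_value
        clone = glucose_minimal.copy()
        pfk = clone.reactions["PFK"]
        clone.add_reaction(mf.Reaction(
            "PFK_copy", stoichiometry=dict(pfk.stoichiometry),
            lower_bound=pfk.lower_bound, upper_bound=pfk.upper_bound))
        assert solve_fba(clone).objective_value == pytest.approx(
            base, abs=1e-8)


class TestFluxVariability:
    def test_linear_chain_collapses_to_a_point(self, toy_chain):
        ranges = flux_variability(toy_chain)
        for rid, (lo, hi) in ranges.items():
            assert hi - lo < 1e-8
            assert abs(abs(lo) - 5.0) < 1e-8

    def test_parallel_duplicate_paths_span_full_range(self, toy_chain):
        model = toy_chain.copy()
        model.add_reaction(mf.Reaction(
            "AB2", stoichiometry={"a[c]": -1, "b[c]": 1}))
        ranges = flux_variability(model)
        for rid in ("AB", "AB2"):
            lo, hi = ranges[rid]
            assert lo == pytest.approx(0.0, abs=1e-8)
            assert hi == pytest.approx(5.0, abs=1e-8)

    def test_fva_brackets_fba_fluxes(self, glucose_minimal):
        state = solve_fba(glucose_minimal)
        ranges = flux_variability(glucose_minimal, objective_fraction=1.0)
        for rid, (lo, hi) in ranges.items():
            assert lo - 1e-6 <= state.fluxes[rid] <= hi + 1e-6

    def test_fva_matches_per_reaction_oracle(self, glucose_minimal):
        probe = ["PFK", "PPP_OX", "EX_co2", "GLCt", "CHS", "ATPM", "BIOMASS",
                 "PDC", "OXPHOS", "EX_o2"]
        ours = flux_variability(glucose_minimal, reactions=probe)
        theirs = cobra_fva(glucose_minimal, reactions=probe)
        for rid in probe:
            assert ours[rid][0] == pytest.approx(theirs[rid][0], abs=1e-6)
            assert ours[rid][1] == pytest.approx(theirs[rid][1], abs=1e-6)

    def test_infeasible_base_problem_raises(self, mini_model):
        model = mini_model.copy()
        model.reactions["ATPM"].lower_bound = 1e6
        model.reactions["ATPM"].upper_bound = 1e6
        with pytest.raises(mf.ModelError):
            flux_variability(model)


class TestRobustnessScan:
    def test_each_point_equals_standalone_solve(self, study_model):
        fixed = mf.fix_growth(study_model, 0.055)
        values = [-0.05, -0.025, 0.0]
        points = robustness_scan(fixed, "EX_etoh", values,
                                 objective="EX_resv")
        for point in points:
            single = fixed.copy()
            single.reactions["EX_etoh"].lower_bound = point.value
            expected = solve_fba(single, objective="EX_resv").objective_value
            assert point.objective_value == pytest.approx(expected, abs=1e-9)

    def test_ethanol_sweep_is_non_decreasing(self, study_model):
        """Opening ethanol uptake relaxes the LP, so the maximum
        resveratrol export cannot decrease (mirrors the published
        robustness curve)."""
        fixed = mf.fix_growth(study_model, 0.055)
        values = sorted(-0.005 * i for i in range(11))
        points = robustness_scan(fixed, "EX_etoh", values,
                                 objective="EX_resv")
        optima = [p.objective_value for p in reversed(points)]  # 0 -> -0.05
        assert all(b >= a - 1e-9 for a, b in zip(optima, optima[1:]))
        assert optima[-1] > optima[0]

    def test_flat_segment_where_control_is_non_binding(self, toy_chain):
        points = robustness_scan(toy_chain, "AB", [6.0, 8.0, 10.0])
        values = [p.objective_value for p in points]
        assert values[0] == pytest.approx(values[1]) == pytest.approx(values[2])

    def test_unsorted_values_rejected(self, toy_chain):
        with pytest.raises(ValueError):
            robustness_scan(toy_chain, "AB", [1.0, 3.0, 2.0])


class TestConnectivity:
    def test_structural_count_ranks_common_species_first(self):
        model = mf.MetabolicModel("m")
        for mid in ("h2o[c]", "a[c]", "b[c]", "c[c]"):
            model.add_metabolite(mf.Metabolite(mid))
        model.add_reaction(mf.Reaction(
            "R1", stoichiometry={"a[c]": -1, "h2o[c]": -1, "b[c]": 1}))
        model.add_reaction(mf.Reaction(
            "R2", stoichiometry={"b[c]": -1, "h2o[c]": -1, "c[c]": 1}))
        model.add_reaction(mf.Reaction(
            "R3", stoichiometry={"c[c]": -1, "h2o[c]": 1}))
        model.add_reaction(mf.Reaction(
            "DM_a", stoichiometry={"a[c]": -1}, kind="demand"))
        ranked = metabolite_connectivity(model)
        assert ranked[0] == ("h2o[c]", 3)

    def test_flux_mode_with_zero_vector_counts_nothing(self, mini_model):
        state = mf.FluxState({rid: 0.0 for rid in mini_model.reactions},
                             0.0, "optimal")
        ranked = metabolite_connectivity(mini_model, state)
        assert all(count == 0 for _, count in ranked)

    def test_cofactors_outrank_pathway_intermediates_in_study_state(
            self, study_model):
        """Under the production constraint set, currency metabolites (H+,
        water, ATP) touch more active reactions than stilbene-pathway
        intermediates, mirroring the published connectivity ranking."""
        fixed = mf.fix_growth(study_model, 0.055)
        state = solve_fba(fixed, objective="EX_resv")
        ranked = dict(metabolite_connectivity(fixed, state))
        for cofactor in ("h[c]", "h2o[c]", "atp[c]"):
            for intermediate in ("couma[c]", "chor[c]", "4cmcoa[c]",
                                 "resv[c]"):
                assert ranked[cofactor] > ranked[intermediate]
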