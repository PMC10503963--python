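"""Co-culture assembly, Pareto trade-offs, respirometry, phenotype tuning."""

import numpy as np
import pytest

from cocult.coculture import (
    CellTag,
    apply_flux_intervals,
    growth_rate_from_biomass_flux,
    merge_models,
    pareto_front,
    respiration_protocol,
)
from cocult.fba import InfeasibleError, fba_optimize, fva
from cocult.netcore import (
    MetabolicModel,
    Metabolite,
    Reaction,
    list_exchanges,
    stoichiometric_matrix,
)


def yield_cell(model_id, y, uptake=6.0, substrate="s"):
    """One cell: shared substrate -> biomass with a fixed linear yield y."""
    return MetabolicModel(
        metabolites=[
            Metabolite(id=f"{substrate}[e]", compartment="e"),
            Metabolite(id=f"{substrate}[c]", compartment="c"),
        ],
        reactions=[
            Reaction(f"EX_{substrate}", {f"{substrate}[e]": -1.0}, -uptake, 1000.0),
            Reaction("T", {f"{substrate}[e]": -1.0, f"{substrate}[c]": 1.0},
                     0.0, 1000.0),
            Reaction("BIO", {f"{substrate}[c]": -1.0 / y}, 0.0, 1000.0),
        ],
        objective_id="BIO",
        id=model_id,
    )


class TestMerge:
    def test_self_merge_counts(self, stromal_cell):
        model = stromal_cell[0]
        cc = merge_models(model, model.copy(), "bm", "cm")
        n_exchanges = len(list_exchanges(model))
        n_internal_rxns = len(model.reactions) - n_exchanges
        assert len(cc.model.reactions) == 2 * n_internal_rxns + n_exchanges
        n_ext = sum(1 for m in model.metabolites if m.compartment == "e")
        n_int = len(model.metabolites) - n_ext
        assert len(cc.model.metabolites) == 2 * n_int + n_ext

    def test_compartment_tags(self, stromal_cell, myeloma_cell):
        cc = merge_models(stromal_cell[0], myeloma_cell[0], "bm", "cm")
        comps = {m.compartment for m in cc.model.metabolites}
        assert "e" in comps
        assert "c_bm" in comps and "c_cm" in comps
        assert "pyr[c_bm]" in cc.model.metabolite_ids
        assert "pyr[c_cm]" in cc.model.metabolite_ids
        # no untagged internal compartments survive
        assert "c" not in comps and "m" not in comps

    def test_exchanges_deduplicated_and_shared(self, stromal_cell, myeloma_cell):
        cc = merge_models(stromal_cell[0], myeloma_cell[0], "bm", "cm")
        ids = cc.model.reaction_ids
        assert ids.count("EX_glc") == 1
        assert cc.cell_of_reaction["EX_glc"] == "shared"

    def test_internal_block_structure(self, stromal_cell, myeloma_cell):
        cc = merge_models(stromal_cell[0], myeloma_cell[0], "bm", "cm")
        S = stoichiometric_matrix(cc.model)
        mids = cc.model.metabolite_ids
        rids = cc.model.reaction_ids
        bm_rows = [i for i, m in enumerate(cc.model.metabolites)
                   if m.compartment.endswith("_bm")]
        cm_cols = [j for j, r in enumerate(rids)
                   if cc.cell_of_reaction[r] == "cm"]
        assert np.all(S[np.ix_(bm_rows, cm_cols)] == 0.0)

    def test_biomass_registered_per_cell(self, stromal_cell, myeloma_cell):
        cc = merge_models(stromal_cell[0], myeloma_cell[0], "bm", "cm")
        assert cc.biomass_ids == {"bm": "BIOMASS_bm", "cm": "BIOMASS_cm"}
        assert cc.model.objective_id == "BIOMASS_bm"

    @pytest.mark.parametrize("seed", range(50))
    def test_count_formulas_on_random_pairs(self, seed):
        from oracles import random_chain_model

        rng = np.random.default_rng(700 + seed)
        a = random_chain_model(rng, n_internal=int(rng.integers(3, 6)))
        b = random_chain_model(rng, n_internal=int(rng.integers(3, 6)))
        cc = merge_models(a, b, "x", "y")
        ex_a, ex_b = set(list_exchanges(a)), set(list_exchanges(b))
        ext_a = {m.id for m in a.metabolites if m.compartment == "e"}
        ext_b = {m.id for m in b.metabolites if m.compartment == "e"}
        int_a, int_b = len(a.metabolites) - len(ext_a), len(b.metabolites) - len(ext_b)
        assert len(cc.model.metabolites) == int_a + int_b + len(ext_a | ext_b)
        shared_ex = len(
            {tuple(a.reaction(r).stoichiometry) for r in ex_a}
            & {tuple(b.reaction(r).stoichiometry) for r in ex_b}
        )
        assert len(cc.model.reactions) == (
            len(a.reactions) + len(b.reactions) - shared_ex
        )

    def test_identical_tags_rejected(self, stromal_cell):
        with pytest.raises(ValueError, match="differ"):
            merge_models(stromal_cell[0], stromal_cell[0].copy(), "bm", "bm")

    def test_tag_e_rejected(self):
        with pytest.raises(ValueError):
            CellTag("e")

    def test_missing_biomass_rejected(self, stromal_cell):
        broken = stromal_cell[0].copy()
        broken.objective_id = None
        with pytest.raises(ValueError, match="biomass"):
            merge_models(broken, stromal_cell[0].copy(), "bm", "cm")

    def test_cross_feeding_via_shared_space_only(self, stromal_cell,
                                                 myeloma_cell):
        # every metabolite id is either extracellular or carries exactly one
        # cell tag, so any secreted/absorbed species must pass through "e"
        cc = merge_models(stromal_cell[0], myeloma_cell[0], "bm", "cm")
        for m in cc.model.metabolites:
            assert (
                m.compartment == "e"
                or m.compartment.endswith("_bm")
                or m.compartment.endswith("_cm")
            )


class TestPareto:
    def test_disjoint_substrates_no_trade_off(self):
        a = yield_cell("a", y=0.5, substrate="s")
        b = yield_cell("b", y=0.25, substrate="t")
        cc = merge_models(a, b, "x", "y")
        points = pareto_front(cc, n_points=11)
        max_a = fba_optimize(cc.model, "BIO_x").objective_value
        max_b = fba_optimize(cc.model, "BIO_y").objective_value
        uniq = {(round(p.biomass_a, 6), round(p.biomass_b, 6)) for p in points}
        assert uniq == {(round(max_a, 6), round(max_b, 6))}

    def test_shared_substrate_resource_partition_line(self):
        y_a, y_b, U = 0.5, 0.2, 6.0
        a = yield_cell("a", y=y_a, uptake=U)
        b = yield_cell("b", y=y_b, uptake=U)
        cc = merge_models(a, b, "x", "y")
        points = pareto_front(cc, n_points=11)
        assert len(points) == 11
        for p in points:
            # closed form: biomass_a/(U y_a) + biomass_b/(U y_b) = 1
            assert p.biomass_a / (U * y_a) + p.biomass_b / (U * y_b) == (
                pytest.approx(1.0, abs=1e-6)
            )

    def test_pairwise_non_domination(self, stromal_cell, myeloma_cell):
        cc = merge_models(stromal_cell[0], myeloma_cell[0], "bm", "cm")
        points = pareto_front(cc, n_points=9)
        for p in points:
            for q in points:
                if q is p:
                    continue
                assert not (
                    q.biomass_a > p.biomass_a + 1e-6
                    and q.biomass_b > p.biomass_b + 1e-6
                )

    def test_endpoints_equal_single_objective_optima(self):
        a = yield_cell("a", y=0.5)
        b = yield_cell("b", y=0.2)
        cc = merge_models(a, b, "x", "y")
        points = pareto_front(cc, n_points=11)
        max_a = fba_optimize(cc.model, "BIO_x").objective_value
        max_b = fba_optimize(cc.model, "BIO_y").objective_value
        assert max(p.biomass_a for p in points) == pytest.approx(max_a, abs=1e-6)
        assert max(p.biomass_b for p in points) == pytest.approx(max_b, abs=1e-6)

    def test_points_are_feasible_flux_vectors(self):
        a = yield_cell("a", y=0.5)
        b = yield_cell("b", y=0.2)
        cc = merge_models(a, b, "x", "y")
        S = stoichiometric_matrix(cc.model)
        for p in pareto_front(cc, n_points=5):
            v = np.array([p.fluxes[r] for r in cc.model.reaction_ids])
            assert np.abs(S @ v).max() <= 1e-6


class TestRespirometry:
    def test_orderings_and_derived_fields(self, stromal_constrained,
                                          myeloma_constrained):
        for model, etc in (stromal_constrained, myeloma_constrained):
            prof = respiration_protocol(model, etc)
            assert prof.oligomycin_o2 <= prof.basal_o2 + 1e-9
            assert prof.basal_o2 <= prof.fccp_o2 + 1e-9
            assert prof.spare_capacity >= -1e-9
            assert prof.atp_linked == pytest.approx(
                prof.basal_o2 - prof.oligomycin_o2
            )
            assert prof.spare_capacity == pytest.approx(
                prof.fccp_o2 - prof.basal_o2
            )

    def test_no_leak_gives_zero_oligomycin_o2(self):
        from cocult.fba import apply_medium_constraints
        from cocult.synthetic import ToySpec, make_toy_cell_model

        model, etc, _, medium = make_toy_cell_model(
            ToySpec(include_leak=False), "stromal_like"
        )
        prof = respiration_protocol(apply_medium_constraints(model, medium), etc)
        assert prof.oligomycin_o2 == pytest.approx(0.0, abs=1e-9)
        assert prof.atp_linked == pytest.approx(prof.basal_o2)

    def test_known_leak_oracle_value(self):
        # with complex V blocked, oxygen consumption is leak-limited: the
        # chain pumps P protons per 1/2 O2, so O2 flux = L / (2 P)
        from cocult.fba import apply_medium_constraints
        from cocult.synthetic import ToySpec, make_toy_cell_model

        L, P = 0.2, 10.0
        model, etc, _, medium = make_toy_cell_model(
            ToySpec(leak_capacity=L, pump_stoichiometry=P), "stromal_like"
        )
        prof = respiration_protocol(apply_medium_constraints(model, medium), etc)
        assert prof.oligomycin_o2 == pytest.approx(L / (2 * P), rel=1e-3)

    def test_complex_i_iii_blockade_zeroes_complex_iv(self, stromal_constrained):
        model, etc = stromal_constrained
        blocked = model.copy()
        for rid in (etc.complex_i, etc.complex_iii):
            r = blocked.reaction(rid)
            r.lower_bound = r.upper_bound = 0.0
        rng = fva(blocked, [etc.complex_iv], objective_fraction=0.0)[0]
        assert abs(rng.minimum) <= 1e-9 and abs(rng.maximum) <= 1e-9

    def test_rot_aa_o2_zero_without_bypass(self, stromal_constrained):
        model, etc = stromal_constrained
        prof = respiration_protocol(model, etc)
        assert prof.rot_aa_o2 == pytest.approx(0.0, abs=1e-9)

    def test_stage_infeasibility_is_labelled(self, stromal_constrained):
        model, etc = stromal_constrained
        broken = model.copy()
        broken.reaction("ATPM").lower_bound = 500.0  # impossible demand
        with pytest.raises(InfeasibleError, match="objective"):
            respiration_protocol(broken, etc)


class TestTuning:
    def test_pinned_interval_fixes_flux(self, stromal_constrained):
        model, _ = stromal_constrained
        tuned = apply_flux_intervals(model, {"ALAt": (0.0, 0.0)})
        res = fba_optimize(tuned)
        assert res.fluxes["ALAt"] == pytest.approx(0.0, abs=1e-9)

    def test_glucose_uptake_cap(self, stromal_constrained):
        model, _ = stromal_constrained
        tuned = apply_flux_intervals(model, {"GLCt": (0.0, 0.45)})
        res = fba_optimize(tuned)
        assert res.fluxes["GLCt"] <= 0.45 + 1e-9

    def test_never_enlarges_flux_polytope(self, stromal_constrained):
        model, _ = stromal_constrained
        tuned = apply_flux_intervals(
            model, {"GLCt": (0.1, 0.4), "GLNt": (0.0, 0.5)}
        )
        ids = model.reaction_ids
        before = {f.reaction_id: f for f in fva(model, ids, 0.0)}
        after = {f.reaction_id: f for f in fva(tuned, ids, 0.0)}
        for rid in ids:
            assert after[rid].minimum >= before[rid].minimum - 1e-6
            assert after[rid].maximum <= before[rid].maximum + 1e-6

    def test_unmatched_ids_reported_and_skipped(self, stromal_constrained):
        model, _ = stromal_constrained
        with pytest.warns(UserWarning, match="v_ghost"):
            tuned = apply_flux_intervals(model, {"v_ghost": (0.0, 1.0)})
        assert tuned.annotations["unmatched_intervals"] == ["v_ghost"]

    def test_empty_intersection_raises(self, stromal_constrained):
        model, _ = stromal_constrained
        with pytest.raises(ValueError, match="GLCt"):
            apply_flux_intervals(model, {"GLCt": (10.0, 20.0)})

    def test_infeasible_tuning_names_culprits(self, stromal_constrained):
        model, _ = stromal_constrained
        # force more maintenance ATP than the pinned glucose allows
        with pytest.raises(InfeasibleError, match="ATPM"):
            apply_flux_intervals(
                model, {"ATPM": (100.0, 200.0), "GLCt": (0.0, 0.1)}
            )


class TestGrowthConversion:
    @pytest.mark.parametrize(
        "flux,factor,expected",
        [(0.0306, 1.0, 0.0306), (0.0, 1.0, 0.0), (0.05, 0.5, 0.025)],
    )
    def test_conversion(self, flux, factor, expected):
        assert growth_rate_from_biomass_flux(flux, factor) == pytest.approx(expected)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            growth_rate_from_biomass_flux(-0.1, 1.0)
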