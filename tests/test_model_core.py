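"""model construction, SBML I/O, curation, boundaries, conservation."""

import math

import cobra
import pytest
from cobra import Metabolite, Reaction

from c4leaf import (
    BoundarySpec,
    CurationAction,
    DEFAULT_CURATION,
    DEFAULT_MAINTENANCE_COSTS,
    FluxRatioConstraint,
    MetabolicModel,
    Objective,
    PhotorespirationSpec,
    add_maintenance,
    add_proton_buffers,
    apply_curation,
    check_conservation,
    conservation_violations,
    read_model,
    solve_pfba,
    write_model,
)
from c4leaf.model_core import INF, element_count, split_cell_prefix
from c4leaf.synthetic_network import build_reduced_leaf_network

from conftest import PHLOEM


def _tiny_model(with_objective=True) -> MetabolicModel:
    cm = cobra.Model("tiny")
    a = Metabolite("A_c", compartment="c", formula="C1")
    b = Metabolite("B_c", compartment="c", formula="C1")
    imp = Reaction("imp", lower_bound=0, upper_bound=5)
    imp.add_metabolites({a: 1})
    conv = Reaction("conv", lower_bound=0, upper_bound=100)
    conv.add_metabolites({a: -1, b: 1})
    exp = Reaction("exp", lower_bound=0, upper_bound=100)
    exp.add_metabolites({b: -1})
    cm.add_reactions([imp, conv, exp])
    if with_objective:
        cm.objective = "exp"
    return MetabolicModel(cm)


class TestSBMLRoundTrip:
    def test_counts_preserved_on_tiny_document(self, tmp_path):
        path = str(tmp_path / "tiny.xml")
        write_model(_tiny_model(), path)
        loaded = read_model(path)
        assert len(loaded.reactions) == 3
        assert len(loaded.metabolites) == 2

    def test_structural_identity_on_leaf_model(self, one_cell, tmp_path):
        path = str(tmp_path / "leaf.xml")
        write_model(one_cell, path)
        loaded = read_model(path)
        assert {r.id for r in loaded.reactions} == {r.id for r in one_cell.reactions}
        assert {m.id for m in loaded.metabolites} == {m.id for m in one_cell.metabolites}
        for rxn in one_cell.reactions:
            other = loaded.require_reaction(rxn.id)
            assert other.bounds == pytest.approx(rxn.bounds)
            assert {m.id: c for m, c in other.metabolites.items()} == pytest.approx(
                {m.id: c for m, c in rxn.metabolites.items()})

    def test_ratio_constraints_survive_annotation_round_trip(self, one_cell, tmp_path):
        path = str(tmp_path / "leaf.xml")
        write_model(one_cell, path)
        loaded = read_model(path)
        original = {(r.reaction_a, r.reaction_b): r.ratio
                    for r in one_cell.ratio_constraints}
        recovered = {(r.reaction_a, r.reaction_b): r.ratio
                     for r in loaded.ratio_constraints}
        assert recovered == pytest.approx(original)
        # and the recovered model solves to the same optimum
        assert solve_pfba(loaded, PHLOEM).objective_value == pytest.approx(
            solve_pfba(one_cell, PHLOEM).objective_value)

    def test_empty_model_round_trips(self, tmp_path):
        path = str(tmp_path / "empty.xml")
        write_model(MetabolicModel(cobra.Model("void")), path)
        loaded = read_model(path)
        assert len(loaded.metabolites) == 0

    def test_write_refuses_invariant_violation(self, tmp_path):
        bad = _tiny_model()
        bad.cobra.add_reactions([Reaction("hollow", lower_bound=0, upper_bound=1)])
        with pytest.raises(ValueError, match="hollow"):
            write_model(bad, str(tmp_path / "bad.xml"))

    def test_missing_objective_warns(self, tmp_path):
        path = str(tmp_path / "noobj.xml")
        write_model(_tiny_model(with_objective=False), path)
        with pytest.warns(UserWarning, match="objective"):
            read_model(path)

    def test_malformed_document_raises(self, tmp_path):
        path = tmp_path / "junk.xml"
        path.write_text("<sbml><model><listOfSpecies></model></sbml>")
        with pytest.raises(ValueError, match="malformed"):
            read_model(str(path))


class TestProtonBuffers:
    def test_one_buffer_per_compartment(self):
        model = build_reduced_leaf_network()
        n0 = len(model.reactions)
        add_proton_buffers(model)
        buffers = [r for r in model.reactions if r.id.startswith("Sink_H")]
        assert len(buffers) == 4
        assert len(model.reactions) == n0 + 4
        for rxn in buffers:
            assert rxn.lower_bound < 0 < rxn.upper_bound

    def test_idempotent(self):
        model = build_reduced_leaf_network()
        add_proton_buffers(model)
        n = len(model.reactions)
        add_proton_buffers(model)
        assert len(model.reactions) == n

    def test_single_compartment_toy(self):
        model = _tiny_model()
        add_proton_buffers(model)
        buffers = [r for r in model.reactions if r.id.startswith("Sink_H")]
        assert len(buffers) == 1


class TestMaintenance:
    def test_measured_costs_pin_ngam_bounds(self, one_cell):
        assert one_cell.require_reaction("NGAM_h").bounds == (0.1527, 0.1527)
        assert one_cell.require_reaction("NGAM_m").bounds == (0.0091, 0.0091)

    def test_peroxisomal_cost_rides_on_cytosol(self, one_cell):
        expected = 0.0427 + 0.0076
        assert one_cell.require_reaction("NGAM_c").bounds == pytest.approx(
            (expected, expected))

    def test_solution_carries_exactly_the_maintenance_flux(self, one_cell):
        sol = solve_pfba(one_cell, PHLOEM)
        assert sol["NGAM_h"] == pytest.approx(0.1527, abs=1e-8)
        assert sol["NGAM_c"] == pytest.approx(0.0503, abs=1e-8)
        assert sol["NGAM_m"] == pytest.approx(0.0091, abs=1e-8)

    def test_zero_costs_zero_flux(self):
        model = build_reduced_leaf_network()
        add_proton_buffers(model)
        add_maintenance(model, {"c": 0, "h": 0, "m": 0, "p": 0})
        for comp in "chm":
            assert model.require_reaction(f"NGAM_{comp}").bounds == (0, 0)

    def test_missing_species_named(self):
        model = _tiny_model()
        with pytest.raises(KeyError, match="ATP"):
            add_maintenance(model, DEFAULT_MAINTENANCE_COSTS)


class TestCuration:
    def test_cofactor_swap_rewires_malate_dehydrogenase(self):
        raw = build_reduced_leaf_network()
        mdh = raw.require_reaction("MDH_c")
        assert any(m.id == "NADPH_c" for m in mdh.metabolites)
        model, report = apply_curation(raw, DEFAULT_CURATION)
        mdh = model.require_reaction("MDH_c")
        met_ids = {m.id for m in mdh.metabolites}
        assert "NADH_c" in met_ids and "NADPH_c" not in met_ids
        assert (report["kind"] == "swap_cofactor").sum() == 3

    def test_atp_synthase_proton_stoichiometry(self):
        model, _ = apply_curation(build_reduced_leaf_network(), DEFAULT_CURATION)
        synth_h = model.require_reaction("ATPSynth_h")
        synth_m = model.require_reaction("ATPSynth_m")
        coef_h = {m.id: c for m, c in synth_h.metabolites.items()}["pmf_h"]
        coef_m = {m.id: c for m, c in synth_m.metabolites.items()}["pmf_m"]
        assert coef_h == -3.0
        assert coef_m == -4.0

    def test_zero_flux_fixes(self):
        model, _ = apply_curation(build_reduced_leaf_network(), DEFAULT_CURATION)
        for rid in ("AOX4_h", "iCitDHNADP_h", "Tr_ADPATP_hc"):
            assert model.require_reaction(rid).bounds == (0, 0)

    def test_decarboxylases_unidirectional_after_curation(self):
        model, _ = apply_curation(build_reduced_leaf_network(), DEFAULT_CURATION)
        for rid in ("NADPME_h", "NADME_m", "PEPCK_c", "GDC_m", "ICDH_m",
                    "TCA2_m", "PDH_m"):
            assert model.require_reaction(rid).lower_bound >= 0

    def test_swap_on_reaction_without_cofactor_errors(self):
        model = build_reduced_leaf_network()
        action = CurationAction("swap_cofactor", {
            "reaction": "RBC_h",
            "mapping": {"NADPH_h": "NADH_h"}})
        with pytest.raises(ValueError, match="none of"):
            apply_curation(model, [action])

    def test_unknown_reaction_errors(self):
        with pytest.raises(KeyError, match="nonexistent"):
            apply_curation(build_reduced_leaf_network(), [
                CurationAction("fix_zero_flux", {"reaction": "nonexistent"})])

    def test_incomplete_payload_rejected_at_construction(self):
        with pytest.raises(ValueError, match="incomplete"):
            CurationAction("set_bounds", {"reaction": "x"})


class TestBoundary:
    def test_table_defaults_applied(self, one_cell):
        assert one_cell.require_reaction("Im_CO2").bounds == (0, 20)
        assert one_cell.require_reaction("Im_H2O").bounds == (-INF, INF)
        assert one_cell.require_reaction("Im_O2").bounds == (-INF, INF)
        assert one_cell.require_reaction("Im_NH4").bounds == (0, 0)

    def test_proton_buffers_not_clamped(self, one_cell):
        assert one_cell.require_reaction("Sink_H_c").bounds == (-INF, INF)

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ValueError, match="lower bound"):
            BoundarySpec(bounds={"Im_CO2": (5, 1)})

    def test_unknown_exchange_rejected(self):
        from c4leaf import set_boundary

        model = _tiny_model()
        with pytest.raises(KeyError, match="Im_CO2"):
            set_boundary(model, BoundarySpec(bounds={"Im_CO2": (0, 20)}))


class TestConservation:
    def test_fixture_balanced_for_carbon_and_nitrogen(self, one_cell):
        for element in ("C", "N"):
            report = check_conservation(one_cell, element)
            assert conservation_violations(report).empty

    def test_raw_network_balanced_too(self):
        raw = build_reduced_leaf_network()
        for element in ("C", "N"):
            assert conservation_violations(check_conservation(raw, element)).empty

    def test_carbon_dropping_reaction_flagged(self):
        model = _tiny_model()
        met_a = model.cobra.metabolites.get_by_id("A_c")
        half = Metabolite("half_c", compartment="c", formula="C2")
        bad = Reaction("leaky", lower_bound=0, upper_bound=10)
        bad.add_metabolites({half: -1, met_a: 1})  # C2 -> C1 drops one carbon
        model.cobra.add_reactions([bad])
        report = check_conservation(model, "C")
        flagged = conservation_violations(report)
        assert list(flagged["reaction"]) == ["leaky"]
        assert flagged["imbalance"].iloc[0] == pytest.approx(-1.0)

    def test_proton_buffers_exempt(self, one_cell):
        report = check_conservation(one_cell, "C").set_index("reaction")
        assert report.loc["Sink_H_c", "status"] == "exempt"

    def test_unknown_formula_reported_unchecked(self):
        model = _tiny_model()
        mystery = Metabolite("mys_c", compartment="c")  # no formula, no notes
        met_a = model.cobra.metabolites.get_by_id("A_c")
        rxn = Reaction("mystify", lower_bound=0, upper_bound=1)
        rxn.add_metabolites({met_a: -1, mystery: 1})
        model.cobra.add_reactions([rxn])
        report = check_conservation(model, "C").set_index("reaction")
        assert report.loc["mystify", "status"] == "unchecked"


class TestDomainTypes:
    def test_ratio_constraint_rejects_negative_and_nonfinite(self):
        with pytest.raises(ValueError):
            FluxRatioConstraint("a", "b", -0.5)
        with pytest.raises(ValueError):
            FluxRatioConstraint("a", "b", math.inf)

    def test_photorespiration_from_specificity(self):
        # ratio = (1/SR) * pO2/pCO2
        spec = PhotorespirationSpec.from_specificity(sr=100.0, po2=200.0, pco2=20.0)
        assert spec.ratio == pytest.approx(0.1)

    def test_lumped_amino_acid_carries_fractional_carbon(self, one_cell):
        met = one_cell.cobra.metabolites.get_by_id("AA_c")
        assert element_count(met, "C") == pytest.approx(5.5)
        assert element_count(met, "N") == pytest.approx(1.0)

    def test_cell_prefix_splitting(self):
        assert split_cell_prefix("[M]_RBC_h") == ("[M]_", "RBC_h")
        assert split_cell_prefix("RBC_h") == ("", "RBC_h")
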