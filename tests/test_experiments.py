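"""Scan drivers, knockouts, transport FVA, energy accounting, linearity."""

import cobra
import numpy as np
import pandas as pd
import pytest
from cobra import Metabolite, Reaction

from c4leaf import (
    MetabolicModel,
    Objective,
    energy_accounting,
    knockout_decarboxylation,
    light_scan,
    limitation_scan,
    linearity_probe,
    photorespiration_scan,
    solve_pfba,
    transport_fva,
    transport_ratio_scan,
)
from c4leaf.experiments import (
    DECARBOXYLASES,
    decarboxylase_shares,
    default_registry,
    extract_features,
    two_cell_objectives,
)
from c4leaf.fba_engine import lexicographic_solve

from conftest import PHLOEM

TOL = 1e-6


@pytest.fixture(scope="module")
def pr_scan(two_cell):
    return photorespiration_scan(two_cell, ratios=[0.0, 0.1, 1 / 3, 1.0])


@pytest.fixture(scope="module")
def knockouts(two_cell):
    return {keep: knockout_decarboxylation(two_cell, keep)
            for keep in DECARBOXYLASES}


class TestPhotorespirationScan:
    def test_all_points_solve(self, pr_scan):
        assert list(pr_scan.table["status"]) == ["optimal"] * 4

    def test_c4_cycle_emerges_with_photorespiration(self, pr_scan):
        t = pr_scan.table.set_index("ratio")
        # at the high end every fixed carbon is funnelled through PEPC
        assert t.loc[1.0, "PEPC"] == pytest.approx(t.loc[1.0, "CO2-uptake"],
                                                   rel=1e-4)
        assert t.loc[1.0, "CO2-uptake"] == pytest.approx(40.0, rel=1e-4)
        # at the low end PEPC is far below the C4 level
        assert t.loc[0.0, "PEPC"] < 0.5 * t.loc[1.0, "PEPC"]

    def test_carbon_shifts_to_ccm_rubisco(self, pr_scan):
        t = pr_scan.table.set_index("ratio")
        assert t.loc[0.0, "Rubisco-CCM"] < 0.1 * t.loc[0.0, "CO2-uptake"]
        assert t.loc[1.0, "Rubisco-CCM"] > 0.9 * t.loc[1.0, "CO2-uptake"]

    def test_glycine_decarboxylase_pump_peaks_at_intermediate_levels(self, pr_scan):
        t = pr_scan.table.set_index("ratio")
        intermediate = max(t.loc[0.1, "GDC(B)"], t.loc[1 / 3, "GDC(B)"])
        assert intermediate > t.loc[0.0, "GDC(B)"] + TOL
        assert intermediate > t.loc[1.0, "GDC(B)"] + TOL

    def test_phloem_optimum_held_across_grid(self, pr_scan, two_cell):
        assert pr_scan.table["phloem"].nunique() == 1 or \
            pr_scan.table["phloem"].max() - pr_scan.table["phloem"].min() < 1e-5

    def test_scan_is_deterministic(self, two_cell, pr_scan):
        again = photorespiration_scan(two_cell, ratios=[0.0, 0.1, 1 / 3, 1.0])
        pd.testing.assert_frame_equal(pr_scan.table, again.table)

    def test_carbon_closure_at_each_point(self, pr_scan):
        """CO2 carbon in equals sucrose + starch + amino-acid carbon out.

        With sucrose : amino acids = 2.2 and starch = sucrose, the phloem
        flux splits as AA = phloem/3.2 and Suc = 2.2 phloem/3.2.
        """
        t = pr_scan.table
        aa = t["phloem"] / 3.2
        suc = 2.2 * t["phloem"] / 3.2
        carbon_out = 12.0 * suc + 12.0 * suc + 5.5 * aa
        assert np.allclose(carbon_out, t["CO2-uptake"], atol=1e-4)


class TestKnockouts:
    def test_each_mode_supports_a_c4_cycle(self, knockouts):
        for keep, sol in knockouts.items():
            assert sol.status == "optimal"
            assert sol.get("[M]_PEPC_c") > 1.0

    def test_bounded_out_enzymes_carry_exactly_zero(self, two_cell, knockouts):
        registry = default_registry(two_cell)
        for keep, sol in knockouts.items():
            for label in DECARBOXYLASES:
                flux = registry.flux(label, sol)
                if label == keep:
                    assert flux > 1.0
                else:
                    assert flux == 0.0

    def test_pepc_carries_the_full_co2_uptake_at_one_third(self, knockouts):
        for sol in knockouts.values():
            assert sol.get("[M]_Im_CO2") == pytest.approx(40.0, rel=1e-5)
            assert sol.get("[M]_PEPC_c") + sol.get("[B]_PEPC_c") == pytest.approx(
                40.0, rel=1e-4)

    def test_mesophyll_core_pattern_shared_across_modes(self, knockouts):
        core = ["[M]_Im_CO2", "[M]_PEPC_c", "[M]_CA_c", "[M]_RBC_h"]
        frames = pd.DataFrame({k: s.fluxes[core] for k, s in knockouts.items()})
        spread = (frames.max(axis=1) - frames.min(axis=1)).max()
        assert spread < 1e-4

    def test_unknown_enzyme_label_rejected(self, two_cell):
        with pytest.raises(KeyError, match="unknown decarboxylation"):
            knockout_decarboxylation(two_cell, "PEPC")


@pytest.fixture(scope="module")
def nadme_fva(two_cell):
    return transport_fva(two_cell, keep="NAD-ME", deviation_fraction=0.015)


class TestTransportFVA:
    def test_solution_nests_inside_intervals(self, two_cell, knockouts, nadme_fva):
        sol = knockouts["NAD-ME"]
        for rid in nadme_fva.ranges.index:
            lo, hi = nadme_fva.interval(rid)
            assert lo - TOL <= sol.get(rid) <= hi + TOL

    def test_aspartate_alanine_shuttle_in_near_optimal_space(self, nadme_fva):
        # the malate/pyruvate shuttle can be partly replaced by
        # aspartate/alanine within 1.5% extra total flux
        assert nadme_fva.interval("[MB]_Asp")[1] > 5.0
        assert nadme_fva.interval("[MB]_Ala")[0] < -5.0
        assert nadme_fva.interval("[MB]_Mal")[1] > 5.0

    def test_zero_deviation_intervals_are_tighter(self, two_cell, nadme_fva):
        tight = transport_fva(two_cell, keep="NAD-ME", deviation_fraction=0.0)
        for rid in tight.ranges.index:
            lo0, hi0 = tight.interval(rid)
            lo1, hi1 = nadme_fva.interval(rid)
            assert lo1 <= lo0 + TOL and hi1 >= hi0 - TOL

    def test_sign_convention_mesophyll_to_bundle_sheath(self, knockouts):
        # carbon flows M -> B: the dominant acid transporter must be positive
        sol = knockouts["NADP-ME"]
        assert sol.get("[MB]_Mal") > 0


@pytest.fixture(scope="module")
def scan(two_cell):
    return light_scan(two_cell, totals=[0.0, 200.0, 400.0, 800.0],
                      ratios=[0.5, 1.0])


class TestLightScan:
    def test_infeasible_dark_point_recorded_not_dropped(self, scan):
        dark = scan.table[scan.table["ppfd_total"] == 0.0]
        assert len(dark) == 2
        assert (dark["status"] != "optimal").all()

    def test_co2_uptake_reduced_below_saturating_light(self, scan):
        t = scan.table[scan.table["status"] == "optimal"]
        low = t[t["ppfd_total"] == 200.0]["CO2-uptake"]
        high = t[t["ppfd_total"] == 800.0]["CO2-uptake"]
        assert (low < 40.0 - 1e-3).all()
        assert high.max() == pytest.approx(40.0, rel=1e-4)

    def test_no_parallel_use_of_the_two_malic_enzymes(self, scan):
        t = scan.table[scan.table["status"] == "optimal"]
        both = (t["NADP-ME(B)"] > 1.0) & (t["NAD-ME(B)"] > 1.0)
        assert not both.any()

    def test_shares_normalised_to_co2_uptake(self, scan):
        t = scan.table[scan.table["status"] == "optimal"]
        shares = t[[f"{l}/CO2" for l in DECARBOXYLASES]].fillna(0.0)
        assert (shares.to_numpy() >= -1e-6).all()
        assert (shares.sum(axis=1) <= 1.0 + 1e-4).all()


@pytest.fixture(scope="module")
def no3_scan(two_cell):
    return limitation_scan(two_cell, "NO3", [0.0, 0.2, 0.4, 1e6])


class TestLimitationScan:
    def test_no_nitrate_no_phloem(self, no3_scan):
        row = no3_scan.table.set_index("bound").loc[0.0]
        assert row["phloem"] == pytest.approx(0.0, abs=1e-6)

    def test_output_scales_proportionally_with_the_limiting_bound(self, no3_scan):
        t = no3_scan.table.set_index("bound")
        assert t.loc[0.2, "phloem"] == pytest.approx(0.5 * t.loc[0.4, "phloem"],
                                                     rel=1e-4)

    def test_decarboxylase_proportions_unchanged_under_limitation(self, no3_scan):
        t = no3_scan.table.set_index("bound")
        for label in DECARBOXYLASES:
            share_limited = t.loc[0.4, f"{label}/CO2"]
            share_free = t.loc[1e6, f"{label}/CO2"]
            assert share_limited == pytest.approx(share_free, abs=0.02)

    def test_unlimited_end_reproduces_unconstrained_optimum(self, two_cell,
                                                            no3_scan):
        objectives = two_cell_objectives(two_cell,
                                         minimize_photorespiration=True)
        free = lexicographic_solve(two_cell, objectives)
        t = no3_scan.table.set_index("bound")
        assert t.loc[1e6, "phloem"] == pytest.approx(free.objective_value,
                                                     rel=1e-5)

    def test_unknown_nutrient_rejected(self, two_cell):
        with pytest.raises(KeyError, match="unknown nutrient"):
            limitation_scan(two_cell, "K", [1.0])


class TestTransportRatioScan:
    def test_installed_ratio_satisfied_exactly(self, two_cell):
        scan = transport_ratio_scan(two_cell, [0.25, 1.0, 4.0])
        for _, row in scan.table.iterrows():
            if row["status"] != "optimal":
                continue
            assert row["[MB]_Asp"] == pytest.approx(
                row["asp_mal_ratio"] * row["[MB]_Mal"], abs=1e-5)

    def test_shares_remain_normalised(self, two_cell):
        scan = transport_ratio_scan(two_cell, [0.5, 2.0])
        t = scan.table[scan.table["status"] == "optimal"]
        shares = t[[f"{l}/CO2" for l in DECARBOXYLASES]].fillna(0.0)
        assert (shares.sum(axis=1) <= 1.0 + 1e-4).all()


class TestEnergyAccounting:
    def test_single_producer_owns_all_production(self):
        cm = cobra.Model("energy_toy")
        atp = Metabolite("ATP_c", compartment="c")
        adp = Metabolite("ADP_c", compartment="c")
        make = Reaction("make", lower_bound=0, upper_bound=10)
        make.add_metabolites({adp: -1, atp: 1})
        burn = Reaction("burn", lower_bound=0, upper_bound=10)
        burn.add_metabolites({atp: -1, adp: 1})
        sink = Reaction("sink", lower_bound=0, upper_bound=10)
        sink.add_metabolites({atp: -1, adp: 1})
        cm.add_reactions([make, burn, sink])
        model = MetabolicModel(cm)
        model.require_reaction("burn").bounds = (2, 2)
        model.require_reaction("sink").bounds = (1, 1)
        sol = solve_pfba(model, Objective({"make": 1.0}, "min"))
        account = energy_accounting(model, sol, "ATP")
        assert account.producers.sum() == pytest.approx(100.0)
        assert len(account.producers) == 1
        assert account.total_production == pytest.approx(3.0)

    def test_shares_sum_to_hundred_on_leaf_model(self, one_cell):
        sol = solve_pfba(one_cell, PHLOEM)
        for cofactor in ("ATP", "NADPH", "NADH"):
            account = energy_accounting(one_cell, sol, cofactor)
            assert account.producers.sum() == pytest.approx(100.0, abs=0.1)
            assert account.consumers.sum() == pytest.approx(100.0, abs=0.1)

    def test_light_reactions_dominate_atp_production(self, one_cell):
        sol = solve_pfba(one_cell, PHLOEM)
        account = energy_accounting(one_cell, sol, "ATP")
        assert account.producers.index[0] == "light reactions"
        assert account.producers.iloc[0] > 90.0

    def test_unknown_cofactor_rejected(self, one_cell):
        sol = solve_pfba(one_cell, PHLOEM)
        with pytest.raises(KeyError, match="cofactor"):
            energy_accounting(one_cell, sol, "FADH2")


class TestLinearityProbe:
    def test_output_linear_in_co2_bound(self, one_cell):
        probe = linearity_probe(one_cell, "CO2", np.linspace(0, 20, 6))
        assert probe.meta["r_squared_linear_segment"] == pytest.approx(1.0,
                                                                       abs=1e-6)
        assert probe.meta["breakpoint"] is None

    def test_zero_co2_zero_output(self, one_cell):
        probe = linearity_probe(one_cell, "CO2", [0.0, 10.0])
        first = probe.table.iloc[0]
        assert first["status"] != "optimal" or first["phloem"] == pytest.approx(
            0.0, abs=1e-6)

    def test_ppfd_axis_saturates_when_carbon_limited(self, one_cell):
        probe = linearity_probe(one_cell, "PPFD",
                                [50, 100, 150, 200, 250, 300, 350])
        assert probe.meta["breakpoint"] is not None
        assert 150 <= probe.meta["breakpoint"] <= 250

    def test_unknown_axis_rejected(self, one_cell):
        with pytest.raises(KeyError, match="axis"):
            linearity_probe(one_cell, "H2O", [1.0])
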