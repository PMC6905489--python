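"""Deterministic reduced leaf metabolic network.

A ~110-reaction, four-compartment (c/h/m/p) model with the stoichiometric
structure the analysis assumes: photon-driven ATP/NADPH generation with
explicit proton-motive charge and ATP synthases, Rubisco carboxylation and
oxygenation, the complete photorespiratory loop with mitochondrial glycine
decarboxylase, every C4-cycle enzyme, nitrate assimilation, TCA/oxidative
phosphorylation with an alternative oxidase, maintenance ATPases and the
phloem outputs (sucrose 12 C, a 12-C starch pseudo-unit, and one lumped
amino-acid species with the phloem-average 5.5 C and 1 N).

The builder emits the network in its *raw* historical state (NADP-dependent
malate dehydrogenases outside the chloroplast, reversible decarboxylases,
uncorrected ATP-synthase H+/ATP stoichiometry, open plastoquinol oxidase);
the packaged default curation set then produces the working C3 model, so
the full curate -> buffer -> maintain -> bound -> constrain pipeline is
exercised end to end without any download.

Lumping conventions (all tunable through :class:`FixtureConfig`): linear
electron flow yields 2 NADPH and 12 protons-worth of proton-motive charge
per 8 photons; cyclic electron flow pumps 2 charges per photon; the
mitochondrial chain pumps 10 per NADH.  Carbon and nitrogen are conserved
exactly by construction; hydrogen book-keeping is deliberately loose and
absorbed by the per-compartment proton sinks, mirroring the unknown
protonation state of transport substrates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Mapping, Optional, Tuple

import numpy as np
from cobra import Metabolite, Model, Reaction
from cobra.core import Group

from .model_core import (
    INF,
    BoundarySpec,
    DEFAULT_CURATION,
    DEFAULT_MAINTENANCE_COSTS,
    FluxRatioConstraint,
    MetabolicModel,
    add_maintenance,
    add_proton_buffers,
    apply_curation,
    set_boundary,
)

# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FixtureConfig:
    """Subsystem toggles and stoichiometry knobs of the reduced network."""

    light_reactions: bool = True
    cyclic_electron_flow: bool = True
    calvin: bool = True
    photorespiration: bool = True
    c4_enzymes: bool = True
    tca: bool = True
    aox: bool = True
    nitrate_assimilation: bool = True
    sugar_synthesis: bool = True
    transporters: bool = True

    photons_per_nadph_pair: float = 8.0
    pmf_per_lef: float = 12.0
    pmf_per_cef_photon: float = 2.0
    pmf_per_nadh: float = 10.0
    seed: int = 0

    def require(self, *flags: str, experiment: str = "pipeline") -> None:
        missing = [f for f in flags if not getattr(self, f)]
        if missing:
            raise ValueError(
                f"{experiment} requires subsystem(s) {missing} which the "
                f"fixture configuration excludes"
            )


# ---------------------------------------------------------------------------
# species catalogue: id -> (name, compartment, formula)
# formulas carry only the elements the conservation checks audit (C, N);
# an empty formula means "no audited elements", None means "unknown".
# ---------------------------------------------------------------------------

def _catalogue() -> Dict[str, Tuple[str, str, Optional[str]]]:
    cat: Dict[str, Tuple[str, str, Optional[str]]] = {}

    def add(base: str, name: str, formula: Optional[str], comps: str) -> None:
        for comp in comps.split():
            cat[f"{base}_{comp}"] = (name, comp, formula)

    add("hnu", "photon", "", "h")
    add("pmf", "proton-motive charge", "", "h m")
    add("ATP", "ATP", "C10N5", "c h m")
    add("ADP", "ADP", "C10N5", "c h m")
    add("Pi", "orthophosphate", "", "c h m")
    add("NAD", "NAD+", "C21N7", "c m p")
    add("NADH", "NADH", "C21N7", "c m p")
    add("NADP", "NADP+", "C21N7", "c h m p")
    add("NADPH", "NADPH", "C21N7", "c h m p")
    add("H", "proton", "H", "c h m p")
    add("H2O", "water", "", "c h m p")
    add("O2", "oxygen", "O2", "c h m p")
    add("CO2", "carbon dioxide", "CO2", "c h m")
    add("HCO3", "bicarbonate", "CO3H", "c")
    add("NO3", "nitrate", "NO3", "c")
    add("NO2", "nitrite", "NO2", "c h")
    add("NH4", "ammonium", "NH4", "c h m")
    add("SO4", "sulfate", "O4S", "c")
    add("H2S", "hydrogen sulfide", "H2S", "c")
    add("RuBP", "ribulose 1,5-bisphosphate", "C5", "h")
    add("PGA", "3-phosphoglycerate", "C3", "c h")
    add("GAP", "glyceraldehyde 3-phosphate", "C3", "c h")
    add("PG2", "2-phosphoglycolate", "C2", "h")
    add("Glycolate", "glycolate", "C2", "c h p")
    add("Glyoxylate", "glyoxylate", "C2", "p")
    add("Gly", "glycine", "C2N", "c m p")
    add("Ser", "serine", "C3N", "c m p")
    add("HPyr", "hydroxypyruvate", "C3", "p")
    add("Glycerate", "glycerate", "C3", "c h p")
    add("PEP", "phosphoenolpyruvate", "C3", "c h")
    add("Pyr", "pyruvate", "C3", "c h m")
    add("OAA", "oxaloacetate", "C4", "c h m p")
    add("Mal", "malate", "C4", "c h m p")
    add("Cit", "citrate", "C6", "c m")
    add("iCit", "isocitrate", "C6", "c h m")
    add("KG", "2-oxoglutarate", "C5", "c h m p")
    add("AcCoA", "acetyl unit (CoA moiety omitted)", "C2", "m")
    add("Glu", "glutamate", "C5N", "c h m p")
    add("Gln", "glutamine", "C5N2", "h")
    add("Ala", "alanine", "C3N", "c h m")
    add("Asp", "aspartate", "C4N", "c h m")
    add("Suc", "sucrose", "C12", "c")
    add("Starch", "starch (12-carbon pseudo-unit)", "C12", "h")
    # lumped phloem amino acid: mean 5.5 carbons cannot be a formula
    cat["AA_c"] = ("phloem amino acid (lumped)", "c", None)
    return cat


_SIXTH = 1.0 / 6.0

# (id, name, subsystem, flag, stoichiometry, lb, ub)
_RawReaction = Tuple[str, str, str, Optional[str], Mapping[str, float], float, float]


def _reaction_table(cfg: FixtureConfig) -> Iterable[_RawReaction]:
    lef_hnu = cfg.photons_per_nadph_pair
    R = []

    def rxn(rid, name, subsystem, flag, stoich, lb=-INF, ub=INF):
        R.append((rid, name, subsystem, flag, stoich, lb, ub))

    # --- light reactions ---------------------------------------------------
    rxn("LEF_h", "linear electron flow (lumped)", "light reactions",
        "light_reactions",
        {"hnu_h": -lef_hnu, "H2O_h": -2, "NADP_h": -2,
         "NADPH_h": 2, "O2_h": 1, "pmf_h": cfg.pmf_per_lef, "H_h": 2}, 0, INF)
    rxn("CEF_h", "cyclic electron flow (lumped)", "light reactions",
        "cyclic_electron_flow",
        {"hnu_h": -1, "pmf_h": cfg.pmf_per_cef_photon}, 0, INF)
    # raw H+/ATP coefficient is wrong on purpose; curation sets 3 (h) / 4 (m)
    rxn("ATPSynth_h", "chloroplast ATP synthase", "light reactions",
        "light_reactions",
        {"pmf_h": -1, "ADP_h": -1, "Pi_h": -1, "ATP_h": 1, "H2O_h": 1}, 0, INF)
    rxn("AOX4_h", "plastoquinol oxidase", "alternative respiration", "aox",
        {"NADPH_h": -2, "O2_h": -1, "H_h": -2, "NADP_h": 2, "H2O_h": 2}, 0, INF)
    # non-photochemical dissipation of surplus proton-motive force; the
    # mitochondrial counterpart is the uncoupling-protein H+ leak
    rxn("Leak_h", "thylakoid proton leak (non-photochemical quenching)",
        "light reactions", "light_reactions",
        {"pmf_h": -1, "H_h": 1}, 0, INF)

    # --- Calvin cycle ------------------------------------------------------
    rxn("RBC_h", "Rubisco carboxylase", "reductive pentose phosphate cycle",
        "calvin",
        {"RuBP_h": -1, "CO2_h": -1, "H2O_h": -1, "PGA_h": 2, "H_h": 2}, 0, INF)
    rxn("RBO_h", "Rubisco oxygenase", "photorespiration", "photorespiration",
        {"RuBP_h": -1, "O2_h": -1, "PGA_h": 1, "PG2_h": 1}, 0, INF)
    rxn("PGAred_h", "phosphoglycerate reduction (PGK+GAPDH)",
        "reductive pentose phosphate cycle", "calvin",
        {"PGA_h": -1, "ATP_h": -1, "NADPH_h": -1, "H_h": -1,
         "GAP_h": 1, "ADP_h": 1, "Pi_h": 1, "NADP_h": 1})
    rxn("RuBPregen_h", "RuBP regeneration (lumped)",
        "reductive pentose phosphate cycle", "calvin",
        {"GAP_h": -5, "ATP_h": -3, "RuBP_h": 3, "ADP_h": 3, "Pi_h": 2}, 0, INF)
    rxn("GLYK_h", "glycerate kinase", "photorespiration", "photorespiration",
        {"Glycerate_h": -1, "ATP_h": -1, "PGA_h": 1, "ADP_h": 1, "H_h": 1},
        0, INF)
    rxn("PGP_h", "phosphoglycolate phosphatase", "photorespiration",
        "photorespiration",
        {"PG2_h": -1, "H2O_h": -1, "Glycolate_h": 1, "Pi_h": 1}, 0, INF)

    # --- C4 cycle enzymes --------------------------------------------------
    rxn("CA_c", "carbonic anhydrase", "C4 cycle", "c4_enzymes",
        {"CO2_c": -1, "H2O_c": -1, "HCO3_c": 1, "H_c": 1})
    rxn("PEPC_c", "PEP carboxylase", "C4 cycle", "c4_enzymes",
        {"PEP_c": -1, "HCO3_c": -1, "OAA_c": 1, "Pi_c": 1}, 0, INF)
    rxn("PPDK_h", "pyruvate phosphate dikinase", "C4 cycle", "c4_enzymes",
        {"Pyr_h": -1, "ATP_h": -2, "PEP_h": 1, "ADP_h": 2, "Pi_h": 1}, 0, INF)
    rxn("NADPMDH_h", "NADP-malate dehydrogenase (chloroplast)", "C4 cycle",
        "c4_enzymes",
        {"OAA_h": -1, "NADPH_h": -1, "H_h": -1, "Mal_h": 1, "NADP_h": 1})
    # raw state: NADP-dependent outside the chloroplast (curation swaps to NAD)
    for comp, flag in (("c", "c4_enzymes"), ("m", "tca"), ("p", "photorespiration")):
        rxn(f"MDH_{comp}", f"malate dehydrogenase ({comp})", "C4 cycle"
            if comp == "c" else ("tricarboxylic acid cycle" if comp == "m"
                                 else "photorespiration"), flag,
            {f"OAA_{comp}": -1, f"NADPH_{comp}": -1, f"H_{comp}": -1,
             f"Mal_{comp}": 1, f"NADP_{comp}": 1})
    # decarboxylases are reversible in the raw state (curation fixes direction)
    rxn("NADPME_h", "NADP-malic enzyme (chloroplast)", "C4 cycle", "c4_enzymes",
        {"Mal_h": -1, "NADP_h": -1, "Pyr_h": 1, "CO2_h": 1, "NADPH_h": 1})
    rxn("NADME_m", "NAD-malic enzyme (mitochondrion)", "C4 cycle", "c4_enzymes",
        {"Mal_m": -1, "NAD_m": -1, "Pyr_m": 1, "CO2_m": 1, "NADH_m": 1})
    rxn("PEPCK_c", "PEP carboxykinase", "C4 cycle", "c4_enzymes",
        {"OAA_c": -1, "ATP_c": -1, "PEP_c": 1, "CO2_c": 1, "ADP_c": 1})
    for comp in "chm":
        rxn(f"AlaAT_{comp}", f"alanine aminotransferase ({comp})",
            "aminotransferases", "c4_enzymes",
            {f"Pyr_{comp}": -1, f"Glu_{comp}": -1, f"Ala_{comp}": 1,
             f"KG_{comp}": 1})
        rxn(f"AspAT_{comp}", f"aspartate aminotransferase ({comp})",
            "aminotransferases", "c4_enzymes",
            {f"OAA_{comp}": -1, f"Glu_{comp}": -1, f"Asp_{comp}": 1,
             f"KG_{comp}": 1})

    # --- photorespiratory loop (peroxisome + mitochondrion) ---------------
    rxn("GOX_p", "glycolate oxidase (+catalase)", "photorespiration",
        "photorespiration",
        {"Glycolate_p": -1, "O2_p": -0.5, "Glyoxylate_p": 1, "H2O_p": 1},
        0, INF)
    rxn("GGT_p", "glutamate:glyoxylate aminotransferase", "photorespiration",
        "photorespiration",
        {"Glyoxylate_p": -1, "Glu_p": -1, "Gly_p": 1, "KG_p": 1}, 0, INF)
    rxn("SGAT_p", "serine:glyoxylate aminotransferase", "photorespiration",
        "photorespiration",
        {"Ser_p": -1, "Glyoxylate_p": -1, "HPyr_p": 1, "Gly_p": 1}, 0, INF)
    rxn("HPR_p", "hydroxypyruvate reductase", "photorespiration",
        "photorespiration",
        {"HPyr_p": -1, "NADH_p": -1, "H_p": -1, "Glycerate_p": 1, "NAD_p": 1},
        0, INF)
    rxn("GDC_m", "glycine decarboxylase complex (+SHMT)", "photorespiration",
        "photorespiration",
        {"Gly_m": -2, "NAD_m": -1, "H2O_m": -1,
         "Ser_m": 1, "CO2_m": 1, "NH4_m": 1, "NADH_m": 1})

    # --- sucrose / starch / amino-acid outputs -----------------------------
    rxn("SucSyn_c", "sucrose synthesis (lumped)", "sucrose synthesis",
        "sugar_synthesis",
        {"GAP_c": -4, "ATP_c": -2, "H2O_c": -4,
         "Suc_c": 1, "ADP_c": 2, "Pi_c": 6}, 0, INF)
    rxn("StarchSyn_h", "starch synthesis (lumped)", "starch synthesis",
        "sugar_synthesis",
        {"GAP_h": -4, "ATP_h": -2, "Starch_h": 1, "ADP_h": 2, "Pi_h": 6},
        0, INF)
    rxn("AASyn_c", "phloem amino-acid synthesis (lumped)",
        "amino acid synthesis", "sugar_synthesis",
        {"Glu_c": -1, "GAP_c": -_SIXTH, "ATP_c": -2, "H2O_c": -2,
         "AA_c": 1, "ADP_c": 2, "Pi_c": 2 + _SIXTH, "H_c": 2}, 0, INF)

    # --- glycolytic shunt + TCA + oxidative phosphorylation ----------------
    rxn("GAPDH_PGK_c", "cytosolic GAPDH/PGK couple", "canonical glycolysis",
        "tca",
        {"GAP_c": -1, "NAD_c": -1, "ADP_c": -1, "Pi_c": -1,
         "PGA_c": 1, "NADH_c": 1, "ATP_c": 1, "H_c": 1})
    rxn("ENO_c", "phosphoglycerate mutase/enolase", "canonical glycolysis",
        "tca", {"PGA_c": -1, "PEP_c": 1, "H2O_c": 1})
    rxn("PK_c", "pyruvate kinase", "canonical glycolysis", "tca",
        {"PEP_c": -1, "ADP_c": -1, "H_c": -1, "Pyr_c": 1, "ATP_c": 1}, 0, INF)
    rxn("PDH_m", "pyruvate dehydrogenase", "tricarboxylic acid cycle", "tca",
        {"Pyr_m": -1, "NAD_m": -1, "AcCoA_m": 1, "CO2_m": 1, "NADH_m": 1,
         "H_m": 1})
    rxn("CS_m", "citrate synthase", "tricarboxylic acid cycle", "tca",
        {"AcCoA_m": -1, "OAA_m": -1, "H2O_m": -1, "Cit_m": 1, "H_m": 1},
        0, INF)
    rxn("ACO_m", "aconitase", "tricarboxylic acid cycle", "tca",
        {"Cit_m": -1, "iCit_m": 1})
    rxn("ICDH_m", "NAD-isocitrate dehydrogenase", "tricarboxylic acid cycle",
        "tca",
        {"iCit_m": -1, "NAD_m": -1, "KG_m": 1, "CO2_m": 1, "NADH_m": 1})
    rxn("TCA2_m", "2-oxoglutarate to malate (lumped)",
        "tricarboxylic acid cycle", "tca",
        {"KG_m": -1, "NAD_m": -2, "ADP_m": -1, "Pi_m": -1, "H2O_m": -2,
         "Mal_m": 1, "CO2_m": 1, "NADH_m": 2, "ATP_m": 1, "H_m": 1})
    rxn("OXPHOS_m", "respiratory chain (lumped)", "oxidative phosphorylation",
        "tca",
        {"NADH_m": -1, "O2_m": -0.5, "H_m": -1,
         "NAD_m": 1, "H2O_m": 1, "pmf_m": cfg.pmf_per_nadh}, 0, INF)
    rxn("ATPSynth_m", "mitochondrial ATP synthase",
        "oxidative phosphorylation", "tca",
        {"pmf_m": -1, "ADP_m": -1, "Pi_m": -1, "ATP_m": 1, "H2O_m": 1}, 0, INF)
    rxn("AOX_m", "alternative oxidase", "alternative respiration", "aox",
        {"NADH_m": -1, "O2_m": -0.5, "H_m": -1, "NAD_m": 1, "H2O_m": 1},
        0, INF)
    rxn("Leak_m", "mitochondrial proton leak (uncoupling protein)",
        "oxidative phosphorylation", "tca",
        {"pmf_m": -1, "H_m": 1}, 0, INF)
    rxn("iCitDHNADP_h", "NADP-isocitrate dehydrogenase (chloroplast)",
        "tricarboxylic acid cycle", "tca",
        {"iCit_h": -1, "NADP_h": -1, "KG_h": 1, "CO2_h": 1, "NADPH_h": 1})

    # --- nitrate assimilation ---------------------------------------------
    rxn("NR_c", "nitrate reductase", "nitrate assimilation",
        "nitrate_assimilation",
        {"NO3_c": -1, "NADH_c": -1, "H_c": -2, "NO2_c": 1, "NAD_c": 1,
         "H2O_c": 1}, 0, INF)
    rxn("NiR_h", "nitrite reductase", "nitrate assimilation",
        "nitrate_assimilation",
        {"NO2_h": -1, "NADPH_h": -3, "H_h": -5,
         "NH4_h": 1, "NADP_h": 3, "H2O_h": 2}, 0, INF)
    rxn("GS_h", "glutamine synthetase", "glutamate biosynthesis",
        "nitrate_assimilation",
        {"Glu_h": -1, "NH4_h": -1, "ATP_h": -1,
         "Gln_h": 1, "ADP_h": 1, "Pi_h": 1, "H_h": 1}, 0, INF)
    rxn("GOGAT_h", "glutamate synthase", "glutamate biosynthesis",
        "nitrate_assimilation",
        {"Gln_h": -1, "KG_h": -1, "NADPH_h": -1, "H_h": -1,
         "Glu_h": 2, "NADP_h": 1}, 0, INF)

    # --- boundary exchanges (bounds re-applied by set_boundary) ------------
    for rid, mid, lb, ub in (
        ("Im_hnu", "hnu_h", 0, INF), ("Im_CO2", "CO2_c", 0, 20),
        ("Im_NO3", "NO3_c", 0, INF), ("Im_NH4", "NH4_c", 0, 0),
        ("Im_SO4", "SO4_c", 0, INF), ("Im_H2S", "H2S_c", 0, INF),
        ("Im_Pi", "Pi_c", 0, INF), ("Im_H2O", "H2O_c", -INF, INF),
        ("Im_O2", "O2_c", -INF, INF),
    ):
        rxn(rid, rid.replace("_", " "), "exchange", None, {mid: 1}, lb, ub)
    for rid, mid in (("Ex_Suc", "Suc_c"), ("Ex_AA", "AA_c"),
                     ("Ex_starch", "Starch_h")):
        rxn(rid, rid.replace("_", " "), "exchange", None, {mid: -1}, 0, INF)

    # --- intracellular transport ------------------------------------------
    pairs = {
        "hc": ["CO2", "O2", "H2O", "Pi", "PGA", "GAP", "Pyr", "PEP", "Mal",
               "OAA", "Glu", "KG", "Ala", "Asp", "Glycolate", "Glycerate",
               "NO2", "NH4", "iCit"],
        "mc": ["CO2", "O2", "H2O", "Pi", "Pyr", "Mal", "OAA", "Cit", "iCit",
               "KG", "Glu", "Ala", "Asp", "Gly", "Ser", "NH4"],
        "pc": ["O2", "H2O", "Glycolate", "Glycerate", "Gly", "Ser", "Mal",
               "OAA", "Glu", "KG"],
    }
    for pair, bases in pairs.items():
        inner = pair[0]
        for base in bases:
            rxn(f"Tr_{base}_{pair}", f"{base} transport ({pair[1]}<->{inner})",
                "intracellular transport", "transporters",
                {f"{base}_c": -1, f"{base}_{inner}": 1})
    # antiport ADP/ATP across the chloroplast envelope (curation fixes to 0)
    rxn("Tr_ADPATP_hc", "chloroplast ADP/ATP carrier",
        "intracellular transport", "transporters",
        {"ATP_h": -1, "ADP_c": -1, "ADP_h": 1, "ATP_c": 1})
    return R


def build_reduced_leaf_network(config: Optional[FixtureConfig] = None) -> MetabolicModel:
    """Assemble the reduced network in its raw (pre-curation) state."""
    cfg = config or FixtureConfig()
    cat = _catalogue()
    cm = Model("reduced_leaf")
    mets: Dict[str, Metabolite] = {}

    def get_met(mid: str) -> Metabolite:
        if mid not in mets:
            name, comp, formula = cat[mid]
            met = Metabolite(mid, name=name, compartment=comp, formula=formula)
            if mid == "AA_c":
                met.notes["carbon_count"] = 5.5
                met.notes["nitrogen_count"] = 1.0
            mets[mid] = met
        return mets[mid]

    subsystems: Dict[str, list] = {}
    reactions = []
    for rid, name, subsystem, flag, stoich, lb, ub in _reaction_table(cfg):
        if flag is not None and not getattr(cfg, flag):
            continue
        rxn = Reaction(rid, name=name, lower_bound=lb, upper_bound=ub)
        rxn.add_metabolites({get_met(mid): coef for mid, coef in stoich.items()})
        rxn.subsystem = subsystem
        reactions.append(rxn)
        subsystems.setdefault(subsystem, []).append(rxn)
    cm.add_reactions(reactions)
    cm.add_groups([
        Group(sub.replace(" ", "_"), name=sub, members=members)
        for sub, members in sorted(subsystems.items())
    ])
    cm.compartments = {
        "c": "cytosol", "h": "chloroplast", "m": "mitochondrion",
        "p": "peroxisome",
    }
    return MetabolicModel(cm)


# ---------------------------------------------------------------------------
# pipelines
# ---------------------------------------------------------------------------

#: Phloem sap composition: sucrose : total amino acids, mol/mol.
SUC_AA_RATIO = 2.2
#: Sucrose export : starch storage, mol/mol (half the assimilate is stored).
SUC_STARCH_RATIO = 1.0
#: Ambient oxygenation : carboxylation flux ratio of Rubisco.
AMBIENT_PHOTORESPIRATION = 0.1


def build_one_cell_model(
    config: Optional[FixtureConfig] = None,
    curate: bool = True,
    photorespiration_ratio: float = AMBIENT_PHOTORESPIRATION,
    co2_upper: float = 20.0,
    maintenance: Optional[Mapping[str, float]] = None,
) -> MetabolicModel:
    """Full one-cell pipeline: build, curate, buffer, maintain, bound, couple.

    Returns the working C3 leaf model with the phloem objective
    (``max Ex_Suc + Ex_AA``) installed on the LP.
    """
    cfg = config or FixtureConfig()
    cfg.require("light_reactions", "calvin", "sugar_synthesis", "tca",
                "nitrate_assimilation", "transporters",
                experiment="one-cell pipeline")
    if photorespiration_ratio > 0:
        cfg.require("photorespiration", experiment="nonzero photorespiration")
    model = build_reduced_leaf_network(cfg)
    if curate:
        apply_curation(model, DEFAULT_CURATION)
    add_proton_buffers(model)
    add_maintenance(model, maintenance or DEFAULT_MAINTENANCE_COSTS)
    set_boundary(model, BoundarySpec.table_default(co2_upper=co2_upper))
    model.set_ratio_constraint(FluxRatioConstraint("Ex_Suc", "Ex_AA", SUC_AA_RATIO))
    model.set_ratio_constraint(
        FluxRatioConstraint("Ex_Suc", "Ex_starch", SUC_STARCH_RATIO))
    model.set_ratio_constraint(
        FluxRatioConstraint("RBO_h", "RBC_h", photorespiration_ratio))
    cm = model.cobra
    cm.objective = (cm.reactions.get_by_id("Ex_Suc").flux_expression
                    + cm.reactions.get_by_id("Ex_AA").flux_expression)
    cm.objective_direction = "max"
    return model


def build_two_cell_model(
    config: Optional[FixtureConfig] = None,
    co2_mesophyll: float = 40.0,
    ppfd_total: float = 1000.0,
    photorespiration_ratio: float = 1.0 / 3.0,
    **one_cell_kwargs,
):
    """One-cell pipeline followed by the two-cell composition."""
    from .two_cell import compose_two_cell

    cfg = config or FixtureConfig()
    cfg.require("c4_enzymes", experiment="two-cell composition")
    one_cell = build_one_cell_model(cfg, **one_cell_kwargs)
    return compose_two_cell(
        one_cell,
        co2_mesophyll=co2_mesophyll,
        ppfd_total=ppfd_total,
        photorespiration_ratio=photorespiration_ratio,
    )


def perturb_fixture(
    model: MetabolicModel, seed: int, jitter_fraction: float
) -> MetabolicModel:
    """Multiplicatively jitter non-fixed bounds; deterministic in ``seed``.

    Equality (fixed-flux) bounds are left untouched so maintenance and
    knockout constraints survive; both bounds of a reaction share one
    factor, which preserves ``lb <= ub``.
    """
    if not 0 <= jitter_fraction < 1:
        raise ValueError("jitter_fraction must be in [0, 1)")
    out = model.copy()
    rng = np.random.default_rng(seed)
    for rxn in out.cobra.reactions:
        factor = 1.0 + jitter_fraction * rng.uniform(-1.0, 1.0)
        if rxn.lower_bound == rxn.upper_bound:
            continue  # fixed bounds are reported as skipped by contract
        lb, ub = rxn.lower_bound * factor, rxn.upper_bound * factor
        rxn.bounds = (min(lb, ub), max(lb, ub))
    return out
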