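"""Mesophyll / bundle-sheath two-cell model composition.

The one-cell model is duplicated into a ``[M]`` (mesophyll) and a ``[B]``
(bundle sheath) copy, the copies are joined by reversible ``[MB]``
transporters for a whitelist of cytosolic metabolites (positive flux means
mesophyll -> bundle sheath), and the bundle sheath receives two Rubisco
populations:

* the *native* population carboxylates mesophyll-supplied ("external")
  CO2 through ``[B]_RBC_h_Ex`` and is ratio-coupled to the oxygenase
  ``[B]_RBO_h`` — photorespiration taxes every externally fixed carbon;
* the *CCM-dependent* population (``[B]_RBC_h``) carboxylates only CO2
  released inside the bundle sheath (glycine decarboxylase, the C4
  decarboxylases, respiration) and carries no oxygenation coupling —
  it is the static stand-in for a CO2-saturated Rubisco.

External CO2 enters the pools ``[B]_CO2_ex_{c,h}`` and may only move to
the chloroplast (``[B]_Tr_CO2h_Ex``) or react with the native Rubisco;
it never mixes with the internal pools, so the model cannot cheat the
concentration dependence in either direction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence, Tuple

import cobra
from cobra import Metabolite, Model, Reaction
from cobra.core import Group

from .model_core import (
    INF,
    FluxRatioConstraint,
    LinearCoupling,
    MetabolicModel,
    split_cell_prefix,
)

MESOPHYLL = "[M]"
BUNDLE_SHEATH = "[B]"
INTERFACE = "[MB]"


@dataclass(frozen=True)
class CellInterfaceSpec:
    """Which cytosolic metabolites may cross between the two cells.

    Charged currency metabolites, oxaloacetate (unstable and scarce in
    vivo), protons and bicarbonate stay cell-autonomous.  Names are base
    metabolite identifiers without the ``_c`` compartment suffix.
    """

    transportable: Tuple[str, ...] = (
        # amino acids (incl. the lumped phloem species and the
        # C4/photorespiratory carriers)
        "AA", "Ala", "Asp", "Glu", "Gly", "Ser",
        # sugars and phosphorylated intermediates
        "Suc", "GAP", "PGA",
        # carboxylic acids
        "PEP", "Pyr", "Cit", "iCit", "KG", "Mal",
        # photorespiratory intermediates
        "Glycolate", "Glycerate",
        # gas
        "CO2",
    )
    excluded: Tuple[str, ...] = (
        "ATP", "ADP", "NAD", "NADH", "NADP", "NADPH", "Pi", "OAA", "H",
        "HCO3", "NO3", "NO2", "NH4", "SO4", "H2S",
    )

    def __post_init__(self) -> None:
        overlap = set(self.transportable) & set(self.excluded)
        if overlap:
            raise ValueError(f"metabolites both transportable and excluded: {sorted(overlap)}")


DEFAULT_INTERFACE = CellInterfaceSpec()


class TwoCellModel(MetabolicModel):
    """A MetabolicModel whose ids carry ``[M]``/``[B]``/``[MB]`` prefixes."""

    def __init__(self, cobra_model, prefixes=(MESOPHYLL, BUNDLE_SHEATH), **kw):
        super().__init__(cobra_model, **kw)
        self.prefixes: Tuple[str, str] = tuple(prefixes)
        self.interface: Optional[CellInterfaceSpec] = None
        self.rubisco_registry: Dict[str, str] = {}
        self.annotations["cell_prefixes"] = ",".join(self.prefixes)

    def copy(self) -> "TwoCellModel":
        out = TwoCellModel(
            self.cobra.copy(), prefixes=self.prefixes,
            ratio_constraints=list(self.ratio_constraints),
            couplings=list(self.couplings),
            annotations=dict(self.annotations),
        )
        out.interface = self.interface
        out.rubisco_registry = dict(self.rubisco_registry)
        return out

    def interface_reactions(self) -> list:
        return [r for r in self.cobra.reactions if r.id.startswith(INTERFACE)]


# ---------------------------------------------------------------------------

def duplicate_cells(
    model: MetabolicModel,
    prefixes: Tuple[str, str] = (MESOPHYLL, BUNDLE_SHEATH),
) -> TwoCellModel:
    """Duplicate the one-cell model into two prefixed, unconnected copies.

    Bounds, ratio constraints, couplings and maintenance travel with each
    copy; metabolite and reaction counts double exactly.
    """
    model.validate()
    for prefix in prefixes:
        for rxn in model.cobra.reactions:
            if rxn.id.startswith(prefix):
                raise ValueError(
                    f"prefix {prefix!r} collides with existing id {rxn.id!r}")
    merged = Model(f"{model.cobra.id}_two_cell")
    group_members: Dict[str, list] = {}
    group_names: Dict[str, str] = {}
    for prefix in prefixes:
        copy = model.cobra.copy()
        for met in copy.metabolites:
            met.id = f"{prefix}_{met.id}"
        for rxn in copy.reactions:
            rxn.id = f"{prefix}_{rxn.id}"
        copy.repair()
        for grp in copy.groups:
            group_members.setdefault(grp.id, []).extend(m.id for m in grp.members)
            group_names[grp.id] = grp.name
        merged.add_reactions(list(copy.reactions))
        # orphan species (e.g. cofactor pools vacated by curation) must
        # still double with the cell
        merged.add_metabolites([m for m in copy.metabolites
                                if not merged.metabolites.has_id(m.id)])
    merged.add_groups([
        Group(gid, name=group_names[gid],
              members=[merged.reactions.get_by_id(r) for r in members])
        for gid, members in group_members.items()
    ])
    merged.compartments = dict(model.cobra.compartments)
    ratio, coupling = [], []
    for prefix in prefixes:
        for rc in model.ratio_constraints:
            ratio.append(FluxRatioConstraint(
                f"{prefix}_{rc.reaction_a}", f"{prefix}_{rc.reaction_b}", rc.ratio))
        for cp in model.couplings:
            coupling.append(LinearCoupling(
                f"{prefix}:{cp.name}",
                {f"{prefix}_{rid}": c for rid, c in cp.coefficients.items()},
                cp.lower, cp.upper))
    out = TwoCellModel(merged, prefixes=prefixes,
                       ratio_constraints=ratio, couplings=coupling)
    return out


def link_cells(
    two_cell: TwoCellModel,
    interface: CellInterfaceSpec = DEFAULT_INTERFACE,
) -> TwoCellModel:
    """Join the cells with one reversible ``[MB]`` transporter per
    whitelisted cytosolic metabolite (positive flux: mesophyll -> bundle
    sheath).  Raises if a whitelisted metabolite is missing from either
    cytosol; excluded metabolites get no transporter."""
    m_prefix, b_prefix = two_cell.prefixes
    cm = two_cell.cobra
    new = []
    for base in interface.transportable:
        mid_m, mid_b = f"{m_prefix}_{base}_c", f"{b_prefix}_{base}_c"
        for mid in (mid_m, mid_b):
            if not cm.metabolites.has_id(mid):
                raise KeyError(
                    f"transportable metabolite {base!r}: {mid!r} absent from cytosol")
        rxn = Reaction(f"{INTERFACE}_{base}", name=f"{base} intercellular transport",
                       lower_bound=-INF, upper_bound=INF)
        rxn.add_metabolites({
            cm.metabolites.get_by_id(mid_m): -1,
            cm.metabolites.get_by_id(mid_b): 1,
        })
        new.append(rxn)
    cm.add_reactions(new)
    if cm.groups.has_id("intercellular_transport"):
        cm.groups.get_by_id("intercellular_transport").add_members(new)
    else:
        cm.add_groups([Group("intercellular_transport",
                             name="intercellular transport", members=new)])
    two_cell.interface = interface
    two_cell.annotations["interface_transportable"] = ",".join(interface.transportable)
    return two_cell


def install_ccm_rubisco(two_cell: TwoCellModel) -> TwoCellModel:
    """Split the bundle-sheath CO2 supply into external and internal pools.

    Adds ``[B]_CO2_ex_{c,h}``, re-points the ``[MB]_CO2`` transporter at the
    external cytosolic pool, and adds the external-CO2 chloroplast import
    ``[B]_Tr_CO2h_Ex`` plus the native carboxylation ``[B]_RBC_h_Ex``.
    The photorespiration ratio constraint of the bundle sheath moves onto
    the (``[B]_RBO_h``, ``[B]_RBC_h_Ex``) pair; the pre-existing
    ``[B]_RBC_h``, now fed exclusively by internally released CO2, becomes
    the unconstrained CCM-dependent population.
    """
    b = two_cell.prefixes[1]
    cm = two_cell.cobra
    for rid in (f"{b}_RBC_h", f"{b}_RBO_h"):
        two_cell.require_reaction(rid)
    if not cm.reactions.has_id(f"{INTERFACE}_CO2"):
        raise KeyError("link_cells must run first: no [MB]_CO2 transporter")
    if cm.metabolites.has_id(f"{b}_CO2_ex_c"):
        return two_cell  # already installed

    co2_c = cm.metabolites.get_by_id(f"{b}_CO2_c")
    ex_c = Metabolite(f"{b}_CO2_ex_c", name="external CO2 (cytosol)",
                      compartment=co2_c.compartment, formula=co2_c.formula)
    ex_h = Metabolite(f"{b}_CO2_ex_h", name="external CO2 (chloroplast)",
                      compartment="h", formula=co2_c.formula)

    transporter = cm.reactions.get_by_id(f"{INTERFACE}_CO2")
    transporter.add_metabolites({co2_c: -1, ex_c: 1}, combine=True)

    tr = Reaction(f"{b}_Tr_CO2h_Ex", name="external CO2 chloroplast import",
                  lower_bound=0.0, upper_bound=INF)
    tr.add_metabolites({ex_c: -1, ex_h: 1})

    native = cm.reactions.get_by_id(f"{b}_RBC_h")
    rbc_ex = Reaction(f"{b}_RBC_h_Ex",
                      name="Rubisco carboxylase (external CO2, native population)",
                      lower_bound=0.0, upper_bound=INF)
    stoich = {}
    for met, coef in native.metabolites.items():
        stoich[ex_h if met.id == f"{b}_CO2_h" else met] = coef
    rbc_ex.add_metabolites(stoich)
    cm.add_reactions([tr, rbc_ex])

    # move the bundle-sheath oxygenation coupling onto the native pair
    moved = []
    for rc in two_cell.ratio_constraints:
        if (rc.reaction_a, rc.reaction_b) == (f"{b}_RBO_h", f"{b}_RBC_h"):
            moved.append(FluxRatioConstraint(
                f"{b}_RBO_h", f"{b}_RBC_h_Ex", rc.ratio))
        else:
            moved.append(rc)
    two_cell.ratio_constraints = moved

    m = two_cell.prefixes[0]
    two_cell.rubisco_registry = {
        "native_m_carboxylase": f"{m}_RBC_h",
        "native_m_oxygenase": f"{m}_RBO_h",
        "native_b_carboxylase": f"{b}_RBC_h_Ex",
        "native_b_oxygenase": f"{b}_RBO_h",
        "ccm_b_carboxylase": f"{b}_RBC_h",
    }
    two_cell.annotations["rubisco_registry"] = json.dumps(two_cell.rubisco_registry)
    return two_cell


def set_two_cell_bounds(
    two_cell: TwoCellModel,
    co2_mesophyll: float = 40.0,
    ppfd_total: float = 1000.0,
    ppfd_ratio_b_over_m: Optional[float] = None,
    enforce_ordering: bool = True,
) -> TwoCellModel:
    """Two-cell input constraints.

    Mesophyll CO2 uptake is capped (the C4 default is 40 umol/(m2 s)); the
    bundle sheath, shielded from the atmosphere, imports none.  The summed
    photon uptake is budgeted and, because the bundle sheath sits deeper in
    the leaf, bounded by the mesophyll's — unless an explicit distribution
    ratio is being scanned, in which case the ordering is released.
    """
    if ppfd_ratio_b_over_m is not None and ppfd_ratio_b_over_m < 0:
        raise ValueError("ppfd ratio must be >= 0")
    if (ppfd_ratio_b_over_m is not None and ppfd_ratio_b_over_m > 1
            and enforce_ordering):
        raise ValueError(
            "PPFD_B/PPFD_M > 1 contradicts the bundle-sheath <= mesophyll "
            "ordering; release enforce_ordering to scan such ratios")
    m, b = two_cell.prefixes
    im_m = two_cell.require_reaction(f"{m}_Im_CO2")
    im_b = two_cell.require_reaction(f"{b}_Im_CO2")
    im_m.bounds = (0.0, co2_mesophyll)
    im_b.bounds = (0.0, 0.0)
    hnu_m = two_cell.require_reaction(f"{m}_Im_hnu")
    hnu_b = two_cell.require_reaction(f"{b}_Im_hnu")
    hnu_m.bounds = (0.0, ppfd_total)
    hnu_b.bounds = (0.0, ppfd_total)
    two_cell.set_coupling(LinearCoupling(
        "ppfd_total", {hnu_m.id: 1.0, hnu_b.id: 1.0}, 0.0, ppfd_total))
    two_cell.drop_coupling("ppfd_ordering")
    two_cell.drop_coupling("ppfd_ratio")
    if ppfd_ratio_b_over_m is not None:
        two_cell.set_coupling(LinearCoupling(
            "ppfd_ratio", {hnu_b.id: 1.0, hnu_m.id: -ppfd_ratio_b_over_m},
            0.0, 0.0))
    elif enforce_ordering:
        two_cell.set_coupling(LinearCoupling(
            "ppfd_ordering", {hnu_b.id: 1.0, hnu_m.id: -1.0}, None, 0.0))
    return two_cell


def phloem_objective_ids(two_cell: TwoCellModel) -> Dict[str, float]:
    """Phloem sap output leaves through the bundle sheath."""
    b = two_cell.prefixes[1]
    return {f"{b}_Ex_Suc": 1.0, f"{b}_Ex_AA": 1.0}


def compose_two_cell(
    one_cell: MetabolicModel,
    interface: CellInterfaceSpec = DEFAULT_INTERFACE,
    co2_mesophyll: float = 40.0,
    ppfd_total: float = 1000.0,
    photorespiration_ratio: Optional[float] = 1.0 / 3.0,
) -> TwoCellModel:
    """duplicate -> link -> install CCM Rubisco -> bounds -> objective."""
    tc = duplicate_cells(one_cell)
    link_cells(tc, interface)
    install_ccm_rubisco(tc)
    set_two_cell_bounds(tc, co2_mesophyll=co2_mesophyll, ppfd_total=ppfd_total)
    if photorespiration_ratio is not None:
        set_native_photorespiration(tc, photorespiration_ratio)
    cm = tc.cobra
    expr = None
    for rid in phloem_objective_ids(tc):
        term = cm.reactions.get_by_id(rid).flux_expression
        expr = term if expr is None else expr + term
    cm.objective = expr
    cm.objective_direction = "max"
    return tc


def set_native_photorespiration(two_cell: TwoCellModel, ratio: float) -> TwoCellModel:
    """Pin the oxygenation:carboxylation ratio of both native populations."""
    reg = two_cell.rubisco_registry
    if not reg:
        raise KeyError("install_ccm_rubisco must run before setting ratios")
    two_cell.set_ratio_constraint(FluxRatioConstraint(
        reg["native_m_oxygenase"], reg["native_m_carboxylase"], ratio))
    two_cell.set_ratio_constraint(FluxRatioConstraint(
        reg["native_b_oxygenase"], reg["native_b_carboxylase"], ratio))
    return two_cell


def as_two_cell(model: MetabolicModel) -> TwoCellModel:
    """Re-attach two-cell metadata after an SBML round trip."""
    prefixes = tuple(model.annotations.get("cell_prefixes", "[M],[B]").split(","))
    out = TwoCellModel(model.cobra, prefixes=prefixes,
                       ratio_constraints=model.ratio_constraints,
                       couplings=model.couplings,
                       annotations=model.annotations)
    if "rubisco_registry" in model.annotations:
        out.rubisco_registry = json.loads(model.annotations["rubisco_registry"])
    if "interface_transportable" in model.annotations:
        out.interface = CellInterfaceSpec(transportable=tuple(
            model.annotations["interface_transportable"].split(",")))
    return out
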