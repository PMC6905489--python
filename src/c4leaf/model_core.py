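"""Core representation and curation of the compartmented leaf metabolic model.

The in-memory container is a thin wrapper around :class:`cobra.Model` that
additionally carries declarative linear flux couplings (flux-ratio
constraints such as the phloem export composition, and generic couplings
such as a total-photon budget).  These are *not* installed into the LP at
construction time; the solver layer (:mod:`c4leaf.fba_engine`) materialises
them for every solve so that ``copy()`` and SBML round trips stay cheap and
loss-free.

Flux units are umol/(m2 s) throughout, matching the leaf gas-exchange
convention.  Compartments are cytosol ``c``, chloroplast ``h``,
mitochondrion ``m`` and peroxisome ``p``; in a two-cell model every
identifier additionally carries a ``[M]``/``[B]`` cell prefix.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import cobra
import pandas as pd
from cobra import Metabolite, Reaction

#: Finite stand-in for an unbounded flux, per the boundary-constraint table.
INF = 1.0e6

#: Non-growth-associated maintenance ATP cost per compartment, umol/(m2 s),
#: measured for a mature leaf.  The peroxisome lacks an ATP pool, so its
#: cost is folded into the cytosolic maintenance reaction.
DEFAULT_MAINTENANCE_COSTS: Dict[str, float] = {
    "c": 0.0427,
    "h": 0.1527,
    "m": 0.0091,
    "p": 0.0076,
}

_CELL_PREFIX_RE = re.compile(r"^(\[[A-Z]{1,2}\]_)")


def split_cell_prefix(identifier: str) -> Tuple[str, str]:
    """Split ``"[M]_RBC_h"`` into ``("[M]_", "RBC_h")``; no prefix -> ``""``."""
    m = _CELL_PREFIX_RE.match(identifier)
    if m:
        return m.group(1), identifier[m.end():]
    return "", identifier


# ---------------------------------------------------------------------------
# declarative constraint types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FluxRatioConstraint:
    """Linear coupling ``v_a = ratio * v_b`` between two reactions."""

    reaction_a: str
    reaction_b: str
    ratio: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.ratio):
            raise ValueError(f"ratio must be finite, got {self.ratio!r}")
        if self.ratio < 0:
            raise ValueError(f"ratio must be >= 0, got {self.ratio!r}")

    def coefficients(self) -> Dict[str, float]:
        return {self.reaction_a: 1.0, self.reaction_b: -self.ratio}


@dataclass(frozen=True)
class LinearCoupling:
    """Generic linear constraint ``lower <= sum_i c_i * v_i <= upper``."""

    name: str
    coefficients: Mapping[str, float]
    lower: Optional[float] = None
    upper: Optional[float] = None

    def __post_init__(self) -> None:
        if self.lower is None and self.upper is None:
            raise ValueError("coupling needs at least one of lower/upper")
        if (
            self.lower is not None
            and self.upper is not None
            and self.lower > self.upper
        ):
            raise ValueError(f"lower {self.lower} > upper {self.upper}")


@dataclass(frozen=True)
class PhotorespirationSpec:
    """Oxygenation:carboxylation flux ratio of Rubisco (``v_RBO/v_RBC``).

    The ratio can be given directly (the ambient default is 0.1) or derived
    from the Rubisco CO2/O2 specificity ``SR`` and the partial pressures:
    ``ratio = (1/SR) * pO2/pCO2``.
    """

    ratio: float

    def __post_init__(self) -> None:
        if self.ratio < 0:
            raise ValueError(f"photorespiration ratio must be >= 0, got {self.ratio}")

    @classmethod
    def from_specificity(cls, sr: float, po2: float, pco2: float) -> "PhotorespirationSpec":
        if sr <= 0 or pco2 <= 0:
            raise ValueError("specificity and pCO2 must be positive")
        return cls(ratio=(1.0 / sr) * (po2 / pco2))


@dataclass
class BoundarySpec:
    """Bounds for the import/export reactions, umol/(m2 s).

    ``math.inf`` entries are replaced by ``infinity_proxy`` when applied.
    Exchanges present in the model but not named here are clamped to zero
    (the leaf exports nothing besides phloem sap, water and oxygen); proton
    sink/source reactions are exempt from the clamp.
    """

    bounds: Dict[str, Tuple[float, float]]
    infinity_proxy: float = INF

    def __post_init__(self) -> None:
        for rid, (lb, ub) in self.bounds.items():
            if lb > ub:
                raise ValueError(f"{rid}: lower bound {lb} > upper bound {ub}")

    @classmethod
    def table_default(cls, co2_upper: float = 20.0) -> "BoundarySpec":
        """Photoautotrophic defaults: CO2-limited, nitrate the sole N source."""
        inf = math.inf
        return cls(bounds={
            "Im_hnu": (0.0, inf),
            "Im_CO2": (0.0, co2_upper),
            "Im_NO3": (0.0, inf),
            "Im_NH4": (0.0, 0.0),
            "Im_SO4": (0.0, inf),
            "Im_H2S": (0.0, inf),
            "Im_Pi": (0.0, inf),
            "Im_H2O": (-inf, inf),
            "Im_O2": (-inf, inf),
            "Ex_AA": (0.0, inf),
            "Ex_Suc": (0.0, inf),
            "Ex_starch": (0.0, inf),
        })

    def resolved(self) -> Dict[str, Tuple[float, float]]:
        out = {}
        for rid, (lb, ub) in self.bounds.items():
            lb = -self.infinity_proxy if lb == -math.inf else lb
            ub = self.infinity_proxy if ub == math.inf else ub
            out[rid] = (lb, ub)
        return out


_CURATION_KINDS = {
    "add_reaction", "remove_reaction", "set_bounds", "swap_cofactor",
    "set_stoichiometry", "add_transport", "fix_zero_flux",
}

_REQUIRED_PAYLOAD = {
    "add_reaction": {"reaction", "stoichiometry", "lower", "upper"},
    "add_transport": {"reaction", "stoichiometry"},
    "remove_reaction": {"reaction"},
    "set_bounds": {"reaction", "lower", "upper"},
    "swap_cofactor": {"reaction", "mapping"},
    "set_stoichiometry": {"reaction", "metabolite", "coefficient"},
    "fix_zero_flux": {"reaction"},
}


@dataclass(frozen=True)
class CurationAction:
    """One declarative model edit; the packaged default set is data, not code."""

    kind: str
    payload: Mapping[str, object]
    note: str = ""

    def __post_init__(self) -> None:
        if self.kind not in _CURATION_KINDS:
            raise ValueError(f"unknown curation kind {self.kind!r}")
        missing = _REQUIRED_PAYLOAD[self.kind] - set(self.payload)
        if missing:
            raise ValueError(
                f"curation action {self.kind!r} payload incomplete: missing {sorted(missing)}"
            )


# ---------------------------------------------------------------------------
# the model container
# ---------------------------------------------------------------------------

class MetabolicModel:
    """Compartmented stoichiometric network with bounds, objective and couplings."""

    def __init__(
        self,
        cobra_model: cobra.Model,
        ratio_constraints: Iterable[FluxRatioConstraint] = (),
        couplings: Iterable[LinearCoupling] = (),
        annotations: Optional[Dict[str, str]] = None,
    ) -> None:
        self.cobra = cobra_model
        self.ratio_constraints: List[FluxRatioConstraint] = list(ratio_constraints)
        self.couplings: List[LinearCoupling] = list(couplings)
        self.annotations: Dict[str, str] = dict(annotations or {})

    # -- delegation ---------------------------------------------------------
    @property
    def reactions(self):
        return self.cobra.reactions

    @property
    def metabolites(self):
        return self.cobra.metabolites

    @property
    def compartments(self):
        return set(self.cobra.compartments)

    def __contains__(self, reaction_id: str) -> bool:
        return self.cobra.reactions.has_id(reaction_id)

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            self.cobra.copy(),
            ratio_constraints=list(self.ratio_constraints),
            couplings=list(self.couplings),
            annotations=dict(self.annotations),
        )

    # -- constraints --------------------------------------------------------
    def require_reaction(self, reaction_id: str) -> Reaction:
        if not self.cobra.reactions.has_id(reaction_id):
            raise KeyError(f"reaction {reaction_id!r} not in model")
        return self.cobra.reactions.get_by_id(reaction_id)

    def add_ratio_constraint(self, constraint: FluxRatioConstraint) -> None:
        self.require_reaction(constraint.reaction_a)
        self.require_reaction(constraint.reaction_b)
        self.ratio_constraints.append(constraint)

    def set_ratio_constraint(self, constraint: FluxRatioConstraint) -> None:
        """Install the ratio, replacing any prior constraint on the same pair."""
        pair = (constraint.reaction_a, constraint.reaction_b)
        self.ratio_constraints = [
            rc for rc in self.ratio_constraints
            if (rc.reaction_a, rc.reaction_b) != pair
        ]
        self.add_ratio_constraint(constraint)

    def set_coupling(self, coupling: LinearCoupling) -> None:
        for rid in coupling.coefficients:
            self.require_reaction(rid)
        self.couplings = [c for c in self.couplings if c.name != coupling.name]
        self.couplings.append(coupling)

    def drop_coupling(self, name: str) -> None:
        self.couplings = [c for c in self.couplings if c.name != name]

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        """Raise ``ValueError`` naming the first violated structural invariant."""
        for rxn in self.cobra.reactions:
            if rxn.lower_bound > rxn.upper_bound:
                raise ValueError(
                    f"invariant violated: {rxn.id} lower bound {rxn.lower_bound} "
                    f"> upper bound {rxn.upper_bound}"
                )
            if len(rxn.metabolites) == 0:
                raise ValueError(f"invariant violated: {rxn.id} has empty stoichiometry")
        comp = set(self.cobra.compartments)
        for met in self.cobra.metabolites:
            if met.compartment and met.compartment not in comp:
                raise ValueError(
                    f"invariant violated: metabolite {met.id} compartment "
                    f"{met.compartment!r} not declared"
                )
        for rc in self.ratio_constraints:
            self.require_reaction(rc.reaction_a)
            self.require_reaction(rc.reaction_b)


# ---------------------------------------------------------------------------
# element accounting
# ---------------------------------------------------------------------------

_NOTE_KEYS = {"C": "carbon_count", "N": "nitrogen_count"}


def element_count(met: Metabolite, element: str) -> Optional[float]:
    """Element count of a metabolite; ``notes`` overrides the formula.

    The override exists because the lumped phloem amino-acid species carries
    a non-integer 5.5 carbons, which no chemical formula can express.
    Returns ``None`` when the metabolite carries neither source.
    """
    key = _NOTE_KEYS.get(element)
    if key and key in met.notes:
        return float(met.notes[key])
    if met.formula is None:
        return None
    return float(met.elements.get(element, 0))


def check_conservation(
    model: MetabolicModel,
    element: str = "C",
    tolerance: float = 1e-9,
    extra_exempt: Sequence[str] = (),
) -> pd.DataFrame:
    """Report reactions whose elemental balance is nonzero.

    Boundary/pseudo reactions (single-metabolite exchanges, which include
    the proton sink/source reactions and photon import) are listed as
    ``exempt``; reactions touching a metabolite without elemental data are
    ``unchecked``; everything else is ``balanced`` or ``flagged`` with its
    imbalance (products minus substrates).
    """
    rows = []
    exempt = set(extra_exempt)
    for rxn in model.cobra.reactions:
        if len(rxn.metabolites) == 1 or rxn.id in exempt:
            rows.append((rxn.id, 0.0, "exempt"))
            continue
        total = 0.0
        unknown = False
        for met, coef in rxn.metabolites.items():
            n = element_count(met, element)
            if n is None:
                unknown = True
                break
            total += coef * n
        if unknown:
            rows.append((rxn.id, float("nan"), "unchecked"))
        elif abs(total) > tolerance:
            rows.append((rxn.id, total, "flagged"))
        else:
            rows.append((rxn.id, 0.0, "balanced"))
    report = pd.DataFrame(rows, columns=["reaction", "imbalance", "status"])
    return report


def conservation_violations(report: pd.DataFrame) -> pd.DataFrame:
    return report[report["status"] == "flagged"].reset_index(drop=True)


# ---------------------------------------------------------------------------
# structural operations
# ---------------------------------------------------------------------------

def add_proton_buffers(model: MetabolicModel) -> MetabolicModel:
    """Add one reversible proton sink/source per compartment (idempotent).

    The protonation state of most transport substrates is unknown, so the
    network cannot balance protons honestly; a free sink/source per
    compartment prevents futile proton-coupled transport cycles.  Operates
    per proton species, so a prefixed two-cell model gets one buffer per
    cell and compartment.
    """
    cm = model.cobra
    # ensure proton species exist for the canonical compartments of an
    # un-prefixed model
    prefixes = {split_cell_prefix(m.id)[0] for m in cm.metabolites}
    if prefixes == {""}:
        for comp in sorted(set(cm.compartments) & {"c", "h", "m", "p"}):
            if not cm.metabolites.has_id(f"H_{comp}"):
                cm.add_metabolites([Metabolite(
                    f"H_{comp}", name="proton", compartment=comp, formula="H", charge=1,
                )])
    new = []
    for met in list(cm.metabolites):
        prefix, base = split_cell_prefix(met.id)
        if not re.fullmatch(r"H_[a-z]\w*", base):
            continue
        rid = f"{prefix}Sink_H_{met.compartment}" if base == f"H_{met.compartment}" \
            else f"{prefix}Sink_{base}"
        if cm.reactions.has_id(rid):
            continue
        rxn = Reaction(rid, name=f"proton sink/source ({met.id})",
                       lower_bound=-INF, upper_bound=INF)
        rxn.add_metabolites({met: 1.0})
        new.append(rxn)
    if new:
        cm.add_reactions(new)
    return model


def add_maintenance(
    model: MetabolicModel,
    costs: Optional[Mapping[str, float]] = None,
) -> MetabolicModel:
    """Install fixed-flux maintenance ATPases ``NGAM_{c,h,m}``.

    ``ATP_x + H2O_x -> ADP_x + H_x + Pi_x`` with both bounds pinned to the
    compartment's measured cost; the peroxisomal cost rides on the cytosolic
    reaction because the model has no peroxisomal ATP pool.
    """
    costs = dict(DEFAULT_MAINTENANCE_COSTS if costs is None else costs)
    cm = model.cobra
    targets = {"c": costs.get("c", 0.0) + costs.get("p", 0.0),
               "h": costs.get("h", 0.0),
               "m": costs.get("m", 0.0)}
    for comp, cost in targets.items():
        rid = f"NGAM_{comp}"
        needed = [f"ATP_{comp}", f"H2O_{comp}", f"ADP_{comp}", f"H_{comp}", f"Pi_{comp}"]
        missing = [s for s in needed if not cm.metabolites.has_id(s)]
        if missing:
            raise KeyError(
                f"cannot build {rid}: compartment {comp!r} lacks species {missing}"
            )
        if cm.reactions.has_id(rid):
            rxn = cm.reactions.get_by_id(rid)
        else:
            rxn = Reaction(rid, name=f"maintenance ATPase ({comp})")
            rxn.add_metabolites({
                cm.metabolites.get_by_id(f"ATP_{comp}"): -1,
                cm.metabolites.get_by_id(f"H2O_{comp}"): -1,
                cm.metabolites.get_by_id(f"ADP_{comp}"): 1,
                cm.metabolites.get_by_id(f"H_{comp}"): 1,
                cm.metabolites.get_by_id(f"Pi_{comp}"): 1,
            })
            cm.add_reactions([rxn])
        rxn.bounds = (cost, cost)
    return model


def set_boundary(model: MetabolicModel, spec: Optional[BoundarySpec] = None) -> MetabolicModel:
    """Apply the import/export bound table; clamp unlisted exchanges to zero."""
    spec = spec or BoundarySpec.table_default()
    cm = model.cobra
    resolved = spec.resolved()
    for rid in resolved:
        if not cm.reactions.has_id(rid):
            raise KeyError(f"boundary spec names unknown exchange {rid!r}")
    for rid, bounds in resolved.items():
        cm.reactions.get_by_id(rid).bounds = bounds
    for rxn in cm.boundary:
        if rxn.id in resolved:
            continue
        _, base = split_cell_prefix(rxn.id)
        if base.startswith("Sink_H"):
            continue
        rxn.bounds = (0.0, 0.0)
    return model


# ---------------------------------------------------------------------------
# curation
# ---------------------------------------------------------------------------

def apply_curation(
    model: MetabolicModel,
    actions: Sequence[CurationAction],
) -> Tuple[MetabolicModel, pd.DataFrame]:
    """Apply curation actions in order; returns the model and a change report."""
    cm = model.cobra
    rows = []
    for action in actions:
        p = dict(action.payload)
        kind = action.kind
        if kind in {"set_bounds", "swap_cofactor", "set_stoichiometry",
                    "fix_zero_flux", "remove_reaction"}:
            rxn = model.require_reaction(str(p["reaction"]))
        if kind == "set_bounds":
            rxn.bounds = (float(p["lower"]), float(p["upper"]))
            detail = f"bounds=({rxn.lower_bound}, {rxn.upper_bound})"
        elif kind == "fix_zero_flux":
            rxn.bounds = (0.0, 0.0)
            detail = "bounds=(0, 0)"
        elif kind == "swap_cofactor":
            mapping = dict(p["mapping"])
            present = [m for m in mapping if any(x.id == m for x in rxn.metabolites)]
            if not present:
                raise ValueError(
                    f"swap_cofactor: reaction {rxn.id!r} uses none of {sorted(mapping)}"
                )
            changes = {}
            for old_id in present:
                new_id = mapping[old_id]
                old = cm.metabolites.get_by_id(old_id)
                new = cm.metabolites.get_by_id(new_id)
                coef = rxn.metabolites[old]
                changes[old] = -coef
                changes[new] = coef
            rxn.add_metabolites(changes, combine=True)
            detail = "; ".join(f"{o}->{mapping[o]}" for o in present)
        elif kind == "set_stoichiometry":
            met = cm.metabolites.get_by_id(str(p["metabolite"]))
            target = float(p["coefficient"])
            current = rxn.metabolites.get(met, 0.0)
            rxn.add_metabolites({met: target - current}, combine=True)
            detail = f"{met.id} coefficient {current} -> {target}"
        elif kind == "remove_reaction":
            cm.remove_reactions([rxn])
            detail = "removed"
        elif kind in {"add_reaction", "add_transport"}:
            rid = str(p["reaction"])
            if cm.reactions.has_id(rid):
                raise ValueError(f"{kind}: reaction {rid!r} already exists")
            lb = float(p.get("lower", -INF))
            ub = float(p.get("upper", INF))
            rxn = Reaction(rid, name=str(p.get("name", rid)), lower_bound=lb, upper_bound=ub)
            stoich = {}
            for mid, coef in dict(p["stoichiometry"]).items():
                stoich[cm.metabolites.get_by_id(mid)] = float(coef)
            rxn.add_metabolites(stoich)
            cm.add_reactions([rxn])
            detail = rxn.build_reaction_string()
        else:  # pragma: no cover - guarded by CurationAction validation
            raise ValueError(kind)
        rows.append((kind, str(p.get("reaction", "")), detail, action.note))
    report = pd.DataFrame(rows, columns=["kind", "reaction", "change", "note"])
    return model, report


def _swap(reaction: str, compartment: str) -> CurationAction:
    return CurationAction(
        "swap_cofactor",
        {"reaction": reaction,
         "mapping": {f"NADPH_{compartment}": f"NADH_{compartment}",
                     f"NADP_{compartment}": f"NAD_{compartment}"}},
        note="malate dehydrogenase is NAD-dependent outside the chloroplast",
    )


#: The packaged default curation set for the bundled reduced leaf network.
#: Cofactor fixes, ATP-synthase H+/ATP stoichiometry, decarboxylase
#: irreversibility and the zero-flux assumptions are edits; subsystems that
#: the historical core model lacked (cyclic electron flow, alternative
#: oxidases, envelope transporters, transferases) are built into the
#: synthetic network directly.
DEFAULT_CURATION: Tuple[CurationAction, ...] = (
    _swap("MDH_c", "c"),
    _swap("MDH_m", "m"),
    _swap("MDH_p", "p"),
    CurationAction("set_stoichiometry",
                   {"reaction": "ATPSynth_h", "metabolite": "pmf_h", "coefficient": -3.0},
                   note="chloroplast ATP synthase translocates 3 H+ per ATP"),
    CurationAction("set_stoichiometry",
                   {"reaction": "ATPSynth_m", "metabolite": "pmf_m", "coefficient": -4.0},
                   note="mitochondrial ATP synthase translocates 4 H+ per ATP"),
) + tuple(
    CurationAction("set_bounds", {"reaction": rid, "lower": 0.0, "upper": INF},
                   note="decarboxylation is kinetically unidirectional")
    for rid in ("NADPME_h", "NADME_m", "PEPCK_c", "GDC_m", "ICDH_m", "TCA2_m", "PDH_m")
) + (
    CurationAction("fix_zero_flux", {"reaction": "iCitDHNADP_h"},
                   note="chloroplastic NADP-isocitrate dehydrogenase has minor effect"),
    CurationAction("fix_zero_flux", {"reaction": "AOX4_h"},
                   note="plastoquinol oxidase has minor effect on photosynthesis"),
    CurationAction("fix_zero_flux", {"reaction": "Tr_ADPATP_hc"},
                   note="chloroplastic ADP/ATP carrier is dispensable in the light"),
)
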