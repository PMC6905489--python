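"""The in-silico experiments: scans, knockouts, FVA and energy accounting.

Every experiment is a driver that sets constraints on (a copy of) the
two-cell model, runs the staged pFBA solve — maximise bundle-sheath phloem
output, optionally minimise photorespiration, then minimise total flux —
and extracts a feature record per grid point into a :class:`ScanResult`.
Infeasible grid points are recorded with their solver status, never
dropped.  Everything is a deterministic LP, so identical grids reproduce
identical tables bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .fba_engine import (
    FluxDistribution,
    FVAResult,
    Objective,
    lexicographic_solve,
    run_fva,
)
from .model_core import FluxRatioConstraint, LinearCoupling, MetabolicModel
from .two_cell import TwoCellModel, phloem_objective_ids, set_two_cell_bounds

#: The three C4 decarboxylation enzymes.
DECARBOXYLASES = ("NADP-ME", "NAD-ME", "PEP-CK")

#: Named photorespiration presets (oxygenation : carboxylation ratio).
PHOTORESPIRATION_PRESETS = {"low": 0.03, "ambient": 0.10, "high": 1.0 / 3.0}

#: Numerical cutoff below which a flux counts as "off".
FLUX_EPS = 1e-6


@dataclass(frozen=True)
class EnzymeRegistry:
    """Maps enzyme labels to the model reaction ids that realise them.

    Declarative configuration: the default matches the bundled reduced
    network's id scheme; a registry for another model (e.g. a genome-scale
    reconstruction with per-isoform reactions) lists its own ids.
    """

    groups: Mapping[str, Tuple[str, ...]]

    def ids(self, label: str) -> Tuple[str, ...]:
        try:
            return self.groups[label]
        except KeyError:
            raise KeyError(f"unknown enzyme label {label!r}; known: {sorted(self.groups)}")

    def flux(self, label: str, solution: FluxDistribution) -> float:
        return float(sum(solution.get(rid) for rid in self.ids(label)))


_BASE_ENZYMES = {
    "PEPC": ("PEPC_c",),
    "PPDK": ("PPDK_h",),
    "NADP-ME": ("NADPME_h",),
    "NAD-ME": ("NADME_m",),
    "PEP-CK": ("PEPCK_c",),
    "GDC": ("GDC_m",),
}


def default_registry(two_cell: TwoCellModel) -> EnzymeRegistry:
    """Registry for the bundled network's ids, expanded over both cells."""
    groups: Dict[str, Tuple[str, ...]] = {}
    for label, bases in _BASE_ENZYMES.items():
        ids = tuple(
            f"{p}_{b}" for p in two_cell.prefixes for b in bases
            if f"{p}_{b}" in two_cell
        )
        groups[label] = ids
        groups[f"{label}(B)"] = tuple(
            i for i in ids if i.startswith(two_cell.prefixes[1]))
    reg = two_cell.rubisco_registry
    groups["Rubisco-native-M"] = (reg["native_m_carboxylase"],)
    groups["Rubisco-native-B"] = (reg["native_b_carboxylase"],)
    groups["Rubisco-CCM"] = (reg["ccm_b_carboxylase"],)
    groups["RBO"] = (reg["native_m_oxygenase"], reg["native_b_oxygenase"])
    groups["CO2-uptake"] = (f"{two_cell.prefixes[0]}_Im_CO2",
                            f"{two_cell.prefixes[1]}_Im_CO2")
    groups["phloem"] = tuple(phloem_objective_ids(two_cell))
    return EnzymeRegistry(groups)


@dataclass
class ScanResult:
    """Parameter grid -> extracted flux features, one row per grid point."""

    axes: Dict[str, np.ndarray]
    table: pd.DataFrame
    meta: Dict[str, object] = field(default_factory=dict)

    def to_tsv(self, path: str) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class EnergyAccount:
    """Subsystem shares of one cofactor's production and consumption."""

    cofactor: str
    producers: pd.Series  # percent of total production, by subsystem
    consumers: pd.Series
    total_production: float
    total_consumption: float

    def __post_init__(self) -> None:
        for name, series in (("producers", self.producers),
                             ("consumers", self.consumers)):
            if len(series) and abs(series.sum() - 100.0) > 0.1:
                raise ValueError(
                    f"{name} percentages sum to {series.sum():.3f}, not 100")


# ---------------------------------------------------------------------------
# solve helpers
# ---------------------------------------------------------------------------

def two_cell_objectives(
    two_cell: TwoCellModel,
    registry: Optional[EnzymeRegistry] = None,
    minimize_photorespiration: bool = False,
) -> List[Objective]:
    registry = registry or default_registry(two_cell)
    objectives = [Objective(phloem_objective_ids(two_cell), "max", "phloem")]
    if minimize_photorespiration:
        objectives.append(Objective(
            {rid: 1.0 for rid in registry.ids("RBO")}, "min", "photorespiration"))
    return objectives


def extract_features(
    two_cell: TwoCellModel,
    solution: FluxDistribution,
    registry: Optional[EnzymeRegistry] = None,
) -> Dict[str, float]:
    registry = registry or default_registry(two_cell)
    rec: Dict[str, float] = {"status": solution.status}
    if not solution.optimal:
        return rec
    for label in ("PEPC", "PPDK", "NADP-ME", "NAD-ME", "PEP-CK", "GDC",
                  "NADP-ME(B)", "NAD-ME(B)", "PEP-CK(B)", "GDC(B)",
                  "Rubisco-native-M", "Rubisco-native-B", "Rubisco-CCM",
                  "RBO", "CO2-uptake", "phloem"):
        rec[label] = registry.flux(label, solution)
    rec["total_abs_flux"] = solution.total_abs_flux
    for rxn in two_cell.interface_reactions():
        rec[rxn.id] = solution.get(rxn.id)
    return rec


def decarboxylase_shares(record: Mapping[str, float]) -> Dict[str, float]:
    """Bundle-sheath decarboxylase activity relative to the CO2 uptake rate."""
    co2 = record.get("CO2-uptake", 0.0)
    out = {}
    for label in DECARBOXYLASES:
        flux = record.get(f"{label}(B)", 0.0)
        out[f"{label}/CO2"] = float("nan") if abs(co2) < FLUX_EPS else flux / co2
    return out


# ---------------------------------------------------------------------------
# experiments
# ---------------------------------------------------------------------------

def photorespiration_scan(
    two_cell: TwoCellModel,
    ratios: Optional[Sequence[float]] = None,
    registry: Optional[EnzymeRegistry] = None,
    minimize_photorespiration: bool = False,
) -> ScanResult:
    """Sweep the native oxygenation:carboxylation ratio (the C3->C4 axis).

    At each grid point the ratio is pinned on both native Rubisco
    populations and the staged pFBA run; the extracted features trace the
    emergence of the C4 cycle.
    """
    from .two_cell import set_native_photorespiration

    ratios = np.asarray(ratios if ratios is not None else np.linspace(0, 1, 21),
                        dtype=float)
    registry = registry or default_registry(two_cell)
    work = two_cell.copy()
    rows = []
    for r in ratios:
        set_native_photorespiration(work, float(r))
        objectives = two_cell_objectives(work, registry, minimize_photorespiration)
        sol = lexicographic_solve(work, objectives)
        rec = {"ratio": float(r)}
        rec.update(extract_features(work, sol, registry))
        rows.append(rec)
    return ScanResult(axes={"ratio": ratios}, table=pd.DataFrame(rows),
                      meta={"minimize_photorespiration": minimize_photorespiration})


def _apply_knockout(
    two_cell: TwoCellModel, keep: str, registry: EnzymeRegistry
) -> TwoCellModel:
    if keep not in DECARBOXYLASES:
        raise KeyError(
            f"unknown decarboxylation enzyme {keep!r}; choose from {DECARBOXYLASES}")
    work = two_cell.copy()
    for label in DECARBOXYLASES:
        if label == keep:
            continue
        for rid in registry.ids(label):
            work.require_reaction(rid).bounds = (0.0, 0.0)
    return work


def knockout_decarboxylation(
    two_cell: TwoCellModel,
    keep: str,
    registry: Optional[EnzymeRegistry] = None,
    photorespiration_ratio: float = 1.0 / 3.0,
) -> FluxDistribution:
    """C4 mode with a single decarboxylation enzyme available.

    The two other enzymes are bounded to zero in both cells; the native
    Rubisco ratio is pinned (default 1:3, the stressed condition) and the
    solve adds photorespiration minimisation between the phloem optimum
    and the parsimony stage.
    """
    from .two_cell import set_native_photorespiration

    registry = registry or default_registry(two_cell)
    work = _apply_knockout(two_cell, keep, registry)
    set_native_photorespiration(work, photorespiration_ratio)
    objectives = two_cell_objectives(work, registry, minimize_photorespiration=True)
    return lexicographic_solve(work, objectives)


def transport_fva(
    two_cell: TwoCellModel,
    keep: Optional[str] = None,
    deviation_fraction: float = 0.015,
    registry: Optional[EnzymeRegistry] = None,
    photorespiration_ratio: float = 1.0 / 3.0,
) -> FVAResult:
    """Variability of the intercellular transporters in the near-optimal
    space (positive flux: mesophyll -> bundle sheath)."""
    from .two_cell import set_native_photorespiration

    registry = registry or default_registry(two_cell)
    work = (_apply_knockout(two_cell, keep, registry) if keep
            else two_cell.copy())
    set_native_photorespiration(work, photorespiration_ratio)
    objectives = two_cell_objectives(work, registry, minimize_photorespiration=True)
    rids = [r.id for r in work.interface_reactions()]
    return run_fva(work, objectives, reactions=rids,
                   deviation_fraction=deviation_fraction)


def light_scan(
    two_cell: TwoCellModel,
    totals: Optional[Sequence[float]] = None,
    ratios: Optional[Sequence[float]] = None,
    registry: Optional[EnzymeRegistry] = None,
) -> ScanResult:
    """Grid over total PPFD and its bundle-sheath : mesophyll distribution.

    The grid deliberately explores distribution ratios up to 2, so the
    anatomical bundle-sheath <= mesophyll ordering is released and the
    exact ratio pinned instead.  Decarboxylase activities are additionally
    reported relative to the CO2 uptake rate.
    """
    totals = np.asarray(
        totals if totals is not None else np.arange(0.0, 1001.0, 50.0), dtype=float)
    ratios = np.asarray(
        ratios if ratios is not None else np.round(np.arange(0.1, 2.01, 0.1), 10),
        dtype=float)
    registry = registry or default_registry(two_cell)
    work = two_cell.copy()
    rows = []
    for total in totals:
        for rho in ratios:
            set_two_cell_bounds(work, ppfd_total=float(total),
                                ppfd_ratio_b_over_m=float(rho),
                                enforce_ordering=False)
            objectives = two_cell_objectives(work, registry,
                                             minimize_photorespiration=True)
            sol = lexicographic_solve(work, objectives)
            rec = {"ppfd_total": float(total), "ppfd_ratio_b_over_m": float(rho)}
            rec.update(extract_features(work, sol, registry))
            if sol.optimal:
                rec.update(decarboxylase_shares(rec))
            rows.append(rec)
    return ScanResult(axes={"ppfd_total": totals, "ppfd_ratio_b_over_m": ratios},
                      table=pd.DataFrame(rows))


_NUTRIENT_MODES = {"NO3", "H2O", "CO2"}


def limitation_scan(
    two_cell: TwoCellModel,
    nutrient: str,
    grid: Sequence[float],
    registry: Optional[EnzymeRegistry] = None,
) -> ScanResult:
    """Cap the uptake of one resource and trace phloem output and the
    decarboxylase proportions.

    NO3 and H2O caps bound the summed import of both cells (imports stay
    individually reversible for water, so only net uptake is limited);
    CO2 caps the mesophyll import, the bundle sheath's being zero already.
    """
    if nutrient not in _NUTRIENT_MODES:
        raise KeyError(f"unknown nutrient {nutrient!r}; choose from {sorted(_NUTRIENT_MODES)}")
    registry = registry or default_registry(two_cell)
    work = two_cell.copy()
    m, b = work.prefixes
    rows = []
    for value in grid:
        value = float(value)
        if nutrient == "CO2":
            work.require_reaction(f"{m}_Im_CO2").bounds = (0.0, value)
        else:
            work.set_coupling(LinearCoupling(
                f"{nutrient}_cap",
                {f"{m}_Im_{nutrient}": 1.0, f"{b}_Im_{nutrient}": 1.0},
                None, value))
        objectives = two_cell_objectives(work, registry,
                                         minimize_photorespiration=True)
        sol = lexicographic_solve(work, objectives)
        rec = {"bound": value}
        rec.update(extract_features(work, sol, registry))
        if sol.optimal:
            rec.update(decarboxylase_shares(rec))
        rows.append(rec)
    return ScanResult(axes={"bound": np.asarray(grid, dtype=float)},
                      table=pd.DataFrame(rows), meta={"nutrient": nutrient})


def transport_ratio_scan(
    two_cell: TwoCellModel,
    asp_mal_ratios: Sequence[float],
    registry: Optional[EnzymeRegistry] = None,
) -> ScanResult:
    """Pin the aspartate : malate intercellular transport ratio.

    The constraint is the two-sided linear form ``v_Asp - r v_Mal = 0``,
    which stays well-posed when either flux is zero.
    """
    registry = registry or default_registry(two_cell)
    work = two_cell.copy()
    for rid in ("[MB]_Asp", "[MB]_Mal"):
        work.require_reaction(rid)
    rows = []
    for r in asp_mal_ratios:
        work.set_ratio_constraint(FluxRatioConstraint("[MB]_Asp", "[MB]_Mal", float(r)))
        objectives = two_cell_objectives(work, registry,
                                         minimize_photorespiration=True)
        sol = lexicographic_solve(work, objectives)
        rec = {"asp_mal_ratio": float(r)}
        rec.update(extract_features(work, sol, registry))
        if sol.optimal:
            rec.update(decarboxylase_shares(rec))
        rows.append(rec)
    return ScanResult(axes={"asp_mal_ratio": np.asarray(asp_mal_ratios, dtype=float)},
                      table=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# energy accounting
# ---------------------------------------------------------------------------

_COFACTORS = {"ATP", "NADPH", "NADH"}


def _subsystem_map(model: MetabolicModel) -> Dict[str, str]:
    mapping: Dict[str, str] = {}
    for grp in model.cobra.groups:
        for member in grp.members:
            mapping[member.id] = grp.name or grp.id
    return mapping


def _fallback_subsystem(reaction_id: str) -> str:
    from .model_core import split_cell_prefix

    _, base = split_cell_prefix(reaction_id)
    if base.startswith("NGAM"):
        return "maintenance"
    if base.startswith("Sink_H"):
        return "proton buffer"
    if reaction_id.startswith("[MB]"):
        return "intercellular transport"
    return "unassigned"


def energy_accounting(
    model: MetabolicModel,
    flux: FluxDistribution,
    cofactor: str = "ATP",
) -> EnergyAccount:
    """Attribute a cofactor's production and consumption to subsystems.

    For every reaction the net stoichiometric coefficient of the cofactor
    species (summed over compartments and cells) is multiplied by the
    reaction's flux; positive rates are production, negative consumption.
    Shares are percentages of the respective totals.
    """
    from .model_core import split_cell_prefix

    if cofactor not in _COFACTORS:
        raise KeyError(f"unknown cofactor {cofactor!r}; choose from {sorted(_COFACTORS)}")
    species = [
        met for met in model.cobra.metabolites
        if split_cell_prefix(met.id)[1].rsplit("_", 1)[0] == cofactor
    ]
    if not species:
        raise KeyError(f"no {cofactor} species in model")
    subsystems = _subsystem_map(model)
    prod: Dict[str, float] = {}
    cons: Dict[str, float] = {}
    for rxn in model.cobra.reactions:
        net = sum(rxn.metabolites.get(met, 0.0) for met in species)
        if net == 0:
            continue
        rate = net * flux.get(rxn.id)
        if abs(rate) < FLUX_EPS:
            continue
        sub = subsystems.get(rxn.id) or _fallback_subsystem(rxn.id)
        if rate > 0:
            prod[sub] = prod.get(sub, 0.0) + rate
        else:
            cons[sub] = cons.get(sub, 0.0) - rate
    total_prod = sum(prod.values())
    total_cons = sum(cons.values())
    producers = pd.Series(
        {k: 100.0 * v / total_prod for k, v in prod.items()}).sort_values(
            ascending=False) if total_prod else pd.Series(dtype=float)
    consumers = pd.Series(
        {k: 100.0 * v / total_cons for k, v in cons.items()}).sort_values(
            ascending=False) if total_cons else pd.Series(dtype=float)
    return EnergyAccount(cofactor=cofactor, producers=producers,
                         consumers=consumers, total_production=total_prod,
                         total_consumption=total_cons)


# ---------------------------------------------------------------------------
# one-cell linearity probe
# ---------------------------------------------------------------------------

def linearity_probe(
    one_cell: MetabolicModel,
    axis: str,
    grid: Sequence[float],
    breakpoint_slope_fraction: float = 0.01,
) -> ScanResult:
    """Phloem output as the CO2 or photon import bound sweeps a grid.

    Reports the output per grid point and detects the saturation
    breakpoint: the first grid value where the local slope falls below
    ``breakpoint_slope_fraction`` of the initial slope (carbon limitation
    taking over from light limitation, or vice versa).
    """
    targets = {"CO2": "Im_CO2", "PPFD": "Im_hnu"}
    if axis not in targets:
        raise KeyError(f"axis must be one of {sorted(targets)}, got {axis!r}")
    rxn = one_cell.require_reaction(targets[axis])
    objective = Objective({"Ex_Suc": 1.0, "Ex_AA": 1.0}, "max", "phloem")
    old_bounds = rxn.bounds
    rows = []
    try:
        for value in grid:
            rxn.bounds = (0.0, float(value))
            sol = lexicographic_solve(one_cell, [objective])
            rows.append({
                "bound": float(value),
                "phloem": sol.objective_value if sol.optimal else float("nan"),
                "co2_uptake": sol.get("Im_CO2") if sol.optimal else float("nan"),
                "status": sol.status,
            })
    finally:
        rxn.bounds = old_bounds
    table = pd.DataFrame(rows)
    meta: Dict[str, object] = {"axis": axis, "breakpoint": None}
    ok = table[table["status"] == "optimal"]
    if len(ok) >= 3:
        x = ok["bound"].to_numpy()
        y = ok["phloem"].to_numpy()
        slopes = np.diff(y) / np.where(np.diff(x) == 0, np.nan, np.diff(x))
        if np.isfinite(slopes[0]) and slopes[0] > 0:
            below = np.nonzero(slopes < breakpoint_slope_fraction * slopes[0])[0]
            if len(below):
                meta["breakpoint"] = float(x[below[0]])
            seg = slice(0, (below[0] + 1) if len(below) else len(x))
            xs, ys = x[seg], y[seg]
            if len(xs) >= 3 and np.ptp(ys) > 0:
                fit = np.polyfit(xs, ys, 1)
                resid = ys - np.polyval(fit, xs)
                meta["r_squared_linear_segment"] = float(
                    1.0 - resid.var() / ys.var())
    return ScanResult(axes={"bound": np.asarray(grid, dtype=float)},
                      table=table, meta=meta)
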