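"""Linear-programming machinery: FBA, parsimonious FBA, lexicographic
multi-objective solving and flux variability analysis.

All solves share one code path: the model's declarative ratio constraints
and couplings are materialised as extra zero-rows/budget-rows of the LP,
objectives are optimised stage by stage with each optimum locked in before
the next stage runs, and (optionally) the total absolute flux
``sum_i |v_i|`` is minimised last.  Absolute values come for free because
the underlying optlang formulation already splits every reaction into a
non-negative forward and reverse variable; reported fluxes are the
recombined net values.

The solver (GLPK through optlang) is deterministic, so identical inputs
give identical flux distributions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from optlang.symbolics import Zero

from .model_core import (
    FluxRatioConstraint,
    LinearCoupling,
    MetabolicModel,
    PhotorespirationSpec,
)

#: Relative tolerance with which a finished stage's optimum is held fixed
#: while later stages run.
STAGE_TOLERANCE = 1e-6


@dataclass(frozen=True)
class Objective:
    """Linear objective ``direction sum_i w_i v_i`` over named reactions."""

    terms: Mapping[str, float]
    direction: str = "max"
    name: str = ""

    def __post_init__(self) -> None:
        if not self.terms:
            raise ValueError("objective needs at least one term")
        if self.direction not in ("max", "min"):
            raise ValueError(f"direction must be 'max' or 'min', got {self.direction!r}")

    def label(self) -> str:
        return self.name or "+".join(sorted(self.terms))


@dataclass
class FluxDistribution:
    """One steady-state solution: net flux per reaction plus diagnostics."""

    fluxes: pd.Series
    objective_value: Optional[float]
    status: str
    total_abs_flux: Optional[float] = None
    stage_values: Tuple[float, ...] = ()

    def __getitem__(self, reaction_id: str) -> float:
        return float(self.fluxes[reaction_id])

    def get(self, reaction_id: str, default: float = 0.0) -> float:
        if reaction_id in self.fluxes.index:
            return float(self.fluxes[reaction_id])
        return default

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def to_tsv(self, path: str) -> None:
        df = self.fluxes.rename("flux").rename_axis("reaction").reset_index()
        df.to_csv(path, sep="\t", index=False)


@dataclass
class FVAResult:
    """Per-reaction flux ranges inside the near-optimal space."""

    ranges: pd.DataFrame  # index: reaction id; columns: minimum, maximum
    deviation_fraction: float
    context: str = ""

    def __post_init__(self) -> None:
        bad = self.ranges[self.ranges["minimum"] > self.ranges["maximum"] + 1e-9]
        if len(bad):
            raise ValueError(f"FVA intervals inverted for {list(bad.index)}")

    def interval(self, reaction_id: str) -> Tuple[float, float]:
        row = self.ranges.loc[reaction_id]
        return float(row["minimum"]), float(row["maximum"])

    def to_tsv(self, path: str) -> None:
        self.ranges.rename_axis("reaction").reset_index().to_csv(
            path, sep="\t", index=False
        )


# ---------------------------------------------------------------------------
# constraint materialisation
# ---------------------------------------------------------------------------

def _flux_expression(model: MetabolicModel, terms: Mapping[str, float]):
    expr = Zero
    for rid, weight in terms.items():
        expr = expr + float(weight) * model.require_reaction(rid).flux_expression
    return expr


def _install_declared_constraints(model: MetabolicModel) -> list:
    cm = model.cobra
    handles = []
    for i, rc in enumerate(model.ratio_constraints):
        expr = _flux_expression(model, rc.coefficients())
        handles.append(cm.problem.Constraint(
            expr, lb=0.0, ub=0.0, name=f"__c4leaf_ratio_{i}"))
    for i, cp in enumerate(model.couplings):
        expr = _flux_expression(model, cp.coefficients)
        handles.append(cm.problem.Constraint(
            expr, lb=cp.lower, ub=cp.upper, name=f"__c4leaf_coupling_{i}"))
    if handles:
        cm.add_cons_vars(handles)
        cm.solver.update()
    return handles


def _parsimony_coefficients(cm) -> Dict:
    coeffs = {}
    for rxn in cm.reactions:
        coeffs[rxn.forward_variable] = 1.0
        coeffs[rxn.reverse_variable] = 1.0
    return coeffs


class _SolveContext:
    """Installs declared constraints and restores the model on exit."""

    def __init__(self, model: MetabolicModel):
        self.model = model
        self.cm = model.cobra
        self.handles: list = []
        self.extra: list = []

    def __enter__(self) -> "_SolveContext":
        cm = self.cm
        self._old_expr = cm.objective.expression
        self._old_dir = cm.objective.direction
        self.handles = _install_declared_constraints(self.model)
        return self

    def __exit__(self, *exc) -> None:
        cm = self.cm
        if self.handles or self.extra:
            cm.remove_cons_vars(self.handles + self.extra)
        cm.objective = cm.problem.Objective(self._old_expr, direction=self._old_dir)
        cm.solver.update()

    # -- staged optimisation ------------------------------------------------
    def optimize(self, expr, direction: str) -> Tuple[float, str]:
        cm = self.cm
        cm.objective = cm.problem.Objective(expr, direction=direction, sloppy=True)
        value = cm.slim_optimize()
        return value, cm.solver.status

    def lock(self, expr, value: float, direction: str,
             tolerance: float = STAGE_TOLERANCE) -> None:
        tol = tolerance * max(1.0, abs(value))
        if direction == "max":
            c = self.cm.problem.Constraint(
                expr, lb=value - tol, name=f"__c4leaf_stage_{len(self.extra)}")
        else:
            c = self.cm.problem.Constraint(
                expr, ub=value + tol, name=f"__c4leaf_stage_{len(self.extra)}")
        self.extra.append(c)
        self.cm.add_cons_vars([c])
        self.cm.solver.update()

    def minimize_total_flux(self) -> Tuple[float, str]:
        cm = self.cm
        cm.objective = cm.problem.Objective(Zero, direction="min", sloppy=True)
        cm.solver.update()
        cm.objective.set_linear_coefficients(_parsimony_coefficients(cm))
        value = cm.slim_optimize()
        return value, cm.solver.status

    def fluxes(self) -> pd.Series:
        return pd.Series(
            {r.id: r.flux for r in self.cm.reactions}, dtype=float, name="flux"
        )


# ---------------------------------------------------------------------------
# public solving API
# ---------------------------------------------------------------------------

def lexicographic_solve(
    model: MetabolicModel,
    objectives: Sequence[Objective],
    final_parsimony: bool = True,
    stage_tolerance: float = STAGE_TOLERANCE,
) -> FluxDistribution:
    """Optimise objectives in order, each subject to all previous optima.

    With ``final_parsimony`` the total absolute flux is minimised last,
    which resolves the degeneracy of alternate optima the way a resource-
    efficient cell would.  A single objective plus parsimony is exactly
    parsimonious FBA.  Infeasibility at any stage is reported in the
    status, naming the failing stage; no fluxes are fabricated.
    """
    if not objectives and not final_parsimony:
        raise ValueError("need at least one objective or final parsimony")
    stage_values: List[float] = []
    with _SolveContext(model) as ctx:
        for i, obj in enumerate(objectives):
            expr = _flux_expression(model, obj.terms)
            direction = "max" if obj.direction == "max" else "min"
            value, status = ctx.optimize(expr, direction)
            if not math.isfinite(value):
                return FluxDistribution(
                    fluxes=pd.Series(dtype=float),
                    objective_value=None,
                    status=f"{status} (stage {i}: {obj.label()})",
                    stage_values=tuple(stage_values),
                )
            stage_values.append(value)
            ctx.lock(expr, value, direction, stage_tolerance)
        if final_parsimony:
            total, status = ctx.minimize_total_flux()
            if not math.isfinite(total):
                return FluxDistribution(
                    fluxes=pd.Series(dtype=float), objective_value=None,
                    status=f"{status} (stage {len(objectives)}: parsimony)",
                    stage_values=tuple(stage_values),
                )
        fluxes = ctx.fluxes()
        if not final_parsimony:
            total = float(fluxes.abs().sum())
    return FluxDistribution(
        fluxes=fluxes,
        objective_value=stage_values[0] if stage_values else total,
        status="optimal",
        total_abs_flux=float(total),
        stage_values=tuple(stage_values),
    )


def solve_fba(model: MetabolicModel, objective: Objective) -> FluxDistribution:
    """Plain FBA: one linear objective, no degeneracy resolution."""
    return lexicographic_solve(model, [objective], final_parsimony=False)


def solve_pfba(model: MetabolicModel, objective: Objective) -> FluxDistribution:
    """Parsimonious FBA: FBA optimum held fixed, then ``sum |v|`` minimised."""
    return lexicographic_solve(model, [objective], final_parsimony=True)


def run_fva(
    model: MetabolicModel,
    objectives: Sequence[Objective],
    reactions: Optional[Sequence[str]] = None,
    deviation_fraction: float = 0.015,
    parsimony_context: bool = True,
    stage_tolerance: float = STAGE_TOLERANCE,
) -> FVAResult:
    """Flux variability inside the near-optimal space.

    The context objectives are optimised and locked exactly as in
    :func:`lexicographic_solve`; with ``parsimony_context`` the minimal
    total flux ``T`` is computed and the budget ``sum |v| <= (1 + d) T``
    added before each queried reaction is minimised and maximised.
    """
    if deviation_fraction < 0:
        raise ValueError("deviation_fraction must be >= 0")
    rids = list(reactions) if reactions is not None else [
        r.id for r in model.cobra.reactions
    ]
    rows = []
    with _SolveContext(model) as ctx:
        for i, obj in enumerate(objectives):
            expr = _flux_expression(model, obj.terms)
            direction = "max" if obj.direction == "max" else "min"
            value, status = ctx.optimize(expr, direction)
            if not math.isfinite(value):
                raise RuntimeError(
                    f"FVA context infeasible at stage {i} ({obj.label()}): {status}"
                )
            ctx.lock(expr, value, direction, stage_tolerance)
        if parsimony_context:
            total, status = ctx.minimize_total_flux()
            if not math.isfinite(total):
                raise RuntimeError(f"FVA parsimony context failed: {status}")
            budget = ctx.cm.problem.Constraint(
                Zero, ub=(1.0 + deviation_fraction) * total, name="__c4leaf_budget")
            ctx.extra.append(budget)
            ctx.cm.add_cons_vars([budget])
            ctx.cm.solver.update()
            budget.set_linear_coefficients(_parsimony_coefficients(ctx.cm))
        for rid in rids:
            expr = model.require_reaction(rid).flux_expression
            lo, status = ctx.optimize(expr, "min")
            if not math.isfinite(lo):
                raise RuntimeError(f"FVA minimisation failed for {rid}: {status}")
            hi, status = ctx.optimize(expr, "max")
            if not math.isfinite(hi):
                raise RuntimeError(f"FVA maximisation failed for {rid}: {status}")
            rows.append((rid, lo, hi))
    ranges = pd.DataFrame(rows, columns=["reaction", "minimum", "maximum"])
    ranges = ranges.set_index("reaction")
    context = " -> ".join(o.label() for o in objectives)
    if parsimony_context:
        context += f" -> total flux within {deviation_fraction:.2%} of minimum"
    return FVAResult(ranges=ranges, deviation_fraction=deviation_fraction,
                     context=context)


# ---------------------------------------------------------------------------
# constraint installation helpers
# ---------------------------------------------------------------------------

def add_ratio_constraint(
    model: MetabolicModel, constraint: FluxRatioConstraint
) -> MetabolicModel:
    """Register ``v_a = r * v_b``; honoured by every subsequent solve."""
    model.add_ratio_constraint(constraint)
    return model


def fix_photorespiration(
    model: MetabolicModel,
    spec: Union[PhotorespirationSpec, float],
    rbo_id: str = "RBO_h",
    rbc_id: str = "RBC_h",
) -> MetabolicModel:
    """Pin the oxygenation:carboxylation ratio of one Rubisco population.

    Replaces any previous ratio on the same reaction pair, so scans can
    sweep the ratio by calling this repeatedly.  The CCM-dependent Rubisco
    of a two-cell model must never be passed here; it carboxylates freely.
    """
    ratio = spec.ratio if isinstance(spec, PhotorespirationSpec) else float(spec)
    if ratio < 0:
        raise ValueError(f"photorespiration ratio must be >= 0, got {ratio}")
    model.set_ratio_constraint(FluxRatioConstraint(rbo_id, rbc_id, ratio))
    return model


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def steady_state_residual(model: MetabolicModel, flux: FluxDistribution) -> float:
    """Max row-wise ``|S . v|``; should vanish for any optimal solution."""
    from cobra.util.array import create_stoichiometric_matrix

    S = create_stoichiometric_matrix(model.cobra)
    v = flux.fluxes.reindex([r.id for r in model.cobra.reactions]).to_numpy()
    return float(np.abs(S @ v).max())


def ratio_residuals(model: MetabolicModel, flux: FluxDistribution) -> pd.Series:
    """Residual ``v_a - r v_b`` of every declared ratio constraint."""
    vals = {}
    for rc in model.ratio_constraints:
        vals[f"{rc.reaction_a}:{rc.reaction_b}"] = (
            flux.get(rc.reaction_a) - rc.ratio * flux.get(rc.reaction_b)
        )
    return pd.Series(vals, dtype=float)


def export_lp(model: MetabolicModel, path: str) -> None:
    """Dump the LP (with declared constraints installed) for audit."""
    with _SolveContext(model) as ctx:
        lp = getattr(ctx.cm.solver, "to_lp", None)
        text = lp() if callable(lp) else str(ctx.cm.solver)
    with open(path, "w") as fh:
        fh.write(text)
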