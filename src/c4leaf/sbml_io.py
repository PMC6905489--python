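"""SBML Level 3 (FBC) reading and writing.

cobrapy handles the FBC core (species, reactions, bounds, objective,
groups); the declarative flux couplings that SBML-FBC cannot express are
carried in a model-level annotation element under the namespace
``https://schemas.c4leaf.dev/constraints/1``:

.. code-block:: xml

    <c4leaf:modelConstraints xmlns:c4leaf="https://schemas.c4leaf.dev/constraints/1">
      <c4leaf:ratioConstraint reactionA="Ex_Suc" reactionB="Ex_AA" ratio="2.2"/>
      <c4leaf:coupling name="ppfd_total" lower="0" upper="1000">
        <c4leaf:term reaction="[M]_Im_hnu" coefficient="1"/>
      </c4leaf:coupling>
      <c4leaf:meta key="cell_prefixes" value="[M],[B]"/>
    </c4leaf:modelConstraints>
"""

from __future__ import annotations

import logging
import math
import warnings
from typing import List, Optional
from xml.etree import ElementTree as ET
from xml.sax.saxutils import escape, quoteattr

import cobra
import libsbml

from .model_core import FluxRatioConstraint, LinearCoupling, MetabolicModel

logger = logging.getLogger(__name__)

NS = "https://schemas.c4leaf.dev/constraints/1"


def _constraints_xml(model: MetabolicModel) -> str:
    parts: List[str] = [f'<c4leaf:modelConstraints xmlns:c4leaf="{NS}">']
    for rc in model.ratio_constraints:
        parts.append(
            f"  <c4leaf:ratioConstraint reactionA={quoteattr(rc.reaction_a)} "
            f"reactionB={quoteattr(rc.reaction_b)} ratio={quoteattr(repr(rc.ratio))}/>"
        )
    for cp in model.couplings:
        lo = "-inf" if cp.lower is None else repr(cp.lower)
        hi = "inf" if cp.upper is None else repr(cp.upper)
        parts.append(
            f"  <c4leaf:coupling name={quoteattr(cp.name)} "
            f"lower={quoteattr(lo)} upper={quoteattr(hi)}>"
        )
        for rid, coef in cp.coefficients.items():
            parts.append(
                f"    <c4leaf:term reaction={quoteattr(rid)} "
                f"coefficient={quoteattr(repr(float(coef)))}/>"
            )
        parts.append("  </c4leaf:coupling>")
    for key, value in model.annotations.items():
        parts.append(
            f"  <c4leaf:meta key={quoteattr(str(key))} value={quoteattr(str(value))}/>"
        )
    parts.append("</c4leaf:modelConstraints>")
    return "\n".join(parts)


def write_model(model: MetabolicModel, path: str) -> None:
    """Serialise to SBML L3+FBC; refuses a model violating its invariants."""
    model.validate()
    cobra.io.write_sbml_model(model.cobra, path)
    if not (model.ratio_constraints or model.couplings or model.annotations):
        return
    doc = libsbml.readSBMLFromFile(path)
    sbml_model = doc.getModel()
    code = sbml_model.appendAnnotation(_constraints_xml(model))
    if code != libsbml.LIBSBML_OPERATION_SUCCESS:  # pragma: no cover
        raise RuntimeError(f"could not append constraint annotation (code {code})")
    libsbml.writeSBMLToFile(doc, path)


def _parse_annotation(sbml_model: libsbml.Model, model: MetabolicModel) -> None:
    raw = sbml_model.getAnnotationString()
    if not raw or "modelConstraints" not in raw:
        return
    root = ET.fromstring(raw)
    block = root.find(f".//{{{NS}}}modelConstraints")
    if block is None:
        return
    for el in block.findall(f"{{{NS}}}ratioConstraint"):
        model.ratio_constraints.append(FluxRatioConstraint(
            reaction_a=el.get("reactionA"),
            reaction_b=el.get("reactionB"),
            ratio=float(el.get("ratio")),
        ))
    for el in block.findall(f"{{{NS}}}coupling"):
        lo, hi = el.get("lower"), el.get("upper")
        model.couplings.append(LinearCoupling(
            name=el.get("name"),
            coefficients={
                t.get("reaction"): float(t.get("coefficient"))
                for t in el.findall(f"{{{NS}}}term")
            },
            lower=None if lo == "-inf" else float(lo),
            upper=None if hi == "inf" else float(hi),
        ))
    for el in block.findall(f"{{{NS}}}meta"):
        model.annotations[el.get("key")] = el.get("value")


def read_model(path: str) -> MetabolicModel:
    """Load an SBML L3+FBC document into a :class:`MetabolicModel`.

    Malformed documents raise with the offending element named; reactions
    lacking FBC flux bounds raise listing their ids; a missing objective is
    tolerated with a warning.
    """
    doc = libsbml.readSBMLFromFile(path)
    for i in range(doc.getNumErrors()):
        err = doc.getError(i)
        if err.getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
            raise ValueError(
                f"malformed SBML in {path}: line {err.getLine()}: {err.getMessage()}"
            )
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ValueError(f"malformed SBML in {path}: document holds no <model> element")
    missing_bounds = []
    for i in range(sbml_model.getNumReactions()):
        rxn = sbml_model.getReaction(i)
        fbc = rxn.getPlugin("fbc")
        if fbc is not None and (
            not fbc.isSetLowerFluxBound() or not fbc.isSetUpperFluxBound()
        ):
            missing_bounds.append(rxn.getId())
    if missing_bounds:
        raise ValueError(f"reactions lack flux bounds: {missing_bounds}")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cobra_model = cobra.io.read_sbml_model(path)
    # cobra reads numeric note values back as strings
    for met in cobra_model.metabolites:
        for key in ("carbon_count", "nitrogen_count"):
            if key in met.notes:
                met.notes[key] = float(met.notes[key])
    model = MetabolicModel(cobra_model)
    _parse_annotation(sbml_model, model)
    from cobra.util.solver import linear_reaction_coefficients

    if not linear_reaction_coefficients(cobra_model):
        warnings.warn(f"{path}: model declares no objective", stacklevel=2)
    logger.info(
        "read %s: %d metabolites, %d reactions, %d ratio constraints",
        path, len(cobra_model.metabolites), len(cobra_model.reactions),
        len(model.ratio_constraints),
    )
    return model
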