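"""Shared fixtures: the bundled leaf models and hand-enumerable LP toys."""

from __future__ import annotations

import cobra
import pytest
from cobra import Metabolite, Reaction

from c4leaf import (
    MetabolicModel,
    Objective,
    build_one_cell_model,
    build_two_cell_model,
)

PHLOEM = Objective({"Ex_Suc": 1.0, "Ex_AA": 1.0}, "max", "phloem")


@pytest.fixture(scope="session")
def one_cell() -> MetabolicModel:
    return build_one_cell_model()


@pytest.fixture(scope="session")
def two_cell():
    return build_two_cell_model()


@pytest.fixture()
def one_cell_copy(one_cell) -> MetabolicModel:
    return one_cell.copy()


@pytest.fixture()
def two_cell_copy(two_cell):
    return two_cell.copy()


# ---------------------------------------------------------------------------
# hand-enumerable toys
# ---------------------------------------------------------------------------

def _toy(reactions) -> MetabolicModel:
    """reactions: list of (id, {met: coef}, lb, ub); mets live in 'c'."""
    cm = cobra.Model("toy")
    mets = {}

    def met(mid):
        if mid not in mets:
            mets[mid] = Metabolite(mid, compartment="c")
        return mets[mid]

    objs = []
    for rid, stoich, lb, ub in reactions:
        rxn = Reaction(rid, lower_bound=lb, upper_bound=ub)
        rxn.add_metabolites({met(m): c for m, c in stoich.items()})
        objs.append(rxn)
    cm.add_reactions(objs)
    return MetabolicModel(cm)


@pytest.fixture()
def toy_chain() -> MetabolicModel:
    """import(<=5) -> A -> B -> export; capacity bound 5."""
    return _toy([
        ("imp", {"A": 1}, 0, 5),
        ("conv", {"A": -1, "B": 1}, 0, 1000),
        ("exp", {"B": -1}, 0, 1000),
    ])


@pytest.fixture()
def toy_diamond() -> MetabolicModel:
    """Two routes of equal capacity: 1 reaction vs 3 reactions."""
    return _toy([
        ("imp", {"S": 1}, 0, 10),
        ("direct", {"S": -1, "P": 1}, 0, 1000),
        ("long1", {"S": -1, "X": 1}, 0, 1000),
        ("long2", {"X": -1, "Y": 1}, 0, 1000),
        ("long3", {"Y": -1, "P": 1}, 0, 1000),
        ("exp", {"P": -1}, 0, 1000),
    ])


@pytest.fixture()
def toy_loop() -> MetabolicModel:
    """Chain with a feasible internal cycle B -> C -> B."""
    return _toy([
        ("imp", {"A": 1}, 0, 5),
        ("conv", {"A": -1, "B": 1}, 0, 1000),
        ("cyc1", {"B": -1, "C": 1}, 0, 1000),
        ("cyc2", {"C": -1, "B": 1}, 0, 1000),
        ("exp", {"B": -1}, 0, 1000),
    ])


@pytest.fixture()
def toy_shuttles() -> MetabolicModel:
    """Two interchangeable transport routes of identical cost."""
    return _toy([
        ("imp", {"S": 1}, 0, 10),
        ("shuttle_mal", {"S": -1, "P": 1}, 0, 1000),
        ("shuttle_asp", {"S": -1, "P": 1}, 0, 1000),
        ("exp", {"P": -1}, 0, 1000),
    ])
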