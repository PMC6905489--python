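"""Run configuration, experiment orchestration and report assembly."""

from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np

import cobra

from . import __version__
from .experiments import (
    DECARBOXYLASES,
    default_registry,
    energy_accounting,
    extract_features,
    knockout_decarboxylation,
    light_scan,
    limitation_scan,
    linearity_probe,
    photorespiration_scan,
    transport_fva,
    transport_ratio_scan,
    two_cell_objectives,
)
from .fba_engine import Objective, lexicographic_solve
from .sbml_io import read_model, write_model
from .synthetic_network import FixtureConfig, build_one_cell_model
from .two_cell import compose_two_cell

logger = logging.getLogger(__name__)

KNOWN_EXPERIMENTS = (
    "one-cell", "scan-pr", "scan-light", "knockout", "fva-transport",
    "scan-limit", "scan-ratio", "energy", "linearity",
)

#: Experiments that operate on the composed two-cell model.
_TWO_CELL_EXPERIMENTS = {
    "scan-pr", "scan-light", "knockout", "fva-transport", "scan-limit",
    "scan-ratio",
}


@dataclass
class RunConfig:
    """What to run and on which model; all randomness flows from ``seed``."""

    model_source: str = "fixture"  # "fixture" or a path to an SBML file
    curate: bool = True
    compose: bool = True
    experiments: Sequence[str] = ("one-cell",)
    output_dir: str = "c4leaf_results"
    seed: int = 0
    grids: Mapping[str, Sequence[float]] = field(default_factory=dict)
    limit_nutrient: str = "NO3"
    knockout_keep: Sequence[str] = DECARBOXYLASES

    def validate(self) -> None:
        unknown = set(self.experiments) - set(KNOWN_EXPERIMENTS)
        if unknown:
            raise ValueError(f"unknown experiments {sorted(unknown)}; "
                             f"known: {KNOWN_EXPERIMENTS}")
        if self.model_source != "fixture" and not os.path.exists(self.model_source):
            raise FileNotFoundError(f"model source {self.model_source!r} does not exist")
        needs_two_cell = _TWO_CELL_EXPERIMENTS & set(self.experiments)
        if needs_two_cell and not self.compose:
            raise ValueError(
                f"experiments {sorted(needs_two_cell)} require the two-cell "
                f"composition; set compose=true")


def _grid(config: RunConfig, name: str, default: Sequence[float]) -> np.ndarray:
    return np.asarray(config.grids.get(name, default), dtype=float)


def run(config: RunConfig) -> Dict[str, object]:
    """Execute the selected stages in dependency order.

    Writes one directory per experiment (``scan.tsv`` / ``fluxes.tsv``),
    a machine-readable ``summary.json`` and a ``run.log``; returns the
    summary dict.  Solver failures surface as per-point statuses in the
    scan tables and in the summary.
    """
    config.validate()
    np.random.seed(config.seed % (2 ** 31))
    os.makedirs(config.output_dir, exist_ok=True)
    log_path = os.path.join(config.output_dir, "run.log")
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("c4leaf")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    summary: Dict[str, object] = {
        "package_version": __version__,
        "cobra_version": cobra.__version__,
        "solver": "glpk",
        "seed": config.seed,
        "model_source": config.model_source,
        "experiments": list(config.experiments),
    }
    t0 = time.time()
    try:
        if config.model_source == "fixture":
            one_cell = build_one_cell_model(FixtureConfig(seed=config.seed),
                                            curate=config.curate)
        else:
            one_cell = read_model(config.model_source)
        summary["n_reactions"] = len(one_cell.reactions)
        summary["n_metabolites"] = len(one_cell.metabolites)
        write_model(one_cell, os.path.join(config.output_dir, "one_cell.sbml.xml"))

        phloem = Objective({"Ex_Suc": 1.0, "Ex_AA": 1.0}, "max", "phloem")
        if "one-cell" in config.experiments:
            out = _outdir(config, "one-cell")
            sol = lexicographic_solve(one_cell, [phloem])
            sol.to_tsv(os.path.join(out, "fluxes.tsv"))
            summary["one_cell"] = {
                "status": sol.status,
                "phloem_output": sol.objective_value,
                "co2_uptake": sol.get("Im_CO2"),
                "ppfd": sol.get("Im_hnu"),
                "sucrose_export": sol.get("Ex_Suc"),
                "aa_export": sol.get("Ex_AA"),
                "suc_aa_ratio": (sol.get("Ex_Suc") / sol.get("Ex_AA")
                                 if sol.optimal and sol.get("Ex_AA") else None),
            }

        if "energy" in config.experiments:
            out = _outdir(config, "energy")
            sol = lexicographic_solve(one_cell, [phloem])
            energy = {}
            for cofactor in ("ATP", "NADPH", "NADH"):
                account = energy_accounting(one_cell, sol, cofactor)
                account.producers.rename("percent").rename_axis("subsystem") \
                    .reset_index().to_csv(
                        os.path.join(out, f"{cofactor}_producers.tsv"),
                        sep="\t", index=False)
                account.consumers.rename("percent").rename_axis("subsystem") \
                    .reset_index().to_csv(
                        os.path.join(out, f"{cofactor}_consumers.tsv"),
                        sep="\t", index=False)
                energy[cofactor] = {
                    "top_producer": (account.producers.index[0]
                                     if len(account.producers) else None),
                    "top_producer_percent": (float(account.producers.iloc[0])
                                             if len(account.producers) else None),
                }
            summary["energy"] = energy

        if "linearity" in config.experiments:
            out = _outdir(config, "linearity")
            for axis, default in (("CO2", np.linspace(0, 20, 11)),
                                  ("PPFD", np.linspace(0, 400, 11))):
                probe = linearity_probe(
                    one_cell, axis, _grid(config, f"linearity_{axis}", default))
                probe.to_tsv(os.path.join(out, f"{axis}.tsv"))
                summary[f"linearity_{axis}"] = probe.meta

        if config.compose:
            two_cell = compose_two_cell(one_cell)
            write_model(two_cell, os.path.join(config.output_dir, "two_cell.sbml.xml"))
            registry = default_registry(two_cell)
            summary["n_reactions_two_cell"] = len(two_cell.reactions)

        if "scan-pr" in config.experiments:
            out = _outdir(config, "scan-pr")
            scan = photorespiration_scan(
                two_cell, _grid(config, "photorespiration", np.linspace(0, 1, 21)),
                registry)
            scan.to_tsv(os.path.join(out, "scan.tsv"))
            summary["scan_pr_points"] = len(scan.table)

        if "knockout" in config.experiments:
            out = _outdir(config, "knockout")
            ko_summary = {}
            for keep in config.knockout_keep:
                sol = knockout_decarboxylation(two_cell, keep, registry)
                sol.to_tsv(os.path.join(out, f"fluxes_{keep}.tsv"))
                rec = extract_features(two_cell, sol, registry)
                ko_summary[keep] = {
                    "status": sol.status,
                    "PEPC": rec.get("PEPC"),
                    keep: rec.get(keep),
                }
            summary["knockout"] = ko_summary

        if "fva-transport" in config.experiments:
            out = _outdir(config, "fva-transport")
            for keep in config.knockout_keep:
                fva = transport_fva(two_cell, keep=keep, registry=registry)
                fva.to_tsv(os.path.join(out, f"fva_{keep}.tsv"))
            summary["fva_deviation"] = 0.015

        if "scan-light" in config.experiments:
            out = _outdir(config, "scan-light")
            scan = light_scan(
                two_cell,
                totals=_grid(config, "ppfd_total", np.arange(0, 1001, 50)),
                ratios=_grid(config, "ppfd_ratio", np.round(np.arange(0.1, 2.01, 0.1), 10)),
                registry=registry)
            scan.to_tsv(os.path.join(out, "scan.tsv"))
            summary["scan_light_points"] = len(scan.table)

        if "scan-limit" in config.experiments:
            out = _outdir(config, "scan-limit")
            scan = limitation_scan(
                two_cell, config.limit_nutrient,
                _grid(config, "limit", np.linspace(0, 1, 11)
                      if config.limit_nutrient == "NO3" else np.linspace(0, 40, 11)),
                registry)
            scan.to_tsv(os.path.join(out, "scan.tsv"))
            summary["scan_limit_nutrient"] = config.limit_nutrient

        if "scan-ratio" in config.experiments:
            out = _outdir(config, "scan-ratio")
            scan = transport_ratio_scan(
                two_cell, _grid(config, "asp_mal", np.round(np.arange(0.1, 2.01, 0.1), 10)),
                registry)
            scan.to_tsv(os.path.join(out, "scan.tsv"))
            summary["scan_ratio_points"] = len(scan.table)

        summary["elapsed_seconds"] = round(time.time() - t0, 2)
        with open(os.path.join(config.output_dir, "summary.json"), "w") as fh:
            json.dump(summary, fh, indent=2, default=float)
        logger.info("run complete: %s", summary)
        return summary
    finally:
        root.removeHandler(handler)
        handler.close()


def _outdir(config: RunConfig, experiment: str) -> str:
    path = os.path.join(config.output_dir, experiment)
    os.makedirs(path, exist_ok=True)
    return path
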