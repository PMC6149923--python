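"""YAML configuration for simulation runs.

Example::

    lattice: {n_per_axis: 100, spacing_um: 5.0}
    init: {n_cells: 100, age_max_h: 24.0}
    time: {time_step_h: 0.72, horizon_steps: 100}
    drugs:
      - {name: gefitinib, half_life_h: 48.0, initial_uM: 20.0}
      - {name: rosiglitazone, half_life_h: 3.5, initial_uM: 80.0}
    phenotype:
      lam: 1.0
      c1: 0.124
      c2: 0.218
      theta: [0.1686, 0.0067, 0.0019]
      p_pro: 0.8
      cell_cycle_steps: 24
      apoptosis_duration_steps: 10
    motility: {D_um2_per_h: 10.0, division_radius: 1}
    seed: 7
"""

from __future__ import annotations

from pathlib import Path
from typing import Any, Mapping

import yaml

from .agents import PhenotypeParams
from .engine import SimulationConfig
from .microenvironment import DrugField

__all__ = ["load_config", "config_from_dict", "config_to_dict", "save_config"]


def config_from_dict(raw: Mapping[str, Any]) -> SimulationConfig:
    lattice = raw.get("lattice", {})
    init = raw.get("init", {})
    time = raw.get("time", {})
    motility = raw.get("motility", {})
    phen_raw = dict(raw.get("phenotype", {}))
    if "theta" in phen_raw:
        phen_raw["theta"] = tuple(phen_raw["theta"])
    if "phase_steps" in phen_raw:
        phen_raw["phase_steps"] = tuple(phen_raw["phase_steps"])
    drugs = tuple(
        DrugField(name=d["name"], initial_uM=float(d["initial_uM"]),
                  half_life_h=float(d["half_life_h"]))
        for d in raw.get("drugs", []))
    return SimulationConfig(
        drugs=drugs,
        phenotype=PhenotypeParams(**phen_raw),
        n_per_axis=int(lattice.get("n_per_axis", 100)),
        spacing_um=float(lattice.get("spacing_um", 5.0)),
        n_cells=int(init.get("n_cells", 100)),
        age_max_h=float(init.get("age_max_h", 24.0)),
        time_step_h=float(time.get("time_step_h", 0.72)),
        horizon_steps=int(time.get("horizon_steps", 100)),
        seed=int(raw.get("seed", 0)),
        motility_D=float(motility.get("D_um2_per_h", 10.0)),
        division_radius=int(motility.get("division_radius", 1)),
        snapshot_every=int(raw.get("snapshot_every", 0)),
    )


def load_config(path: str | Path) -> SimulationConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_dict(raw)


def config_to_dict(config: SimulationConfig) -> dict:
    p = config.phenotype
    return {
        "lattice": {"n_per_axis": config.n_per_axis,
                    "spacing_um": config.spacing_um},
        "init": {"n_cells": config.n_cells, "age_max_h": config.age_max_h},
        "time": {"time_step_h": config.time_step_h,
                 "horizon_steps": config.horizon_steps},
        "drugs": [{"name": d.name, "half_life_h": d.half_life_h,
                   "initial_uM": d.initial_uM} for d in config.drugs],
        "phenotype": {"lam": p.lam, "c1": p.c1, "c2": p.c2,
                      "theta": list(p.theta), "p_pro": p.p_pro,
                      "cell_cycle_steps": p.cell_cycle_steps,
                      "apoptosis_duration_steps": p.apoptosis_duration_steps,
                      "phase_steps": list(p.phase_steps)},
        "motility": {"D_um2_per_h": config.motility_D,
                     "division_radius": config.division_radius},
        "seed": config.seed,
        "snapshot_every": config.snapshot_every,
    }


def save_config(config: SimulationConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)
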