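"""Synthetic dose-inhibition tables with known ground truth.

Stands in for the triplicate 30-combination inhibition assays of the
three drug pairs (gefitinib + rosiglitazone, erlotinib + imatinib,
gefitinib + quinacrine) on which the model is calibrated.  Each table
follows the documented stand-in grid — four mixing ratios (4:1, 3:2,
2:3, 1:4) at six total concentrations within the 0-100 uM working
range, plus six single-agent anchor rows — with a smooth linear
dose-mortality surface and truncated Gaussian replicate noise.  The
generating parameters are embedded in the table so recovery tests can
compare estimates to truth.

This generator emulates the structure of the assays, not their
plate-reader mechanics; its dose grid is a documented stand-in, not a
claim about the original experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from .calibration import DoseResponseTable, Simulator

__all__ = [
    "GeneratorSpec", "default_dose_grid", "generate_table",
    "generate_simulator_consistent_table", "default_pair_specs",
    "PAIR_HALF_LIVES",
]

#: elimination half-lives (hours) wired into the default engine configs
PAIR_HALF_LIVES: Dict[str, float] = {
    "gefitinib": 48.0,
    "imatinib": 18.0,
    "rosiglitazone": 3.5,    # reported 3-4 h
    "quinacrine": 228.0,     # reported 5-14 days; midpoint 9.5 d
    "erlotinib": 36.0,
}

#: mixing ratios and total doses of the stand-in grid (uM)
GRID_RATIOS: Tuple[Tuple[int, int], ...] = ((4, 1), (3, 2), (2, 3), (1, 4))
GRID_TOTALS: Tuple[float, ...] = (5.0, 10.0, 20.0, 40.0, 60.0, 80.0)
SINGLE_AGENT_DOSES: Tuple[float, ...] = (10.0, 40.0, 80.0)


def default_dose_grid() -> np.ndarray:
    """The 30-row stand-in dose grid: 4 ratios x 6 totals, plus 3
    single-agent anchors per drug.  All doses lie within 0-100 uM."""
    rows: List[Tuple[float, float]] = []
    for a, b in GRID_RATIOS:
        for total in GRID_TOTALS:
            rows.append((total * a / (a + b), total * b / (a + b)))
    for d in SINGLE_AGENT_DOSES:
        rows.append((d, 0.0))
    for d in SINGLE_AGENT_DOSES:
        rows.append((0.0, d))
    return np.array(rows)


@dataclass
class GeneratorSpec:
    """Ground truth and sampling plan for one synthetic drug pair."""

    label: str
    theta: Tuple[float, float, float]
    c1: float = 0.1
    c2: float = 0.3
    lam: float = 1.0
    dose_grid: np.ndarray = field(default_factory=default_dose_grid)
    replicates: int = 3
    noise_sd: float = 0.03
    seed: int | None = None

    def __post_init__(self) -> None:
        grid = np.asarray(self.dose_grid, dtype=float)
        if grid.ndim != 2 or grid.shape[1] != 2:
            raise ValueError("dose_grid must be (m, 2)")
        if (grid < 0).any() or (grid > 100).any():
            raise ValueError("doses must lie in the 0-100 uM working range")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        self.dose_grid = grid

    @property
    def truth(self) -> dict:
        return dict(theta=tuple(self.theta), c1=self.c1, c2=self.c2,
                    lam=self.lam, noise_sd=self.noise_sd)


def _assemble(spec: GeneratorSpec, means: np.ndarray,
              rng: np.random.Generator) -> DoseResponseTable:
    reps = means[:, None] + rng.normal(0.0, spec.noise_sd,
                                       size=(len(means), spec.replicates))
    reps = np.clip(reps, 0.0, 1.0)
    frame = pd.DataFrame({
        "pair": spec.label,
        "dose1_uM": spec.dose_grid[:, 0],
        "dose2_uM": spec.dose_grid[:, 1],
    })
    for k in range(spec.replicates):
        frame[f"rep{k + 1}"] = reps[:, k]
    return DoseResponseTable(frame, spec.label, truth=spec.truth)


def generate_table(spec: GeneratorSpec) -> DoseResponseTable:
    """Dose-inhibition table from the linear mortality surface.

    Per-row mean inhibition is ``clamp(theta0 + theta1 d1 + theta2 d2,
    0, 1)``; replicates add Gaussian noise truncated to [0, 1].
    Seeded and reproducible.
    """
    t0, t1, t2 = spec.theta
    d = spec.dose_grid
    means = np.clip(t0 + t1 * d[:, 0] + t2 * d[:, 1], 0.0, 1.0)
    rng = np.random.default_rng(spec.seed)
    return _assemble(spec, means, rng)


def generate_simulator_consistent_table(spec: GeneratorSpec,
                                        simulator: Simulator,
                                        ) -> DoseResponseTable:
    """Table whose "experimental" inhibition is the engine's own
    replicate-averaged endpoint mortality at the spec's ground-truth
    parameters (plus replicate noise).

    The simulator callable must carry the spec's theta and the pair's
    half-lives; this closes the loop for recovering ``(c1, c2,
    lambda)`` with the global fit, since a perfect recovery reproduces
    the table up to noise.  Mean mortality can be negative under net
    growth; values are clipped to [0, 1] to stay valid inhibition
    fractions.
    """
    means = np.array([
        simulator(spec.c1, spec.c2, spec.lam, d1, d2)
        for d1, d2 in spec.dose_grid])
    means = np.clip(means, 0.0, 1.0)
    rng = np.random.default_rng(spec.seed)
    return _assemble(spec, means, rng)


def default_pair_specs(seed: int = 0) -> Dict[str, GeneratorSpec]:
    """Three named specs shaped like the study's drug pairs.

    Ground-truth thetas reuse the published local-fit coefficients as
    realistic values; (c1, c2, lambda) reuse the published swarm
    estimates.
    """
    base = [
        GeneratorSpec("gefitinib+rosiglitazone",
                      theta=(0.1686, 0.0067, 0.0019),
                      c1=0.124, c2=0.218, lam=1.0),
        GeneratorSpec("erlotinib+imatinib",
                      theta=(0.1789, 0.0076, 0.0031),
                      c1=0.0081, c2=0.3704, lam=1.0),
        GeneratorSpec("gefitinib+quinacrine",
                      theta=(0.0006, 0.0085, 0.0101),
                      c1=0.2303, c2=0.4722, lam=1.0),
    ]
    rng = np.random.default_rng(seed)
    return {s.label: replace(s, seed=int(rng.integers(2**31)))
            for s in base}


def pair_drug_names(label: str) -> Tuple[str, str]:
    """Split a ``drug1+drug2`` pair label into its drug names."""
    names = label.split("+")
    if len(names) != 2:
        raise ValueError(f"pair label {label!r} is not 'drug1+drug2'")
    return names[0], names[1]
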