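"""Per-cell phenotype rules: apoptosis, proliferation, cycling, quiescence.

Each cell carries an age, a cell-cycle position and a phase.  Every time
step a cell first faces an apoptosis decision that mixes a natural
exponential hazard (Mnrate) with a drug-computed mortality (Mcrate);
survivors either progress through the cell cycle or sit in a reversible
quiescent state and re-test the proliferation rule next step.  A cell
that enters apoptosis occupies its site for a fixed number of steps
before being absorbed.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Tuple

from .microenvironment import Site

__all__ = [
    "Phase", "Cell", "PhenotypeParams",
    "natural_mortality", "computed_mortality",
    "apoptosis_decision", "proliferation_decision", "advance_phase",
]


class Phase(str, enum.Enum):
    """Cell state: four cycle phases plus quiescent and apoptotic."""

    G0G1 = "G0G1"
    S = "S"
    G2 = "G2"
    M = "M"
    QUIESCENT = "quiescent"
    APOPTOTIC = "apoptotic"


# Phase split of the 24-step (17.28 h) cycle: proportions of a canonical
# 24 h mammalian cycle, since only the phase names are constrained.
DEFAULT_PHASE_STEPS: Tuple[int, int, int, int] = (11, 8, 4, 1)  # G0/G1, S, G2, M


@dataclass
class PhenotypeParams:
    """Parameters of the phenotype-switching rules.

    Attributes
    ----------
    lam : float
        Mean apoptosis frequency per hour (hazard of the natural
        mortality rate ``1 - exp(-lam * t)``).
    c1, c2 : float
        Non-negative mixing weights of natural and drug-computed
        mortality in the apoptosis decision.
    theta : (float, float, float)
        Dose-mortality coefficients ``(theta0, theta1, theta2)``:
        intercept plus one linear slope per drug (per uM).
    p_pro : float
        Probability per decision that a resting cell enters the cycle.
    cell_cycle_steps : int
        Length of a full division cycle in time steps (default 24).
    apoptosis_duration_steps : int
        Steps between the apoptosis decision and absorption (default 10).
    phase_steps : tuple of 4 ints
        Steps spent in G0/G1, S, G2, M; must sum to ``cell_cycle_steps``.
    """

    lam: float = 0.0
    c1: float = 0.0
    c2: float = 0.0
    theta: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    p_pro: float = 0.8
    cell_cycle_steps: int = 24
    apoptosis_duration_steps: int = 10
    phase_steps: Tuple[int, int, int, int] = DEFAULT_PHASE_STEPS

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if self.c1 < 0 or self.c2 < 0:
            raise ValueError("c1, c2 must be >= 0")
        if not 0.0 <= self.p_pro <= 1.0:
            raise ValueError("p_pro must be in [0, 1]")
        if sum(self.phase_steps) != self.cell_cycle_steps:
            raise ValueError(
                f"phase_steps {self.phase_steps} must sum to "
                f"cell_cycle_steps={self.cell_cycle_steps}")

    def phase_at(self, cycle_position: int) -> Phase:
        """Cycle phase for a 1-based position in ``[1, cell_cycle_steps]``."""
        g1, s, g2, _ = self.phase_steps
        if cycle_position <= g1:
            return Phase.G0G1
        if cycle_position <= g1 + s:
            return Phase.S
        if cycle_position <= g1 + s + g2:
            return Phase.G2
        return Phase.M


@dataclass
class Cell:
    """One agent on the lattice."""

    id: int
    site: Site
    age_steps: int = 0
    phase: Phase = Phase.QUIESCENT
    cycle_position: int = 0          # 0 = not cycling
    apoptosis_countdown: int = 0     # > 0 iff apoptotic
    apoptosis_step: int = -1         # step index of the apoptosis decision
    division_ready: bool = field(default=False)

    @property
    def in_cycle(self) -> bool:
        return self.cycle_position > 0 and self.phase not in (
            Phase.QUIESCENT, Phase.APOPTOTIC)

    @property
    def apoptotic(self) -> bool:
        return self.phase is Phase.APOPTOTIC

    def age_h(self, time_step_h: float) -> float:
        return self.age_steps * time_step_h

    def start_apoptosis(self, duration_steps: int, step: int) -> None:
        self.phase = Phase.APOPTOTIC
        self.apoptosis_countdown = duration_steps
        self.apoptosis_step = step
        self.cycle_position = 0
        self.division_ready = False


def natural_mortality(lam: float, t: float) -> float:
    """Natural mortality rate ``Mnrate``: ``1 - exp(-lam t)`` for t > 0, else 0.

    ``t`` is the cell's age in hours; the result is a probability in
    ``[0, 1)`` that is monotone in both arguments.
    """
    if lam < 0:
        raise ValueError(f"lam must be >= 0, got {lam}")
    if t <= 0:
        return 0.0
    return -math.expm1(-lam * t)


def computed_mortality(theta: Tuple[float, float, float], dose1: float,
                       dose2: float, clamp: bool = True) -> float:
    """Drug-computed mortality ``Mcrate = theta0 + theta1 d1 + theta2 d2``.

    The raw linear value is what the dose-response fit sees; inside the
    simulator it feeds a probability mixture, so ``clamp=True`` (the
    default) truncates it to ``[0, 1]``.
    """
    if dose1 < 0 or dose2 < 0:
        raise ValueError("doses must be >= 0")
    t0, t1, t2 = theta
    mc = t0 + t1 * dose1 + t2 * dose2
    if clamp:
        mc = min(1.0, max(0.0, mc))
    return mc


def apoptosis_decision(mn: float, mc: float, c1: float, c2: float,
                       u: float) -> bool:
    """True iff ``c1*Mnrate + c2*Mcrate > u`` for a uniform draw ``u``.

    The cell starts apoptosis when the mixed mortality exceeds the
    random threshold.
    """
    if not 0.0 <= u <= 1.0:
        raise ValueError("u must be in [0, 1]")
    return c1 * mn + c2 * mc > u


def proliferation_decision(u: float, p_pro: float) -> bool:
    """Cycle ON iff ``u < p_pro`` (ties at exactly ``p_pro`` are OFF)."""
    if not 0.0 <= u <= 1.0:
        raise ValueError("u must be in [0, 1]")
    return u < p_pro


def advance_phase(cell: Cell, params: PhenotypeParams) -> Cell:
    """Advance a cycling cell one step through G0/G1 -> S -> G2 -> M.

    Increments ``cycle_position``, re-maps the phase, and flags the cell
    division-ready when it completes the M phase.  Not valid for
    apoptotic cells; quiescent cells re-test the proliferation rule in
    the engine instead of advancing here.
    """
    if cell.apoptotic:
        raise ValueError("cannot advance an apoptotic cell")
    cell.cycle_position += 1
    if cell.cycle_position >= params.cell_cycle_steps:
        cell.phase = Phase.M
        cell.division_ready = True
    else:
        cell.phase = params.phase_at(cell.cycle_position)
    return cell
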