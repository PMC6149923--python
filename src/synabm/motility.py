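"""Candidate-site ranking and roulette-wheel selection for movement.

A cell looking for somewhere to migrate or place a daughter scores each
free site in its neighborhood by a distance kernel times a crowding
preference, normalizes the scores to a probability wheel over [0, 1],
and spins the wheel with one uniform draw.  If no free site exists the
cell becomes reversibly quiescent instead (Rule 2).

The ranking score is ``R_l = (1/4) * P(r_l) * V_l`` with the kernel
``P(r) = exp(-r^2 / (4 pi D dt)) / (4 pi D dt)`` and a neighbor-count
preference ``V_l`` in {1/16, 1/8, 1/4, 1}.  The 1/4 prefactor and the
``4 pi D dt`` exponent scale are kept literally as the model defines
them; both cancel under normalization whenever all candidates share one
radius, which is the case for the default face-neighbor search.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Sequence

import numpy as np

from .agents import Cell, Phase
from .microenvironment import Lattice, Site

__all__ = [
    "CandidateSite", "SelectionWheel", "NoFreeSiteError",
    "neighbor_preference", "move_kernel", "rank_candidates",
    "select_site", "free_candidates", "attempt_move_or_divide",
]

#: preference weight per occupied-neighbor count (0..6 face neighbors)
_PREFERENCE = (
    1.0 / 16.0,  # 0 neighbors
    1.0, 1.0,    # 1-2 neighbors
    0.25, 0.25,  # 3-4 neighbors
    0.125, 0.125,  # 5-6 neighbors
)


class NoFreeSiteError(Exception):
    """No unoccupied candidate exists around the cell (Rule 2 path)."""


def neighbor_preference(n_neighbors: int) -> float:
    """Preference weight ``V_l`` for a candidate with ``n_neighbors``
    occupied face neighbors: moderately crowded sites (1-2 neighbors)
    are favored, empty and saturated neighborhoods are penalized."""
    if not 0 <= n_neighbors <= 6:
        raise ValueError(f"n_neighbors must be in [0, 6], got {n_neighbors}")
    return _PREFERENCE[n_neighbors]


def move_kernel(r: float, D: float, dt: float) -> float:
    """Distance kernel ``P(r) = exp(-r^2/(4 pi D dt)) / (4 pi D dt)``.

    ``r`` in um, ``D`` in um^2/h, ``dt`` in hours.
    """
    if r < 0:
        raise ValueError("r must be >= 0")
    if D <= 0 or dt <= 0:
        raise ValueError("D and dt must be > 0")
    s = 4.0 * math.pi * D * dt
    return math.exp(-r * r / s) / s


@dataclass
class CandidateSite:
    """One free site under consideration, with its ranking ingredients."""

    site: Site
    r_um: float
    n_neighbors: int
    preference: float = 0.0
    kernel: float = 0.0
    rank: float = 0.0
    rank_normalized: float = 0.0


def rank_candidates(candidates: Sequence[CandidateSite], D: float,
                    dt: float) -> List[CandidateSite]:
    """Score and normalize free candidates: ``R_l = (1/4) P(r_l) V_l``,
    then ``R~_l = R_l / sum R_l`` so the normalized ranks sum to 1."""
    if not candidates:
        raise NoFreeSiteError("no free candidate site")
    total = 0.0
    for c in candidates:
        c.preference = neighbor_preference(c.n_neighbors)
        c.kernel = move_kernel(c.r_um, D, dt)
        c.rank = 0.25 * c.kernel * c.preference
        total += c.rank
    for c in candidates:
        c.rank_normalized = c.rank / total
    return list(candidates)


class SelectionWheel:
    """Contiguous intervals partitioning [0, 1], one per candidate.

    Interval ``l`` has width ``R~_l``; intervals are half-open
    ``[lo, hi)`` except the last, which is closed at 1.
    """

    def __init__(self, normalized_ranks: Sequence[float]) -> None:
        ranks = np.asarray(normalized_ranks, dtype=float)
        if ranks.size == 0:
            raise ValueError("wheel needs at least one candidate")
        if not math.isclose(float(ranks.sum()), 1.0, abs_tol=1e-9):
            raise ValueError("normalized ranks must sum to 1")
        self.edges = np.concatenate([[0.0], np.cumsum(ranks)])
        self.edges[-1] = 1.0

    def __len__(self) -> int:
        return len(self.edges) - 1

    def select(self, d: float) -> int:
        """Index of the interval containing the uniform draw ``d``."""
        if not 0.0 <= d <= 1.0:
            raise ValueError("draw must be in [0, 1]")
        idx = int(np.searchsorted(self.edges, d, side="right")) - 1
        return min(idx, len(self) - 1)


def select_site(wheel: SelectionWheel, d: float) -> int:
    """Spin the wheel: return the candidate index whose interval holds ``d``."""
    return wheel.select(d)


def free_candidates(lattice: Lattice, origin: Site,
                    radius: int = 1) -> List[CandidateSite]:
    """Free candidate sites around ``origin``.

    ``radius=1`` gives the 6 face neighbors; ``radius=2`` widens the
    search to every site within Chebyshev distance 2.  Each candidate's
    ``n_neighbors`` counts occupied face neighbors of the candidate
    itself, excluding the origin (the cell is about to leave it or, for
    division, is not a crowding obstacle to its own daughter).
    """
    spacing = lattice.spacing_um
    out: List[CandidateSite] = []
    if radius == 1:
        sites = lattice.face_neighbors(origin)
    else:
        x, y, z = origin
        sites = []
        for dx in range(-radius, radius + 1):
            for dy in range(-radius, radius + 1):
                for dz in range(-radius, radius + 1):
                    if dx == dy == dz == 0:
                        continue
                    nb = (x + dx, y + dy, z + dz)
                    if lattice.in_bounds(nb):
                        sites.append(nb)
    for nb in sites:
        if nb in lattice:
            continue
        r_um = spacing * math.dist(nb, origin)
        n_occ = lattice.occupied_face_neighbor_count(nb, exclude=origin)
        out.append(CandidateSite(site=nb, r_um=r_um, n_neighbors=n_occ))
    return out


def _fast_pick_face_neighbor(lattice: Lattice, origin: Site,
                             rng: np.random.Generator) -> Site | None:
    """Equal-radius fast path of rank-and-spin for the 6 face neighbors.

    All face-neighbor candidates share r = spacing, so the distance
    kernel and the 1/4 prefactor cancel under normalization and the
    selection probabilities reduce to the preference weights V_l.  One
    uniform draw spins the wheel, exactly as the general path does.
    Returns the chosen free site, or None when every candidate is
    occupied.
    """
    occ = lattice._occupancy
    n = lattice.n_per_axis
    x, y, z = origin
    sites: list[Site] = []
    weights: list[float] = []
    total = 0.0
    for dx, dy, dz in Lattice.FACE_OFFSETS:
        cx, cy, cz = x + dx, y + dy, z + dz
        if not (0 <= cx < n and 0 <= cy < n and 0 <= cz < n):
            continue
        cand = (cx, cy, cz)
        if cand in occ:
            continue
        count = 0
        for ex, ey, ez in Lattice.FACE_OFFSETS:
            nb = (cx + ex, cy + ey, cz + ez)
            # out-of-bounds triples are never occupancy keys
            if nb != origin and nb in occ:
                count += 1
        w = _PREFERENCE[count]
        sites.append(cand)
        weights.append(w)
        total += w
    if not sites:
        return None
    d = rng.random() * total
    acc = 0.0
    for site, w in zip(sites, weights):
        acc += w
        if d < acc:
            return site
    return sites[-1]


def attempt_move_or_divide(cell: Cell, lattice: Lattice, mode: str,
                           rng: np.random.Generator, *, D: float = 10.0,
                           dt: float = 0.72, division_radius: int = 1,
                           make_daughter=None) -> Cell | None:
    """Try to migrate the cell, or place a daughter, on a selected free site.

    ``mode`` is ``"migrate"`` or ``"divide"``.  On success, migration
    relocates the cell (one site freed, one occupied) and division
    places a fresh daughter produced by ``make_daughter(site)``; the
    function returns the daughter (division) or None (migration).  With
    no free candidate the cell becomes reversibly quiescent and the
    lattice is untouched (Rule 2): the quiescent cell re-enters the
    normal decision flow next step.
    """
    if mode not in ("migrate", "divide"):
        raise ValueError(f"mode must be 'migrate' or 'divide', got {mode!r}")
    radius = division_radius if mode == "divide" else 1
    if radius == 1:
        chosen = _fast_pick_face_neighbor(lattice, cell.site, rng)
    else:
        cands = free_candidates(lattice, cell.site, radius=radius)
        chosen = None
        if cands:
            rank_candidates(cands, D, dt)
            wheel = SelectionWheel([c.rank_normalized for c in cands])
            chosen = cands[wheel.select(float(rng.random()))].site
    if chosen is None:
        # Rule 2: no space -> reversible quiescence
        cell.phase = Phase.QUIESCENT
        if mode == "migrate":
            cell.cycle_position = 0
        return None
    if mode == "migrate":
        lattice.move(cell.site, chosen)
        cell.site = chosen
        return None
    if make_daughter is None:
        raise ValueError("divide mode needs a make_daughter factory")
    daughter = make_daughter(chosen)
    lattice.place(chosen, daughter.id)
    return daughter
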