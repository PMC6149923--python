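"""3D extracellular-matrix lattice and exponentially decaying drug fields.

The microenvironment is a bounded cubic lattice (default 100 sites per
axis, 5 um spacing, roughly one cancer-cell radius per site) holding at
most one cell per site, plus one spatially uniform concentration scalar
per drug.  Drug exposure follows first-order half-life kinetics; the
model has no diffusion term, so each drug field is a single scalar that
is shaped so a per-site field could replace it later.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, Tuple

import numpy as np

Site = Tuple[int, int, int]

__all__ = ["Site", "DrugField", "Lattice", "decay_drug", "init_lattice"]


def decay_drug(c0: float, half_life: float, elapsed: float) -> float:
    """Concentration after first-order decay with the given half-life.

    Parameters
    ----------
    c0 : float
        Initial concentration (uM), ``>= 0``.
    half_life : float
        Half-life ``T`` in hours, ``> 0``.
    elapsed : float
        Time since ``t0`` in hours, ``>= 0``.

    Returns
    -------
    float
        ``c0 * (1/2) ** (elapsed / half_life)``.
    """
    if c0 < 0:
        raise ValueError(f"initial concentration must be >= 0, got {c0}")
    if half_life <= 0:
        raise ValueError(f"half-life must be > 0, got {half_life}")
    if elapsed < 0:
        raise ValueError(f"elapsed time must be >= 0, got {elapsed}")
    return c0 * 0.5 ** (elapsed / half_life)


@dataclass(frozen=True)
class DrugField:
    """Spatially uniform drug exposure with half-life decay.

    Attributes
    ----------
    name : str
        Drug name (e.g. ``"gefitinib"``).
    initial_uM : float
        Concentration applied at ``t0`` (uM).
    half_life_h : float
        Elimination half-life in hours.
    """

    name: str
    initial_uM: float
    half_life_h: float

    def __post_init__(self) -> None:
        if self.initial_uM < 0:
            raise ValueError("initial concentration must be >= 0")
        if self.half_life_h <= 0:
            raise ValueError("half-life must be > 0")

    def concentration(self, t_h: float) -> float:
        """Concentration at ``t_h`` hours after dosing (closed form)."""
        return decay_drug(self.initial_uM, self.half_life_h, t_h)


class Lattice:
    """Cubic occupancy grid with at most one cell per site.

    Sites are 0-based integer triples in ``[0, n_per_axis)^3``; the
    physical position of a site is ``coordinate * spacing_um``.  The
    boundary is hard: border sites simply have fewer neighbors.
    """

    #: the 6 face-neighbor (von Neumann) offsets
    FACE_OFFSETS: Tuple[Site, ...] = (
        (1, 0, 0), (-1, 0, 0),
        (0, 1, 0), (0, -1, 0),
        (0, 0, 1), (0, 0, -1),
    )

    def __init__(self, n_per_axis: int = 100, spacing_um: float = 5.0) -> None:
        if n_per_axis < 1:
            raise ValueError("n_per_axis must be >= 1")
        if spacing_um <= 0:
            raise ValueError("spacing_um must be > 0")
        self.n_per_axis = int(n_per_axis)
        self.spacing_um = float(spacing_um)
        self._occupancy: Dict[Site, int] = {}

    # -- occupancy ---------------------------------------------------------

    def __contains__(self, site: Site) -> bool:
        return site in self._occupancy

    def __len__(self) -> int:
        return len(self._occupancy)

    def occupant(self, site: Site) -> int | None:
        return self._occupancy.get(site)

    def occupied_sites(self) -> Iterator[Site]:
        return iter(self._occupancy)

    def in_bounds(self, site: Site) -> bool:
        n = self.n_per_axis
        x, y, z = site
        return 0 <= x < n and 0 <= y < n and 0 <= z < n

    def is_free(self, site: Site) -> bool:
        """True for an in-bounds, unoccupied site."""
        return self.in_bounds(site) and site not in self._occupancy

    def place(self, site: Site, cell_id: int) -> None:
        if not self.in_bounds(site):
            raise ValueError(f"site {site} outside the lattice")
        if site in self._occupancy:
            raise ValueError(f"site {site} already occupied")
        self._occupancy[site] = cell_id

    def remove(self, site: Site) -> int:
        return self._occupancy.pop(site)

    def move(self, old: Site, new: Site) -> None:
        cell_id = self.remove(old)
        try:
            self.place(new, cell_id)
        except ValueError:
            self._occupancy[old] = cell_id
            raise

    # -- neighborhoods -----------------------------------------------------

    def face_neighbors(self, site: Site) -> list[Site]:
        """In-bounds face neighbors (up to 6) of a site."""
        x, y, z = site
        out = []
        for dx, dy, dz in self.FACE_OFFSETS:
            nb = (x + dx, y + dy, z + dz)
            if self.in_bounds(nb):
                out.append(nb)
        return out

    def occupied_face_neighbor_count(self, site: Site, exclude: Site | None = None) -> int:
        """Occupied face neighbors of ``site``, optionally ignoring one site."""
        occ = self._occupancy
        x, y, z = site
        n = self.n_per_axis
        count = 0
        for dx, dy, dz in self.FACE_OFFSETS:
            nb = (x + dx, y + dy, z + dz)
            if nb == exclude:
                continue
            if 0 <= nb[0] < n and 0 <= nb[1] < n and 0 <= nb[2] < n and nb in occ:
                count += 1
        return count

    def audit(self) -> None:
        """Raise if any occupied site is out of bounds (exclusion is
        structural: the dict key is the site, so double occupancy cannot
        be represented)."""
        for site in self._occupancy:
            if not self.in_bounds(site):
                raise AssertionError(f"occupied site {site} out of bounds")


def _center_sites_by_shell(n_per_axis: int, n_needed: int,
                           rng: np.random.Generator) -> list[Site]:
    """Sites around the lattice center, by increasing Chebyshev shell.

    Within a shell, sites are enumerated in lexicographic order and then
    shuffled by the seeded RNG, giving a compact, reproducible blob.
    """
    c = n_per_axis // 2
    center = (c, c, c)
    sites: list[Site] = [center]
    k = 0
    while len(sites) < n_needed:
        k += 1
        if c - k < 0 and c + k >= n_per_axis:
            break
        shell = []
        lo, hi = max(0, c - k), min(n_per_axis - 1, c + k)
        for x in range(lo, hi + 1):
            for y in range(lo, hi + 1):
                for z in range(lo, hi + 1):
                    if max(abs(x - c), abs(y - c), abs(z - c)) == k:
                        shell.append((x, y, z))
        order = rng.permutation(len(shell))
        sites.extend(shell[i] for i in order)
    return sites


@dataclass
class SeededLattice:
    """Result of :func:`init_lattice`: the lattice plus initial ages."""

    lattice: Lattice
    sites: list[Site]
    ages_h: np.ndarray = field(repr=False)


def init_lattice(n_per_axis: int = 100, n_cells: int = 100,
                 age_max_h: float = 24.0, seed: int | None = None,
                 spacing_um: float = 5.0) -> SeededLattice:
    """Seed ``n_cells`` cells in a compact blob at the lattice center.

    Cell ids are ``0 .. n_cells-1`` in placement order; each age is drawn
    uniformly in ``[0, age_max_h]`` hours.  Identical seeds reproduce the
    occupancy and ages bit for bit.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if n_cells > n_per_axis ** 3:
        raise ValueError(
            f"cannot place {n_cells} cells on a {n_per_axis}^3 lattice")
    rng = np.random.default_rng(seed)
    lattice = Lattice(n_per_axis, spacing_um)
    sites = _center_sites_by_shell(n_per_axis, n_cells, rng)
    if len(sites) < n_cells:
        raise ValueError("not enough central sites for the requested cells")
    chosen = sites[:n_cells]
    for cell_id, site in enumerate(chosen):
        lattice.place(site, cell_id)
    ages_h = rng.uniform(0.0, age_max_h, size=n_cells)
    return SeededLattice(lattice=lattice, sites=chosen, ages_h=ages_h)
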