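import itertools
import math

import numpy as np
import pytest

from synabm.agents import Cell, Phase
from synabm.microenvironment import Lattice
from synabm.motility import (CandidateSite, NoFreeSiteError, SelectionWheel,
                             attempt_move_or_divide, free_candidates,
                             move_kernel, neighbor_preference,
                             rank_candidates, select_site)


class TestNeighborPreference:
    @pytest.mark.parametrize("n, expected", [
        (0, 1 / 16), (1, 1.0), (2, 1.0), (3, 0.25), (4, 0.25),
        (5, 0.125), (6, 0.125),
    ])
    def test_preference_table(self, n, expected):
        assert neighbor_preference(n) == expected

    @pytest.mark.parametrize("n", [-1, 7])
    def test_out_of_range(self, n):
        with pytest.raises(ValueError):
            neighbor_preference(n)


class TestMoveKernel:
    def test_zero_distance(self):
        D, dt = 10.0, 0.72
        assert move_kernel(0.0, D, dt) == pytest.approx(1 / (4 * math.pi * D * dt))

    def test_strictly_decreasing_in_r(self):
        vals = [move_kernel(r, 10.0, 0.72) for r in np.linspace(0, 20, 30)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_log_space_cross_check(self):
        # independent evaluation: exp(-log(4*pi*D*dt) - r^2/(4*pi*D*dt))
        r, D, dt = 5.0, 10.0, 0.72
        s = 4 * math.pi * D * dt
        oracle = math.exp(-math.log(s) - r * r / s)
        assert move_kernel(r, D, dt) == pytest.approx(oracle, rel=1e-14)
        assert move_kernel(r, D, dt) == pytest.approx(0.008383, rel=1e-3)

    @pytest.mark.parametrize("kwargs", [
        dict(r=-1.0, D=1.0, dt=1.0), dict(r=1.0, D=0.0, dt=1.0),
        dict(r=1.0, D=1.0, dt=-1.0),
    ])
    def test_invalid(self, kwargs):
        with pytest.raises(ValueError):
            move_kernel(**kwargs)


def _candidates(specs):
    return [CandidateSite(site=(i, 0, 0), r_um=r, n_neighbors=n)
            for i, (r, n) in enumerate(specs)]


class TestRankCandidates:
    def test_single_candidate(self):
        c = rank_candidates(_candidates([(5.0, 2)]), 10.0, 0.72)
        assert c[0].rank_normalized == pytest.approx(1.0)

    def test_six_symmetric_candidates(self):
        cands = rank_candidates(_candidates([(5.0, 3)] * 6), 10.0, 0.72)
        for c in cands:
            assert c.rank_normalized == pytest.approx(1 / 6)

    def test_preference_dominates_at_equal_distance(self):
        # V = (1, 1/4) at equal r: kernel cancels, weights (0.8, 0.2)
        cands = rank_candidates(_candidates([(5.0, 1), (5.0, 3)]), 10.0, 0.72)
        assert cands[0].rank_normalized == pytest.approx(0.8)
        assert cands[1].rank_normalized == pytest.approx(0.2)

    def test_normalization_sums_to_one(self, rng):
        for _ in range(50):
            k = int(rng.integers(1, 7))
            specs = [(float(rng.uniform(5, 15)), int(rng.integers(0, 7)))
                     for _ in range(k)]
            cands = rank_candidates(_candidates(specs), 10.0, 0.72)
            assert sum(c.rank_normalized for c in cands) == pytest.approx(1.0)

    def test_empty_candidate_list_signals(self):
        with pytest.raises(NoFreeSiteError):
            rank_candidates([], 10.0, 0.72)

    def test_brute_force_enumeration_oracle(self):
        """Agreement with first-principles arithmetic over all 2^6
        occupancy patterns of a cell's face neighborhood."""
        offsets = Lattice.FACE_OFFSETS
        pref_table = {0: 1 / 16, 1: 1.0, 2: 1.0, 3: 0.25, 4: 0.25,
                      5: 0.125, 6: 0.125}
        center = (3, 3, 3)
        for pattern in itertools.product([0, 1], repeat=6):
            lat = Lattice(7)
            lat.place(center, 99)
            occupied = set()
            for bit, (dx, dy, dz) in zip(pattern, offsets):
                if bit:
                    site = (3 + dx, 3 + dy, 3 + dz)
                    lat.place(site, len(occupied))
                    occupied.add(site)
            cands = free_candidates(lat, center, radius=1)
            assert len(cands) == 6 - sum(pattern)
            if not cands:
                continue
            # oracle: count occupied face neighbors by set intersection,
            # apply the printed preference table, normalize explicitly
            expected = []
            for c in cands:
                nb = {(c.site[0] + dx, c.site[1] + dy, c.site[2] + dz)
                      for dx, dy, dz in offsets} - {center}
                expected.append(pref_table[len(nb & occupied)])
            expected = np.array(expected) / sum(expected)
            ranked = rank_candidates(cands, 10.0, 0.72)
            got = np.array([c.rank_normalized for c in ranked])
            np.testing.assert_allclose(got, expected, rtol=1e-12)


class TestFastPathAgreement:
    def test_fast_pick_frequencies_match_general_ranking(self, rng):
        """The equal-radius shortcut used for face-neighbor moves must
        select sites with the same probabilities as the full
        rank-and-spin path."""
        from synabm.motility import _fast_pick_face_neighbor

        lat = Lattice(9)
        center = (4, 4, 4)
        lat.place(center, 0)
        # asymmetric crowding around the neighborhood
        for i, site in enumerate([(4, 5, 5), (4, 3, 5), (5, 5, 4),
                                  (3, 4, 5), (5, 4, 5)], start=1):
            lat.place(site, i)
        cands = rank_candidates(free_candidates(lat, center, radius=1),
                                10.0, 0.72)
        expected = {c.site: c.rank_normalized for c in cands}
        n = 30_000
        counts = {}
        for _ in range(n):
            site = _fast_pick_face_neighbor(lat, center, rng)
            counts[site] = counts.get(site, 0) + 1
        assert set(counts) <= set(expected)
        for site, p in expected.items():
            freq = counts.get(site, 0) / n
            assert abs(freq - p) < 3 * math.sqrt(p * (1 - p) / n) + 1e-9


class TestSelectionWheel:
    def test_single_candidate_always_chosen(self):
        wheel = SelectionWheel([1.0])
        for d in (0.0, 0.5, 1.0):
            assert select_site(wheel, d) == 0

    def test_interval_membership(self):
        wheel = SelectionWheel([0.8, 0.2])
        assert select_site(wheel, 0.9) == 1
        assert select_site(wheel, 0.79) == 0
        assert select_site(wheel, 0.8) == 1   # half-open [0, 0.8), [0.8, 1]
        assert select_site(wheel, 1.0) == 1

    def test_empirical_frequencies_match_ranks(self, rng):
        ranks = np.array([0.5, 0.3, 0.15, 0.05])
        wheel = SelectionWheel(ranks)
        n = 100_000
        draws = rng.random(n)
        counts = np.bincount([wheel.select(float(d)) for d in draws],
                             minlength=4)
        for freq, p in zip(counts / n, ranks):
            assert abs(freq - p) < 3 * math.sqrt(p * (1 - p) / n)


class TestMoveOrDivide:
    def _enclosed(self):
        lat = Lattice(7)
        cell = Cell(id=0, site=(3, 3, 3))
        lat.place(cell.site, 0)
        for i, (dx, dy, dz) in enumerate(Lattice.FACE_OFFSETS, start=1):
            lat.place((3 + dx, 3 + dy, 3 + dz), i)
        return lat, cell

    def test_enclosed_cell_goes_quiescent(self, rng):
        lat, cell = self._enclosed()
        before = set(lat.occupied_sites())
        out = attempt_move_or_divide(cell, lat, "migrate", rng)
        assert out is None
        assert cell.phase is Phase.QUIESCENT
        assert set(lat.occupied_sites()) == before

    def test_enclosed_division_blocked_keeps_readiness(self, rng):
        lat, cell = self._enclosed()
        cell.division_ready = True
        attempt_move_or_divide(cell, lat, "divide", rng,
                               make_daughter=lambda s: Cell(id=9, site=s))
        assert cell.division_ready          # retries when space frees up
        assert cell.phase is Phase.QUIESCENT

    def test_isolated_migration_conserves_occupancy(self, rng):
        lat = Lattice(9)
        cell = Cell(id=0, site=(4, 4, 4))
        lat.place(cell.site, 0)
        attempt_move_or_divide(cell, lat, "migrate", rng)
        assert len(lat) == 1
        assert lat.occupant(cell.site) == 0
        assert max(abs(a - 4) for a in cell.site) == 1

    def test_isolated_division_adds_one_cell(self, rng):
        lat = Lattice(9)
        cell = Cell(id=0, site=(4, 4, 4))
        lat.place(cell.site, 0)
        daughter = attempt_move_or_divide(
            cell, lat, "divide", rng,
            make_daughter=lambda s: Cell(id=1, site=s, age_steps=0))
        assert daughter is not None and daughter.age_steps == 0
        assert len(lat) == 2
        assert daughter.site != cell.site

    def test_radius_two_search_reaches_second_shell(self, rng):
        lat, cell = self._enclosed()  # face neighbors all blocked
        cell.division_ready = True
        daughter = attempt_move_or_divide(
            cell, lat, "divide", rng, division_radius=2,
            make_daughter=lambda s: Cell(id=9, site=s))
        assert daughter is not None
        assert max(abs(a - 3) for a in daughter.site) <= 2
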