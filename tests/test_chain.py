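"""Chain observables and move generators."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hydropore.chain import (
    MoveProposal,
    apply_proposal,
    count_contact_points,
    max_contact_points,
    propose_corner_flip,
    propose_crankshaft,
    propose_pivot,
    propose_translation,
    wall_overlap,
)
from hydropore.engine import random_saw, rod_chain
from hydropore.fixtures import fixture_chain
from hydropore.lattice import GridSpec, build_slit_pore, validate_chain


def _max_ncp_exhaustive(n):
    """Exhaustive maximum N_CP over every n-cell SAW (oracle for small n)."""
    best = 0

    def ncp(cells):
        index = {c: i for i, c in enumerate(cells)}
        total = 0
        for i, (x, y) in enumerate(cells):
            for dx, dy in ((1, 0), (0, 1)):
                j = index.get((x + dx, y + dy))
                if j is not None and abs(j - i) >= 2:
                    total += 1
        return total

    def grow(cells, used):
        nonlocal best
        if len(cells) == n:
            best = max(best, ncp(cells))
            return
        x, y = cells[-1]
        for dx, dy in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            c = (x + dx, y + dy)
            if c not in used:
                grow(cells + [c], used | {c})

    grow([(0, 0)], {(0, 0)})
    return best


class TestContactPoints:
    def test_rod_zero(self, spec40):
        assert count_contact_points(fixture_chain("rod"), spec40) == 0

    def test_unit_square_one(self, spec40):
        sq = np.array([[5, 5], [6, 5], [6, 6], [5, 6]])
        assert count_contact_points(sq, spec40) == 1

    def test_snake_maximal(self, spec40):
        assert count_contact_points(fixture_chain("snake6x6"), spec40) == 25

    def test_hairpin(self, spec40):
        # two antiparallel 18-mers: 18 cross contacts minus the turn adjacency
        chain = fixture_chain("hairpin")
        assert count_contact_points(chain, spec40) == 17

    def test_invalid_chain_raises(self, spec40):
        with pytest.raises(ValueError):
            count_contact_points(np.array([[0, 0], [2, 0]]), spec40)

    def test_bound_formula_vs_exhaustive(self):
        for n in range(2, 10):
            assert max_contact_points(n) == _max_ncp_exhaustive(n)

    def test_bound_36(self):
        assert max_contact_points(36) == 25

    def test_every_chain_below_bound(self, rng):
        spec = GridSpec(L=20, wall_row=None)
        for _ in range(10):
            chain = random_saw(16, spec, rng)
            assert count_contact_points(chain, spec) <= max_contact_points(16)


class TestCornerFlip:
    def test_interior_kink(self, spec40, rng):
        chain = np.array([[5, 5], [6, 5], [6, 6], [6, 7]])
        prop = propose_corner_flip(chain, 1, rng, spec40)
        assert prop.valid
        assert list(prop.moved) == [1]
        assert tuple(prop.new_xy[0]) == (5, 6)  # the opposite corner of the kink

    def test_straight_segment_invalid(self, spec40, rng):
        chain = rod_chain(6, spec40)
        prop = propose_corner_flip(chain, 3, rng, spec40)
        assert not prop.valid

    def test_end_rotation_targets(self, spec40):
        chain = rod_chain(6, spec40)
        seen = set()
        for choice in range(64):
            rng = np.random.default_rng(choice)
            prop = propose_corner_flip(chain, 0, rng, spec40)
            if prop.valid:
                seen.add(tuple(prop.new_xy[0]))
        # terminal residue rotates to any of the 3 other neighbours of residue 1
        assert len(seen) == 3


class TestCrankshaft:
    def test_u_segment_flip(self, spec40, rng):
        chain = np.array([[5, 5], [5, 6], [6, 6], [6, 5]])
        prop = propose_crankshaft(chain, 0, rng, spec40)
        assert prop.valid
        assert list(prop.moved) == [1, 2]
        assert tuple(prop.new_xy[0]) == (5, 4)
        assert tuple(prop.new_xy[1]) == (6, 4)

    def test_involution(self, spec40, rng):
        chain = np.array([[5, 5], [5, 6], [6, 6], [6, 5]])
        prop = propose_crankshaft(chain, 0, rng, spec40)
        flipped = apply_proposal(chain, prop)
        back = propose_crankshaft(flipped, 0, rng, spec40)
        assert np.array_equal(apply_proposal(flipped, back), chain)

    def test_non_u_invalid(self, spec40, rng):
        prop = propose_crankshaft(rod_chain(8, spec40), 2, rng, spec40)
        assert not prop.valid


class TestPivot:
    def test_rotates_shorter_arm(self, spec40, rng):
        chain = rod_chain(9, spec40)
        prop = propose_pivot(chain, 6, rng, spec40, rotation=2)
        assert prop.valid
        assert sorted(prop.moved) == [7, 8]  # tail is shorter

    def test_180_reflects_through_pivot(self, spec40):
        chain = rod_chain(5, spec40)
        rng = np.random.default_rng(0)
        prop = propose_pivot(chain, 3, rng, spec40, rotation=2)
        new_chain = apply_proposal(chain, prop)
        px, py = chain[3]
        assert tuple(new_chain[4]) == ((2 * px - chain[4, 0]) % 40, (2 * py - chain[4, 1]) % 40)

    def test_result_is_valid_saw(self, spec40, rng):
        # with the occupancy grid supplied, excluded volume is enforced and
        # every valid proposal yields a proper SAW
        chain = fixture_chain("hairpin")
        occ = build_slit_pore(spec40, chain)
        for _ in range(20):
            idx = int(rng.integers(len(chain)))
            prop = propose_pivot(chain, idx, rng, spec40, occ=occ)
            if prop.valid:
                validate_chain(apply_proposal(chain, prop), spec40)


class TestTranslation:
    def test_moves_every_residue(self, spec40, rng):
        chain = rod_chain(6, spec40)
        prop = propose_translation(chain, False, rng, spec40)
        assert prop.valid
        assert len(prop.moved) == 6

    def test_bias_never_proposes_down(self, spec40):
        chain = rod_chain(6, spec40)
        for seed in range(200):
            rng = np.random.default_rng(seed)
            prop = propose_translation(chain, True, rng, spec40)
            dy = (int(prop.new_xy[0, 1]) - int(chain[0, 1])) % 40
            assert dy != 39  # -y never proposed under bias

    def test_unbiased_proposes_all_directions(self, spec40):
        chain = rod_chain(6, spec40)
        deltas = set()
        for seed in range(200):
            rng = np.random.default_rng(seed)
            prop = propose_translation(chain, False, rng, spec40)
            deltas.add(
                (
                    (int(prop.new_xy[0, 0]) - int(chain[0, 0])) % 40,
                    (int(prop.new_xy[0, 1]) - int(chain[0, 1])) % 40,
                )
            )
        assert deltas == {(1, 0), (39, 0), (0, 1), (0, 39)}

    def test_wall_blocking(self, spec40):
        chain = np.array([[5, 1], [6, 1]])  # directly above the wall
        occ = build_slit_pore(spec40, chain)
        rng = np.random.default_rng(3)
        for _ in range(50):
            prop = propose_translation(chain, False, rng, spec40, occ=occ)
            if prop.valid:
                assert not wall_overlap(prop, occ)


class TestProposalPlumbing:
    def test_apply_invalid_raises(self):
        with pytest.raises(ValueError):
            apply_proposal(np.zeros((2, 2), dtype=np.int64), MoveProposal.invalid("pivot"))

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_random_moves_preserve_saw(self, seed):
        rng = np.random.default_rng(seed)
        spec = GridSpec(L=20, wall_row=None)
        chain = random_saw(12, spec, rng)
        movers = (
            lambda c: propose_corner_flip(c, int(rng.integers(len(c))), rng, spec),
            lambda c: propose_crankshaft(c, int(rng.integers(len(c))), rng, spec),
            lambda c: propose_pivot(c, int(rng.integers(len(c))), rng, spec),
            lambda c: propose_translation(c, False, rng, spec),
        )
        for _ in range(10):
            prop = movers[int(rng.integers(4))](chain)
            if prop.valid:
                candidate = apply_proposal(chain, prop)
                try:
                    validate_chain(candidate, spec)
                except ValueError:
                    continue  # self-collision: a rejected proposal, chain unchanged
                chain = candidate
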