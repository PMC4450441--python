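"""Plane linking: printed criteria, optimal assignment, chain splitting."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import rootmosaic as rm
from rootmosaic.segmentation import PlaneSegmentation

from .oracles import brute_force_link, random_instance


def _seg(plane, *regions):
    return PlaneSegmentation.from_records(
        plane,
        [
            {"label": i + 1, "row": r, "col": c, "area_px": a}
            for i, (r, c, a) in enumerate(regions)
        ],
    )


class TestRelativeAreaDiff:
    @pytest.mark.parametrize(
        "a1,a2,expected",
        [(100, 100, 0.0), (100, 200, 0.5), (140, 100, 40 / 140), (100, 140, 40 / 140)],
    )
    def test_examples(self, a1, a2, expected):
        assert rm.relative_area_diff(a1, a2) == pytest.approx(expected)

    @given(
        st.floats(min_value=1e-3, max_value=1e6),
        st.floats(min_value=1e-3, max_value=1e6),
    )
    def test_symmetric_and_bounded(self, a1, a2):
        d = rm.relative_area_diff(a1, a2)
        assert d == rm.relative_area_diff(a2, a1)
        assert 0.0 <= d < 1.0

    @pytest.mark.parametrize("bad", [(0, 10), (10, 0), (-5, 10)])
    def test_nonpositive_area_rejected(self, bad):
        with pytest.raises(ValueError):
            rm.relative_area_diff(*bad)


class TestPairCriteria:
    def link2(self, r1, r2):
        segs = [_seg(0, r1), _seg(1, r2)]
        return rm.link_planes(segs, rm.LinkCriteria())

    def test_within_both_criteria_links(self):
        cells = self.link2((50, 50, 100), (50, 69, 140))  # 19 px, rel 0.286
        assert len(cells) == 1 and cells[0].n_planes == 2

    def test_centroids_beyond_20px_do_not_link(self):
        assert self.link2((50, 50, 100), (50, 71, 140)) == []  # 21 px

    def test_area_change_beyond_half_does_not_link(self):
        assert self.link2((50, 50, 100), (50, 50, 250)) == []  # rel 0.6

    def test_exact_boundaries_link(self):
        cells = self.link2((50, 50, 100), (50, 70, 200))  # 20 px, rel 0.5
        assert len(cells) == 1

    def test_long_chain_is_cut_at_six_planes(self):
        segs = [_seg(p, (50, 50, 100)) for p in range(8)]
        cells = rm.link_planes(segs, rm.LinkCriteria())
        assert sorted(c.n_planes for c in cells) == [2, 6]
        assert max(c.n_planes for c in cells) <= 6

    def test_single_plane_fragments_dropped_by_default_but_configurable(self):
        segs = [_seg(0, (10, 10, 100)), _seg(1, (90, 90, 100))]  # unlinkable
        assert rm.link_planes(segs, rm.LinkCriteria()) == []
        kept = rm.link_planes(segs, rm.LinkCriteria(), min_planes=1)
        assert len(kept) == 2

    def test_empty_input(self):
        assert rm.link_planes([], rm.LinkCriteria()) == []

    def test_inconsistent_z_extent_cap_rejected(self):
        crit = rm.LinkCriteria(max_z_extent_planes=6, max_z_extent_um=18.0)
        with pytest.raises(ValueError):
            rm.link_planes([_seg(0, (1, 1, 10))], crit, z_step_um=2.0)


def test_assignment_prefers_minimum_total_distance():
    # two regions each; greedy from label order would pair 1-1 (dist 10) and
    # leave 2 with a long link; the optimal assignment swaps to 8+8 < 10+12
    a = _seg(0, (50, 50, 100), (50, 70, 100))
    b = _seg(1, (50, 58, 100), (50, 62, 100))
    pairs = rm.match_adjacent(a.regions, b.regions, rm.LinkCriteria())
    assert sorted(pairs) == [(1, 1), (2, 2)]
    a = _seg(0, (50, 50, 100), (50, 66, 100))
    b = _seg(1, (50, 60, 100), (50, 56, 100))
    pairs = rm.match_adjacent(a.regions, b.regions, rm.LinkCriteria())
    # total |50-60|+|66-56| = 20 vs |50-56|+|66-60| = 12: picks the latter
    assert sorted(pairs) == [(1, 2), (2, 1)]


def test_exact_tie_breaks_by_area_difference_then_label():
    crit = rm.LinkCriteria()
    # equidistant candidates; the second has the smaller area difference
    a = _seg(0, (50, 50, 100))
    b = _seg(1, (50, 40, 150), (50, 60, 120))
    assert rm.match_adjacent(a.regions, b.regions, crit) == [(1, 2)]
    # fully identical candidates: lower label wins
    b = _seg(1, (50, 40, 100), (50, 60, 100))
    assert rm.match_adjacent(a.regions, b.regions, crit) == [(1, 1)]


def test_matches_bruteforce_oracle_on_random_instances():
    crit = rm.LinkCriteria()
    rng = np.random.default_rng(42)
    for _ in range(60):
        segs = random_instance(rng)
        ours = sorted(tuple(c.regions) for c in rm.link_planes(segs, crit))
        oracle = brute_force_link(segs, crit)
        assert ours == oracle


def test_reconstruction_partitions_regions_and_passes_audit(demo_segs, demo_cells):
    problems = rm.audit_cells(demo_cells, demo_segs, rm.LinkCriteria())
    assert problems == []
    used = [node for c in demo_cells for node in c.regions]
    assert len(used) == len(set(used))
    available = {
        (s.plane_index, int(l)) for s in demo_segs for l in s.regions["label"]
    }
    assert set(used) <= available
    assert max(c.n_planes for c in demo_cells) <= 6
    assert max((c.n_planes - 1) * 3.0 for c in demo_cells) <= 18.0


def test_most_true_cells_recovered_one_to_one(demo_root, demo_pairing):
    _, truth = demo_root
    assert len(demo_pairing) >= 0.8 * len(truth.table)
    # one-to-one by construction
    assert len(set(demo_pairing.values())) == len(demo_pairing)
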