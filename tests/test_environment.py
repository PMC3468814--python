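"""Tests for the spatial food environment builders."""

import numpy as np
import pytest

from rewardgrid import (
    build_gradient,
    build_quadrants,
    build_well_mixed,
    neighbors,
    switch_pure_quadrants_to_mixed,
)
from rewardgrid.environment import REGION_HH, REGION_LL


class TestWellMixed:
    def test_grid_size_and_item_count(self):
        env = build_well_mixed(100, 100, seed=0)
        assert env.h_count.shape == (100, 100)
        assert env.items_per_cell == 2
        assert env.cell_contents((0, 0)) in (("H", "H"), ("H", "L"), ("L", "L"))

    def test_degenerate_single_cell(self):
        env = build_well_mixed(1, 1, seed=0)
        assert env.h_count.shape == (1, 1)
        assert len(env.cell_contents((0, 0))) == 2

    def test_cell_mix_follows_binomial_law(self):
        # Two independent fair draws: HH ~ 1/4, HL ~ 1/2, LL ~ 1/4.
        counts = np.zeros(3)
        for seed in range(5):
            env = build_well_mixed(200, 200, seed=seed)
            for k in range(3):
                counts[k] += (env.h_count == k).mean() / 5
        assert counts[0] == pytest.approx(0.25, abs=0.01)
        assert counts[1] == pytest.approx(0.50, abs=0.01)
        assert counts[2] == pytest.approx(0.25, abs=0.01)

    def test_rejects_bad_dimensions(self):
        with pytest.raises(ValueError):
            build_well_mixed(0, 10)


class TestQuadrants:
    def test_four_equal_regions(self):
        env = build_quadrants(100, 100, seed=1)
        sizes = [(env.region == r).sum() for r in range(4)]
        assert sizes == [2500] * 4
        # Partition is exhaustive and disjoint by construction of sizes.
        assert sum(sizes) == env.region.size

    def test_pure_quadrant_contents(self):
        env = build_quadrants(40, 40, seed=2)
        assert (env.h_count[env.region == REGION_HH] == 2).all()
        assert (env.h_count[env.region == REGION_LL] == 0).all()
        assert env.cell_contents((0, 0)) == ("H", "H")

    def test_mixed_quadrant_hl_fraction(self):
        env = build_quadrants(200, 200, seed=3)
        upper_right = env.h_count[:100, 100:]
        assert (upper_right == 1).mean() == pytest.approx(0.5, abs=0.02)

    def test_rejects_odd_dimensions(self):
        with pytest.raises(ValueError):
            build_quadrants(99, 100)


class TestGradient:
    def test_pure_edges(self):
        env = build_gradient(100, 50, seed=4)
        assert (env.h_count[:, 0] == 0).all()  # left edge: all L
        assert (env.h_count[:, -1] == 2).all()  # right edge: all H

    def test_middle_column_half_h(self):
        env = build_gradient(3, 4000, seed=5)
        assert env.h_count[:, 1].mean() / 2 == pytest.approx(0.5, abs=0.03)

    def test_expected_h_fraction_increases_with_column(self):
        env = build_gradient(100, 400, seed=6)
        col_means = env.h_count.mean(axis=0)
        slope = np.polyfit(np.arange(100), col_means, 1)[0]
        assert slope == pytest.approx(2 / 99, rel=0.05)

    def test_rejects_too_narrow(self):
        with pytest.raises(ValueError):
            build_gradient(1, 10)


class TestSwitch:
    def test_pure_quadrants_become_uniform_hl(self):
        env = build_quadrants(40, 40, seed=7)
        switched = switch_pure_quadrants_to_mixed(env)
        assert (switched.h_count[switched.region == REGION_HH] == 1).all()
        assert (switched.h_count[switched.region == REGION_LL] == 1).all()
        assert switched.cell_contents((0, 0)) == ("H", "L")

    def test_mixed_quadrants_untouched(self):
        env = build_quadrants(40, 40, seed=8)
        switched = switch_pure_quadrants_to_mixed(env)
        mixed = (env.region != REGION_HH) & (env.region != REGION_LL)
        assert (switched.h_count[mixed] == env.h_count[mixed]).all()

    def test_original_environment_not_mutated(self):
        env = build_quadrants(40, 40, seed=9)
        before = env.h_count.copy()
        switch_pure_quadrants_to_mixed(env)
        assert (env.h_count == before).all()

    def test_rejects_non_quadrant_environment(self):
        with pytest.raises(ValueError):
            switch_pure_quadrants_to_mixed(build_well_mixed(10, 10, seed=0))


class TestNeighbors:
    def test_interior_free_cell_has_eight(self):
        env = build_well_mixed(10, 10, seed=0)
        assert len(neighbors(env, (5, 5))) == 8

    def test_torus_wrap_at_corner(self):
        env = build_well_mixed(5, 5, seed=0)
        nbrs = neighbors(env, (0, 0))
        assert len(nbrs) == 8
        assert (4, 4) in nbrs

    def test_quadrant_corner_is_walled(self):
        env = build_quadrants(10, 10, seed=0)
        # (0, 0) sits in the corner of the HH quadrant: 3 reachable cells.
        assert neighbors(env, (0, 0)) == {(0, 1), (1, 0), (1, 1)}

    def test_single_cell_grid_has_no_moves(self):
        env = build_well_mixed(1, 1, seed=0)
        assert neighbors(env, (0, 0)) == set()

    def test_region_partition_respected(self):
        env = build_quadrants(20, 20, seed=1)
        # A cell at a quadrant edge can never reach the other region.
        for pos in [(9, 3), (3, 9), (10, 3), (9, 9)]:
            my_region = env.region[pos]
            for nbr in neighbors(env, pos):
                assert env.region[nbr] == my_region


def test_text_dump_codes_cells():
    env = build_quadrants(4, 4, seed=0)
    lines = env.to_text().splitlines()
    assert len(lines) == 4
    assert lines[0].split()[:2] == ["HH", "HH"]
    assert lines[3].split()[2:] == ["LL", "LL"]
    assert set("".join(lines).replace(" ", "")) <= set("HL")
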