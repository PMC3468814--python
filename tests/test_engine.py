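"""Tests for the choice rules and the move-consume-update scheduler."""

import numpy as np
import pytest

from rewardgrid import (
    LearnerParams,
    Simulation,
    SimulationConfig,
    Valuations,
    choose_food,
    choose_food_neighborhood,
    closed_form_vhat,
    FoodType,
    build_quadrants,
    build_well_mixed,
    run_until_equilibrium,
)
from rewardgrid.environment import REGION_LL


def make_vals(vh: float, vl: float) -> Valuations:
    v = Valuations(["H", "L"])
    v["H"] = vh
    v["L"] = vl
    return v


class TestChooseFood:
    def test_single_type_forces_choice(self, rng):
        vals = make_vals(0.0, 0.9)  # L valued higher, but only H on offer
        assert choose_food(["H", "H"], vals, epsilon=0.5, rng=rng) == "H"

    def test_noiseless_greedy(self, rng):
        vals = make_vals(0.9, 0.6)
        for _ in range(50):
            assert choose_food(["H", "L"], vals, epsilon=0.0, rng=rng) == "H"

    def test_tie_split_is_uniform(self, rng):
        vals = make_vals(0.0, 0.0)
        n = 100_000
        h = sum(choose_food(["H", "L"], vals, 0.05, rng) == "H" for _ in range(n))
        # 4-sigma binomial band around 1/2
        assert abs(h / n - 0.5) < 4 * 0.5 / np.sqrt(n)

    def test_epsilon_picks_lower_valued_type(self, rng):
        vals = make_vals(0.9, 0.6)
        n = 50_000
        eps = 0.2
        low = sum(choose_food(["H", "L"], vals, eps, rng) == "L" for _ in range(n))
        assert abs(low / n - eps) < 4 * np.sqrt(eps * (1 - eps) / n)

    def test_empty_cell_rejected(self, rng):
        with pytest.raises(ValueError):
            choose_food([], make_vals(0, 0), 0.05, rng)


class TestChooseFoodNeighborhood:
    def test_uniform_pool_forces_type(self, rng):
        vals = make_vals(0.0, 0.9)
        assert choose_food_neighborhood(["H"] * 18, vals, 0.5, rng) == "H"

    def test_full_noise_samples_items(self, rng):
        # epsilon = 1: the branch samples items, so a 50/50 pool gives 50/50
        # regardless of valuations.
        vals = make_vals(0.0, 0.9)
        pool = ["H"] * 9 + ["L"] * 9
        n = 50_000
        h = sum(choose_food_neighborhood(pool, vals, 1.0, rng) == "H"
                for _ in range(n))
        assert abs(h / n - 0.5) < 4 * 0.5 / np.sqrt(n)

    def test_item_weighted_noise_branch(self, rng):
        # 15 H vs 3 L: under epsilon=1, H frequency tracks item abundance.
        vals = make_vals(0.0, 0.9)
        pool = ["H"] * 15 + ["L"] * 3
        n = 30_000
        h = sum(choose_food_neighborhood(pool, vals, 1.0, rng) == "H"
                for _ in range(n))
        assert abs(h / n - 15 / 18) < 4 * np.sqrt((15 / 18) * (3 / 18) / n)

    def test_greedy_over_present_types(self, rng):
        vals = make_vals(0.9, 0.6)
        assert choose_food_neighborhood(["H", "L", "L"], vals, 0.0, rng) == "H"
        # Highest-valued type absent: greedy falls back to what is there.
        assert choose_food_neighborhood(["L", "L"], vals, 0.0, rng) == "L"


def forced_h_config(**kw) -> SimulationConfig:
    defaults = dict(scenario="base_case", width=10, height=10, n_agents=5,
                    epsilon=0.05, seed=3, max_steps=500)
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestStep:
    def test_forced_exposure_reproduces_closed_form(self):
        """An agent that can only ever consume H must track the analytic
        learning curve exactly, step by step."""
        env = build_well_mixed(10, 10, seed=0, p_high=1.0)  # all cells HH
        cfg = forced_h_config()
        sim = Simulation(env, cfg, record=True)
        for _ in range(30):
            sim.step()
        _, vh, _ = sim.trajectory_arrays()
        params = LearnerParams(alpha=cfg.alpha)
        food = FoodType("H", cfg.p_high)
        for k in range(1, 31):
            expected = closed_form_vhat(k, params, food)
            assert vh[k - 1] == pytest.approx(expected, abs=1e-12)

    def test_one_record_per_agent_per_step(self):
        env = build_well_mixed(10, 10, seed=1)
        sim = Simulation(env, forced_h_config(n_agents=7), record=True)
        for _ in range(4):
            sim.step()
        consumed, vh, vl = sim.trajectory_arrays()
        assert consumed.shape == vh.shape == vl.shape == (4, 7)
        frame = sim.trajectory_frame()
        assert len(frame) == 28

    def test_valuations_bounded_by_asymptote(self):
        env = build_well_mixed(20, 20, seed=2)
        cfg = forced_h_config(n_agents=50, width=20, height=20)
        sim = Simulation(env, cfg)
        for _ in range(300):
            sim.step()
            assert (sim.vhat_h >= 0).all() and (sim.vhat_l >= 0).all()
            assert (sim.vhat_h <= cfg.p_high + 1e-12).all()
            assert (sim.vhat_l <= cfg.p_low + 1e-12).all()

    def test_single_cell_grid_movement_is_noop(self):
        env = build_well_mixed(1, 1, seed=0)
        sim = Simulation(env, forced_h_config(width=1, height=1, n_agents=3))
        sim.step()
        assert (sim.rows == 0).all() and (sim.cols == 0).all()

    def test_region_locked_agents_stay_in_region(self):
        env = build_quadrants(20, 20, seed=4)
        cfg = forced_h_config(scenario="quadrants", width=20, height=20,
                              n_agents=40)
        sim = Simulation(env, cfg)
        start_regions = env.region[sim.rows, sim.cols].copy()
        for _ in range(100):
            sim.step()
        assert (env.region[sim.rows, sim.cols] == start_regions).all()


class TestEquilibrium:
    def test_alpha_one_equilibrates_immediately(self):
        env = build_well_mixed(10, 10, seed=5, p_high=1.0)
        cfg = forced_h_config(alpha=1.0)
        sim = Simulation(env, cfg)
        run_until_equilibrium(sim)
        assert sim.equilibrated
        # One jump to the fixed point, then a window of zero deltas.
        assert sim.step_count <= cfg.equilibrium_window + 1

    def test_base_case_equilibrates_within_a_few_hundred_steps(self):
        env = build_well_mixed(30, 30, seed=6)
        cfg = forced_h_config(width=30, height=30, n_agents=60, max_steps=2000)
        sim = Simulation(env, cfg)
        _, steps = run_until_equilibrium(sim)
        assert sim.equilibrated and steps < 1000

    def test_ll_region_agents_never_learn_h(self):
        """Agents confined to the pure-L quadrant keep vhat_H = 0 exactly."""
        env = build_quadrants(20, 20, seed=7)
        cfg = forced_h_config(scenario="quadrants", width=20, height=20,
                              n_agents=30, max_steps=2000)
        rng = np.random.default_rng(0)
        rows, cols = np.nonzero(env.region == REGION_LL)
        idx = rng.integers(len(rows), size=cfg.n_agents)
        sim = Simulation(env, cfg, rng=rng,
                         positions=np.column_stack([rows[idx], cols[idx]]))
        run_until_equilibrium(sim)
        assert sim.equilibrated
        assert (sim.vhat_h == 0.0).all()
        assert sim.vhat_l.mean() == pytest.approx(cfg.p_low, abs=1e-3)


def test_determinism_same_seed_bitwise_identical():
    cfg = forced_h_config(n_agents=20)

    def one_run():
        env = build_well_mixed(10, 10, seed=42)
        sim = Simulation(env, cfg, rng=np.random.default_rng(99), record=True)
        for _ in range(50):
            sim.step()
        return sim.trajectory_arrays()

    a, b = one_run(), one_run()
    for x, y in zip(a, b):
        assert (x == y).all()
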