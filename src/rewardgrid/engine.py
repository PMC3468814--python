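"""Simulation engine: move -> consume -> update scheduler and choice rules.

Each round has three phases.  (1) Every agent moves to a uniformly random
reachable Moore-adjacent cell.  (2) Every agent consumes one food item.  In
two-option cells the agent takes the type with the higher internal valuation,
except with probability ``epsilon`` it takes the lower-valued type
(exact ties split uniformly); pure cells force the only type present.  In
the gradient scenario agents instead choose over the 3x3 neighborhood's item
pool: greedy over the types present with probability 1 - epsilon, a
uniformly random *item* from the pool with probability epsilon.  (3) Every
agent applies the delta-rule update to the consumed food's valuation.

Because food never depletes and cells have no occupancy limit, agents do not
interact, so the nominally random per-phase agent orderings have no
observable effect; the engine exploits this and processes all agents as
simultaneous numpy array operations.  A single seeded Generator drives every
draw, which makes runs bit-reproducible.

Equilibrium is operational: a run is at equilibrium once every agent's last
update magnitude ``|alpha * (beta*p - vhat)|`` has stayed at or below
``equilibrium_tol`` for ``equilibrium_window`` consecutive steps.  With
choice noise, exact "no change" happens only at the fixed points, which this
criterion detects without requiring exact float equality.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .environment import FOOD_H, FOOD_L, MOORE_OFFSETS, Environment
from .learning import Valuations

# Food codes used in vectorized state: 1 = H, 0 = L.
_CODE = {FOOD_H: 1, FOOD_L: 0}
_ID = {1: FOOD_H, 0: FOOD_L}


def choose_food(options, valuations, epsilon: float, rng) -> str:
    """Two-option cell choice rule (scalar reference implementation).

    ``options`` is the multiset of food ids in the cell.  With a single
    distinct type there is no decision.  With two, the higher-valued type is
    taken with probability 1 - epsilon and the lower-valued with probability
    epsilon; exact ties are broken uniformly at random.
    """
    if not options:
        raise ValueError("cannot choose from an empty cell")
    distinct = sorted(set(options))
    if len(distinct) == 1:
        return distinct[0]
    a, b = distinct
    va, vb = valuations[a], valuations[b]
    if va == vb:
        return a if rng.random() < 0.5 else b
    hi, lo = (a, b) if va > vb else (b, a)
    return lo if rng.random() < epsilon else hi


def choose_food_neighborhood(local_items, valuations, epsilon: float, rng) -> str:
    """Neighborhood choice rule (scalar reference implementation).

    ``local_items`` pools the items of the agent's cell and its 8 neighbors.
    With probability 1 - epsilon: the type with the highest valuation among
    types present (ties uniform).  With probability epsilon: the type of a
    uniformly random *item* in the pool, so the noise branch is weighted by
    local abundance.
    """
    items = list(local_items)
    if not items:
        raise ValueError("cannot choose from an empty neighborhood")
    if rng.random() < epsilon:
        return items[rng.integers(len(items))]
    present = sorted(set(items))
    best = max(valuations[t] for t in present)
    top = [t for t in present if valuations[t] == best]
    return top[rng.integers(len(top))]


class Simulation:
    """Vectorized population state for one run.

    Agent state is held in flat arrays over agents: positions ``rows`` /
    ``cols``, learning rates ``alpha``, responsivities ``beta_h`` /
    ``beta_l``, and valuations ``vhat_h`` / ``vhat_l``.  ``group`` carries an
    integer group code per agent (meaning assigned by the caller via
    ``group_labels``).
    """

    def __init__(
        self,
        env: Environment,
        config: SimulationConfig,
        rng: np.random.Generator | np.random.SeedSequence | int | None = None,
        positions: np.ndarray | None = None,
        alpha: np.ndarray | float | None = None,
        beta_h: np.ndarray | float = 1.0,
        beta_l: np.ndarray | float = 1.0,
        group: np.ndarray | None = None,
        group_labels: dict[int, str] | None = None,
        choice_rule: str = "pairwise",
        record: bool = False,
    ) -> None:
        if choice_rule not in ("pairwise", "neighborhood"):
            raise ValueError(f"unknown choice rule {choice_rule!r}")
        self.env = env
        self.config = config
        self.choice_rule = choice_rule
        self.rng = (
            rng
            if isinstance(rng, np.random.Generator)
            else np.random.default_rng(config.seed if rng is None else rng)
        )
        n = config.n_agents
        if positions is None:
            rows = self.rng.integers(env.height, size=n)
            cols = self.rng.integers(env.width, size=n)
        else:
            rows = np.asarray(positions)[:, 0].copy()
            cols = np.asarray(positions)[:, 1].copy()
            if len(rows) != n:
                raise ValueError("positions length != n_agents")
        self.rows = rows.astype(np.int64)
        self.cols = cols.astype(np.int64)
        self.alpha = np.broadcast_to(
            np.asarray(config.alpha if alpha is None else alpha, dtype=float), (n,)
        ).copy()
        self.beta_h = np.broadcast_to(np.asarray(beta_h, dtype=float), (n,)).copy()
        self.beta_l = np.broadcast_to(np.asarray(beta_l, dtype=float), (n,)).copy()
        self.vhat_h = np.zeros(n)
        self.vhat_l = np.zeros(n)
        self.group = (
            np.zeros(n, dtype=np.int16) if group is None else np.asarray(group, np.int16)
        )
        self.group_labels = group_labels or {0: "all"}
        # Region of each agent is fixed under region-locked mobility.
        self.agent_region = self.env.region[self.rows, self.cols].copy()

        self.step_count = 0
        self.equilibrated = False
        self._calm_streak = 0
        self.last_delta = np.full(n, np.inf)

        self.record = record
        self._traj_consumed: list[np.ndarray] = []
        self._traj_vh: list[np.ndarray] = []
        self._traj_vl: list[np.ndarray] = []

        self._offsets = np.array(MOORE_OFFSETS, dtype=np.int64)
        if config.allow_stay:
            self._offsets = np.vstack([self._offsets, [[0, 0]]])
        self._nbhd_cache: tuple[int, np.ndarray, np.ndarray] | None = None

    # ------------------------------------------------------------------ #
    # environment switching

    def set_environment(self, env: Environment) -> None:
        """Swap the food environment mid-run (exposure switch).

        Agent positions and valuations are untouched; the neighborhood item
        cache is invalidated.  Region geometry must be unchanged.
        """
        if env.h_count.shape != self.env.h_count.shape:
            raise ValueError("replacement environment has a different shape")
        self.env = env
        self._nbhd_cache = None
        self.agent_region = env.region[self.rows, self.cols].copy()

    # ------------------------------------------------------------------ #
    # per-round phases

    def _move(self) -> None:
        env = self.env
        n = len(self.rows)
        cand_r = self.rows[:, None] + self._offsets[None, :, 0]
        cand_c = self.cols[:, None] + self._offsets[None, :, 1]
        valid = np.ones(cand_r.shape, dtype=bool)
        if env.wrap_rows:
            cand_r %= env.height
        else:
            valid &= (cand_r >= 0) & (cand_r < env.height)
            cand_r = np.clip(cand_r, 0, env.height - 1)
        if env.wrap_cols:
            cand_c %= env.width
        else:
            valid &= (cand_c >= 0) & (cand_c < env.width)
            cand_c = np.clip(cand_c, 0, env.width - 1)
        # Degenerate 1-wide axes: wrapping can map a neighbor onto the
        # current cell; such "moves" are not moves.
        if env.height == 1 or env.width == 1:
            valid &= ~((cand_r == self.rows[:, None]) & (cand_c == self.cols[:, None]))
        if env.region_locked:
            valid &= env.region[cand_r, cand_c] == self.agent_region[:, None]
        n_valid = valid.sum(axis=1)
        movable = n_valid > 0
        if not movable.any():
            return
        # Pick the k-th valid candidate, k uniform in [0, n_valid).
        k = np.floor(self.rng.random(n) * n_valid).astype(np.int64)
        k = np.minimum(k, np.maximum(n_valid - 1, 0))
        csum = np.cumsum(valid, axis=1)
        sel = (csum <= k[:, None]).sum(axis=1)
        idx = np.arange(n)
        self.rows[movable] = cand_r[idx[movable], sel[movable]]
        self.cols[movable] = cand_c[idx[movable], sel[movable]]

    def _consume_pairwise(self) -> np.ndarray:
        hc = self.env.h_count[self.rows, self.cols]
        food = np.where(hc == 2, 1, 0).astype(np.int8)
        mixed = hc == 1
        m = int(mixed.sum())
        if m:
            vh = self.vhat_h[mixed]
            vl = self.vhat_l[mixed]
            tie_coin = self.rng.random(m) < 0.5
            greedy = np.where(vh > vl, 1, np.where(vl > vh, 0, tie_coin)).astype(np.int8)
            flip = self.rng.random(m) < self.config.epsilon
            food[mixed] = np.where(flip, 1 - greedy, greedy)
        return food

    def _neighborhood_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-cell 3x3 pooled H-item and total-item counts (cached)."""
        if self._nbhd_cache is not None and self._nbhd_cache[0] == id(self.env):
            return self._nbhd_cache[1], self._nbhd_cache[2]
        env = self.env
        h = env.h_count.astype(np.int64)
        ones = np.ones_like(h)

        def pooled(a: np.ndarray) -> np.ndarray:
            out = np.zeros_like(a)
            for dr in (-1, 0, 1):
                rolled_r = np.roll(a, dr, axis=0)
                if not env.wrap_rows:
                    if dr == 1:
                        rolled_r[0, :] = 0
                    elif dr == -1:
                        rolled_r[-1, :] = 0
                for dc in (-1, 0, 1):
                    rolled = np.roll(rolled_r, dc, axis=1)
                    if not env.wrap_cols:
                        if dc == 1:
                            rolled[:, 0] = 0
                        elif dc == -1:
                            rolled[:, -1] = 0
                    out += rolled
            return out

        n_h = pooled(h)
        n_items = pooled(ones) * env.items_per_cell
        self._nbhd_cache = (id(self.env), n_h, n_items)
        return n_h, n_items

    def _consume_neighborhood(self) -> np.ndarray:
        n_h_grid, n_items_grid = self._neighborhood_counts()
        n_h = n_h_grid[self.rows, self.cols]
        n_tot = n_items_grid[self.rows, self.cols]
        n_l = n_tot - n_h
        n = len(n_h)
        has_h = n_h > 0
        has_l = n_l > 0
        tie_coin = self.rng.random(n) < 0.5
        greedy = np.where(
            self.vhat_h > self.vhat_l,
            1,
            np.where(self.vhat_l > self.vhat_h, 0, tie_coin),
        ).astype(np.int8)
        # Greedy is restricted to types actually present in the pool.
        greedy = np.where(~has_h, 0, np.where(~has_l, 1, greedy))
        random_item = (self.rng.random(n) < n_h / n_tot).astype(np.int8)
        eps_branch = self.rng.random(n) < self.config.epsilon
        return np.where(eps_branch, random_item, greedy).astype(np.int8)

    def step(self) -> None:
        """Advance one round: move, consume, update; record trajectories."""
        self._move()
        if self.choice_rule == "pairwise":
            food = self._consume_pairwise()
        else:
            food = self._consume_neighborhood()
        is_h = food == 1
        target = np.where(is_h, self.beta_h * self.config.p_high,
                          self.beta_l * self.config.p_low)
        current = np.where(is_h, self.vhat_h, self.vhat_l)
        delta = self.alpha * (target - current)
        new = current + delta
        self.vhat_h = np.where(is_h, new, self.vhat_h)
        self.vhat_l = np.where(is_h, self.vhat_l, new)
        self.last_delta = np.abs(delta)
        self.last_food = food
        self.step_count += 1

        if np.all(self.last_delta <= self.config.equilibrium_tol):
            self._calm_streak += 1
        else:
            self._calm_streak = 0
        if self._calm_streak >= self.config.equilibrium_window:
            self.equilibrated = True

        if self.record:
            self._traj_consumed.append(food.copy())
            self._traj_vh.append(self.vhat_h.copy())
            self._traj_vl.append(self.vhat_l.copy())

    # ------------------------------------------------------------------ #
    # outputs

    def valuations_of(self, agent_id: int) -> Valuations:
        """The named-food view of one agent's current valuations."""
        v = Valuations([FOOD_H, FOOD_L])
        v[FOOD_H] = float(self.vhat_h[agent_id])
        v[FOOD_L] = float(self.vhat_l[agent_id])
        return v

    def trajectory_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(consumed, vhat_H, vhat_L) arrays of shape (steps, n_agents)."""
        if not self.record:
            raise RuntimeError("run was not recorded; pass record=True")
        return (
            np.array(self._traj_consumed, dtype=np.int8),
            np.array(self._traj_vh),
            np.array(self._traj_vl),
        )

    def trajectory_frame(self, run_id: int = 0) -> pd.DataFrame:
        """Tidy per-agent-per-step trajectory table."""
        consumed, vh, vl = self.trajectory_arrays()
        n_steps, n = consumed.shape
        steps = np.repeat(np.arange(1, n_steps + 1), n)
        agents = np.tile(np.arange(n), n_steps)
        labels = np.array([self.group_labels[g] for g in self.group])
        return pd.DataFrame(
            {
                "run_id": run_id,
                "step": steps,
                "agent_id": agents,
                "group_label": np.tile(labels, n_steps),
                "food_consumed": np.where(consumed.ravel() == 1, FOOD_H, FOOD_L),
                "vhat_H": vh.ravel(),
                "vhat_L": vl.ravel(),
            }
        )


def run_until_equilibrium(sim: Simulation, callback=None) -> tuple[Simulation, int]:
    """Step ``sim`` until equilibrium or ``max_steps`` (flagged, not raised).

    ``callback(sim)`` is invoked after every step; use it to harvest
    population statistics without recording full trajectories.
    Returns ``(sim, steps_taken)``; ``sim.equilibrated`` tells whether the
    stop was equilibrium or exhaustion.
    """
    while not sim.equilibrated and sim.step_count < sim.config.max_steps:
        sim.step()
        if callback is not None:
            callback(sim)
    return sim, sim.step_count


def food_id_of(code: int) -> str:
    """Map the engine's integer food code (1/0) to its id ('H'/'L')."""
    return _ID[int(code)]
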