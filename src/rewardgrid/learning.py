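"""Per-agent reward-valuation learning rule.

Agents learn the reward value of food types by a delta-rule
(temporal-difference) update driven by reward-prediction error.  Each food
type *j* carries an intrinsic palatability ``p_j``; agent *i* scales it by a
personal responsivity ``beta_ij``, so the agent's true reward for food *j* is
``beta_ij * p_j``.  After each consumption the internal estimate ``vhat``
moves a fraction ``alpha`` (the learning rate) of the way toward that target:

    vhat <- vhat + alpha * (beta * p - vhat)

Starting from ``vhat = 0``, *n* consumptions of the same food give the closed
form ``beta * p * (1 - (1 - alpha)**n)`` — a geometric approach to the fixed
point ``beta * p``.  Both the single-step update and the closed form are
exposed here; the closed form doubles as an analytic oracle for the
simulation engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

__all__ = [
    "FoodType",
    "LearnerParams",
    "Valuations",
    "td_update",
    "closed_form_vhat",
]


@dataclass(frozen=True)
class FoodType:
    """A food category with an intrinsic palatability ``p > 0``.

    Palatability is an abstract reward scale (e.g. energy density); the
    defaults used throughout the experiments are L: 0.6 and H: 0.9, giving a
    high-to-low palatability ratio theta = 1.5.
    """

    id: str
    palatability: float

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("food id must be a non-empty string")
        if not self.palatability > 0:
            raise ValueError(
                f"palatability must be > 0, got {self.palatability!r}"
            )


@dataclass(frozen=True)
class LearnerParams:
    """An agent's learning rate ``alpha`` and per-food responsivities ``beta``.

    ``beta`` maps food ids to positive multipliers; any food not listed gets
    the neutral responsivity 1.0.
    """

    alpha: float
    beta: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha!r}")
        for food_id, b in self.beta.items():
            if not b > 0:
                raise ValueError(
                    f"beta for food {food_id!r} must be > 0, got {b!r}"
                )

    def beta_for(self, food_id: str) -> float:
        """Responsivity for ``food_id`` (1.0 if not explicitly set)."""
        return self.beta.get(food_id, 1.0)


class Valuations:
    """Internal reward estimates ``vhat[j]`` for every food type.

    Every food type present in the environment gets an entry from the start,
    initialised to exactly 0 — agents begin naive about all foods.
    """

    __slots__ = ("vhat",)

    def __init__(self, food_ids) -> None:
        self.vhat: dict[str, float] = {fid: 0.0 for fid in food_ids}

    def __getitem__(self, food_id: str) -> float:
        return self.vhat[food_id]

    def __setitem__(self, food_id: str, value: float) -> None:
        if value < 0:
            raise ValueError(f"vhat must be >= 0, got {value!r}")
        self.vhat[food_id] = value

    def __contains__(self, food_id: str) -> bool:
        return food_id in self.vhat

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Valuations({self.vhat!r})"


def td_update(vhat_j: float, params: LearnerParams, food: FoodType) -> float:
    """One delta-rule update of the estimate for ``food`` after consuming it.

    Returns ``vhat_j + alpha * (beta * p - vhat_j)``; pure function, no state
    is mutated.  ``beta * p`` is the fixed point: the prediction error there
    is zero and the estimate no longer moves.
    """
    target = params.beta_for(food.id) * food.palatability
    return vhat_j + params.alpha * (target - vhat_j)


def closed_form_vhat(
    n_updates: int, params: LearnerParams, food: FoodType
) -> float:
    """Value after ``n_updates`` consecutive updates starting from vhat = 0.

    Analytic solution of the recursion: ``beta * p * (1 - (1 - alpha)**n)``.
    Equals ``n_updates``-fold application of :func:`td_update` to within
    floating-point tolerance, and is used as the independent oracle in tests
    of the simulation engine's forced-exposure paths.
    """
    if n_updates < 0:
        raise ValueError(f"n_updates must be >= 0, got {n_updates!r}")
    target = params.beta_for(food.id) * food.palatability
    return target * (1.0 - (1.0 - params.alpha) ** n_updates)
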