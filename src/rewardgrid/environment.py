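"""Spatial food environments: well-mixed torus, walled quadrants, gradient.

Every environment is a rectangular grid of cells, each holding exactly two
food items drawn from two types, high-palatability ``H`` and
low-palatability ``L``.  Cell contents are stored compactly as the per-cell
count of H items (0, 1 or 2).  Food is non-depleting: the two items in a
cell are standing options, not consumables, so composition is constant
within a phase of a run.

Three layouts are provided:

* **well-mixed** — every item independently H or L with probability 1/2,
  giving the binomial HH/HL/LL cell mix (1/4, 1/2, 1/4); full torus
  wrapping, free movement.
* **quadrants** — four equal walled regions: upper-left pure HH, lower-right
  pure LL, the other two well-mixed; agents are confined to their region and
  outer torus wrapping is off.
* **gradient** — the probability that an item is H rises linearly with
  column index from 0 at the left edge to 1 at the right edge; rows wrap but
  columns do not, so the two pure edges are real boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

FOOD_H = "H"
FOOD_L = "L"

#: Moore 8-neighborhood offsets (row, col); the current cell is excluded.
MOORE_OFFSETS: tuple[tuple[int, int], ...] = (
    (-1, -1), (-1, 0), (-1, 1),
    (0, -1), (0, 1),
    (1, -1), (1, 0), (1, 1),
)

# Quadrant region ids.
REGION_HH = 0      # upper-left, pure H
REGION_MIX_UR = 1  # upper-right, well-mixed
REGION_MIX_LL = 2  # lower-left, well-mixed
REGION_LL = 3      # lower-right, pure L


@dataclass
class Environment:
    """Grid of food cells plus region structure and mobility rules.

    ``h_count[r, c]`` is the number of H items among the two in cell
    ``(r, c)``.  ``region`` partitions cells into region ids; with
    ``region_locked`` mobility an agent's reachable set is exactly its
    region.  ``wrap_rows`` / ``wrap_cols`` control torus wrapping per axis.
    """

    h_count: np.ndarray
    region: np.ndarray
    region_locked: bool
    wrap_rows: bool
    wrap_cols: bool
    kind: str
    items_per_cell: int = 2
    food_ids: tuple[str, str] = (FOOD_H, FOOD_L)

    def __post_init__(self) -> None:
        self.h_count = np.asarray(self.h_count, dtype=np.int8)
        self.region = np.asarray(self.region, dtype=np.int16)
        if self.h_count.shape != self.region.shape:
            raise ValueError("h_count and region shapes differ")
        if self.h_count.min() < 0 or self.h_count.max() > self.items_per_cell:
            raise ValueError("h_count out of range")

    @property
    def height(self) -> int:
        return self.h_count.shape[0]

    @property
    def width(self) -> int:
        return self.h_count.shape[1]

    def cell_contents(self, position: tuple[int, int]) -> tuple[str, ...]:
        """The multiset of food ids in a cell, as a sorted tuple."""
        h = int(self.h_count[position])
        return (FOOD_H,) * h + (FOOD_L,) * (self.items_per_cell - h)

    def to_text(self) -> str:
        """Plain-text dump, one line per row, cells coded HH/HL/LL."""
        codes = {2: "HH", 1: "HL", 0: "LL"}
        return "\n".join(
            " ".join(codes[int(h)] for h in row) for row in self.h_count
        )


def _check_dims(width: int, height: int) -> None:
    if width < 1 or height < 1:
        raise ValueError(f"grid dimensions must be >= 1, got {width}x{height}")


def build_well_mixed(
    width: int = 100,
    height: int = 100,
    seed: int | np.random.Generator | None = 0,
    p_high: float = 0.5,
) -> Environment:
    """Well-mixed torus: each of a cell's 2 items is H with prob ``p_high``."""
    _check_dims(width, height)
    rng = np.random.default_rng(seed)
    h_count = rng.binomial(2, p_high, size=(height, width)).astype(np.int8)
    region = np.zeros((height, width), dtype=np.int16)
    return Environment(
        h_count=h_count,
        region=region,
        region_locked=False,
        wrap_rows=True,
        wrap_cols=True,
        kind="well_mixed",
    )


def build_quadrants(
    width: int = 100,
    height: int = 100,
    seed: int | np.random.Generator | None = 0,
    p_high_mixed: float = 0.5,
) -> Environment:
    """Four walled quadrants: pure HH (upper-left), pure LL (lower-right),
    two well-mixed; region-locked movement, no outer wrapping."""
    _check_dims(width, height)
    if width % 2 or height % 2:
        raise ValueError(
            f"quadrant layout needs even dimensions, got {width}x{height}"
        )
    rng = np.random.default_rng(seed)
    h2, w2 = height // 2, width // 2
    h_count = rng.binomial(2, p_high_mixed, size=(height, width)).astype(np.int8)
    h_count[:h2, :w2] = 2  # upper-left: pure H
    h_count[h2:, w2:] = 0  # lower-right: pure L
    region = np.empty((height, width), dtype=np.int16)
    region[:h2, :w2] = REGION_HH
    region[:h2, w2:] = REGION_MIX_UR
    region[h2:, :w2] = REGION_MIX_LL
    region[h2:, w2:] = REGION_LL
    return Environment(
        h_count=h_count,
        region=region,
        region_locked=True,
        wrap_rows=False,
        wrap_cols=False,
        kind="quadrants",
    )


def build_gradient(
    width: int = 100,
    height: int = 100,
    seed: int | np.random.Generator | None = 0,
) -> Environment:
    """Gradient space: item in column x is H with probability x/(width-1).

    Column 0 is 100% L and the last column 100% H.  Rows wrap (cylinder);
    columns do not, so the pure edges are genuine boundaries.
    """
    _check_dims(width, height)
    if width < 2:
        raise ValueError("gradient space needs width >= 2")
    rng = np.random.default_rng(seed)
    p = np.arange(width, dtype=float) / (width - 1)
    h_count = rng.binomial(2, p[None, :], size=(height, width)).astype(np.int8)
    region = np.zeros((height, width), dtype=np.int16)
    return Environment(
        h_count=h_count,
        region=region,
        region_locked=False,
        wrap_rows=True,
        wrap_cols=False,
        kind="gradient",
    )


def switch_pure_quadrants_to_mixed(
    env: Environment, seed: int | None = None
) -> Environment:
    """Mid-run exposure switch: both pure quadrants become uniform HL.

    Every cell of the formerly pure-HH and pure-LL regions now holds exactly
    one H and one L item; the two originally mixed quadrants are untouched.
    The result is deterministic, so ``seed`` is accepted but unused.  Agent
    state (positions, valuations) lives in the simulation and is unaffected.
    """
    del seed
    if env.kind != "quadrants":
        raise ValueError(
            f"can only switch a quadrant environment, got kind={env.kind!r}"
        )
    h_count = env.h_count.copy()
    pure = (env.region == REGION_HH) | (env.region == REGION_LL)
    h_count[pure] = 1
    return Environment(
        h_count=h_count,
        region=env.region.copy(),
        region_locked=env.region_locked,
        wrap_rows=env.wrap_rows,
        wrap_cols=env.wrap_cols,
        kind="quadrants_switched",
    )


def neighbors(
    env: Environment, position: tuple[int, int], radius: int = 1
) -> set[tuple[int, int]]:
    """Reachable Moore neighbors of ``position``.

    Torus wrapping applies per axis where enabled; with region-locked
    mobility only cells in the agent's own region are reachable.  The
    current cell is not included (agents must move if any neighbor exists).
    """
    if radius != 1:
        raise ValueError("only radius=1 adjacency is supported")
    r, c = position
    if not (0 <= r < env.height and 0 <= c < env.width):
        raise ValueError(f"position {position!r} outside grid")
    my_region = env.region[r, c]
    out: set[tuple[int, int]] = set()
    for dr, dc in MOORE_OFFSETS:
        nr, nc = r + dr, c + dc
        if env.wrap_rows:
            nr %= env.height
        elif not 0 <= nr < env.height:
            continue
        if env.wrap_cols:
            nc %= env.width
        elif not 0 <= nc < env.width:
            continue
        if (nr, nc) == (r, c):
            continue  # wrapped back onto itself (degenerate 1-wide axis)
        if env.region_locked and env.region[nr, nc] != my_region:
            continue
        out.add((nr, nc))
    return out
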