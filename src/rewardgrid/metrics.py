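"""Learning-time metrics and replicate statistics.

"Time to learn" a food is the first step at which the agent's valuation for
it reaches its asymptote ``beta * p`` minus a small tolerance (default
0.01) and stays there.  Because the delta rule moves valuations
monotonically toward the asymptote from below, a first crossing is also a
permanent one.  Agents that never cross within the run horizon are
censored, and censoring is reported rather than silently dropped.

The lock-in (learning) ratio for a group of agents is the mean time to
learn the *second* food they were exposed to, divided by the mean time to
learn their *first*; values above 1 quantify lock-in.
"""

from __future__ import annotations

import math

import numpy as np

CENSORED = -1  # sentinel used in vectorized crossing-step arrays


def time_to_learn(
    vhat_series,
    asymptote: float,
    tol: float = 0.01,
    v0: float = 0.0,
) -> int | None:
    """First step at which a valuation series reaches ``asymptote - tol``.

    ``vhat_series[t]`` is the valuation *after* step ``t + 1``; ``v0`` is the
    value before any step (0 for naive agents).  Returns the 1-based step
    count, 0 if the series already starts at or above the threshold, or
    ``None`` (censored) if the threshold is never reached.
    """
    if tol >= asymptote:
        raise ValueError(f"tol ({tol}) must be smaller than the asymptote ({asymptote})")
    thresh = asymptote - tol
    if v0 >= thresh:
        return 0
    arr = np.asarray(vhat_series, dtype=float)
    hits = np.nonzero(arr >= thresh)[0]
    if hits.size == 0:
        return None
    return int(hits[0]) + 1


def first_crossing_update(
    crossed: np.ndarray, values: np.ndarray, thresh, step: int
) -> None:
    """Record ``step`` for agents whose ``values`` first reach ``thresh``.

    Online companion of :func:`time_to_learn` for vectorized runs:
    ``crossed`` holds the crossing step per agent (``CENSORED`` until it
    happens) and is updated in place.
    """
    newly = (crossed == CENSORED) & (values >= thresh)
    crossed[newly] = step


def learning_ratio(group_times_second, group_times_first) -> float | None:
    """Mean second-food learning time over mean first-food learning time.

    Inputs are uncensored per-agent step counts.  Returns ``None`` when the
    second-food sample is empty (all agents censored) — undefined rather
    than infinite.  An empty first-food sample is a caller error.
    """
    first = [t for t in group_times_first if t is not None]
    second = [t for t in group_times_second if t is not None]
    if not first:
        raise ValueError("first-food sample is empty")
    if not second:
        return None
    mean_first = sum(first) / len(first)
    if mean_first == 0:
        return math.inf if sum(second) else None
    return (sum(second) / len(second)) / mean_first


def replicate_stats(per_run_values) -> tuple[float, float]:
    """Sample mean and standard error (SD / sqrt(n)) across replicate runs."""
    arr = np.asarray(list(per_run_values), dtype=float)
    if arr.size < 2:
        raise ValueError("standard error needs at least 2 replicates")
    return float(arr.mean()), float(arr.std(ddof=1) / math.sqrt(arr.size))
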