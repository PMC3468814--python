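"""Scripted experiment drivers.

Five experiments, each run as ``n_replicates`` independent seeded
simulations and aggregated with 15-run-style means and standard errors:

* **base_case** — homogeneous agents on a well-mixed torus; population mean
  valuation curves converge to the intrinsic palatabilities p_H and p_L.
* **hetero_types** — four agent types crossing learning rate
  (alpha in {0.4, 0.1}) with H-responsivity (beta_H in {2.0, 0.5});
  per-type curves converge to beta_H * p_H at alpha-dependent rates.
* **quadrants** — four walled regions (pure HH, pure LL, two mixed);
  region-mean curves show lock-in in the mixed regions.
* **movement** — two-phase exposure switch: agents start in pure-HH,
  pure-LL or mixed quadrants, the pure quadrants are flipped to uniform HL
  once HH-origin agents finish learning, and per-origin learning ratios
  (second food vs first food) quantify lock-in.
* **gradient** — a left-to-right H-probability gradient with 3x3
  neighborhood choice; lock-in is measured against the initial exposure
  level (decile of starting-column H probability).

Replicate r of an experiment uses an RNG stream derived from
``(config.seed, r)`` only, so any single replicate can be reproduced in
isolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import environment as envmod
from .config import ExperimentSpec
from .engine import Simulation, run_until_equilibrium
from .environment import (
    REGION_HH,
    REGION_LL,
    REGION_MIX_UR,
    build_gradient,
    build_quadrants,
    build_well_mixed,
    switch_pure_quadrants_to_mixed,
)
from .metrics import CENSORED, first_crossing_update, replicate_stats

#: The four heterogeneity types: (label, alpha, beta_H); beta_L is 1.
HETERO_TYPES = (
    ("type1", 0.4, 2.0),  # fast learner, highly responsive to H
    ("type2", 0.4, 0.5),  # fast learner, low responsivity to H
    ("type3", 0.1, 2.0),  # slow learner, highly responsive to H
    ("type4", 0.1, 0.5),  # slow learner, low responsivity to H
)

QUADRANT_LABELS = {
    REGION_HH: "HH",
    REGION_MIX_UR: "HL",
    envmod.REGION_MIX_LL: "HL2",
    REGION_LL: "LL",
}

NOISE_SWEEP_EPSILONS = (0.05, 0.1, 0.2, 0.3, 0.4, 0.5)


def _replicate_rngs(spec: ExperimentSpec):
    """One (env_rng, sim_rng) pair per replicate, from independent streams."""
    out = []
    for child in spec.replicate_seeds():
        env_ss, sim_ss = child.spawn(2)
        out.append((np.random.default_rng(env_ss), np.random.default_rng(sim_ss)))
    return out


def _pad_stack(curves: list[np.ndarray]) -> np.ndarray:
    """Stack per-replicate curves, padding shorter runs with their final
    (converged) value so every step has all replicates."""
    n_steps = max(len(c) for c in curves)
    out = np.empty((len(curves), n_steps))
    for i, c in enumerate(curves):
        out[i, : len(c)] = c
        out[i, len(c):] = c[-1]
    return out


def _mean_se(stacked: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = stacked.mean(axis=0)
    if stacked.shape[0] < 2:  # SE undefined for a single replicate
        return mean, np.full_like(mean, np.nan)
    se = stacked.std(axis=0, ddof=1) / np.sqrt(stacked.shape[0])
    return mean, se


def _positions_in_region(env, region_id: int, count: int, rng) -> np.ndarray:
    rows, cols = np.nonzero(env.region == region_id)
    idx = rng.integers(len(rows), size=count)
    return np.column_stack([rows[idx], cols[idx]])


# --------------------------------------------------------------------- #
# base case


@dataclass
class BaseCaseResult:
    curves: pd.DataFrame
    terminal_vhat_h: float
    terminal_vhat_l: float
    equilibrium_flags: list[bool]
    per_replicate: pd.DataFrame

    def frames(self) -> dict[str, pd.DataFrame]:
        return {"curves": self.curves, "per_replicate": self.per_replicate}


def run_base_case(spec: ExperimentSpec) -> BaseCaseResult:
    """Homogeneous agents, well-mixed torus; population learning curves."""
    cfg = spec.config
    curves_h, curves_l, flags, terminal = [], [], [], []
    for rep, (env_rng, sim_rng) in enumerate(_replicate_rngs(spec)):
        env = build_well_mixed(cfg.width, cfg.height, seed=env_rng)
        sim = Simulation(env, cfg, rng=sim_rng)
        mh: list[float] = []
        ml: list[float] = []
        run_until_equilibrium(
            sim,
            callback=lambda s: (mh.append(s.vhat_h.mean()), ml.append(s.vhat_l.mean())),
        )
        curves_h.append(np.array(mh))
        curves_l.append(np.array(ml))
        flags.append(sim.equilibrated)
        terminal.append(
            {
                "replicate": rep,
                "steps": sim.step_count,
                "equilibrated": sim.equilibrated,
                "terminal_vhat_H": sim.vhat_h.mean(),
                "terminal_vhat_L": sim.vhat_l.mean(),
            }
        )
    sh, sl = _pad_stack(curves_h), _pad_stack(curves_l)
    mh_, seh = _mean_se(sh)
    ml_, sel = _mean_se(sl)
    curves = pd.DataFrame(
        {
            "step": np.arange(1, len(mh_) + 1),
            "mean_vhat_H": mh_,
            "se_vhat_H": seh,
            "mean_vhat_L": ml_,
            "se_vhat_L": sel,
        }
    )
    per_rep = pd.DataFrame(terminal)
    return BaseCaseResult(
        curves=curves,
        terminal_vhat_h=float(per_rep["terminal_vhat_H"].mean()),
        terminal_vhat_l=float(per_rep["terminal_vhat_L"].mean()),
        equilibrium_flags=flags,
        per_replicate=per_rep,
    )


# --------------------------------------------------------------------- #
# heterogeneous learner types


@dataclass
class HeteroResult:
    curves: pd.DataFrame
    final_vhat_h: dict[str, float]
    steps_to_90pct: pd.DataFrame  # per replicate x type mean crossing step
    equilibrium_flags: list[bool]

    def frames(self) -> dict[str, pd.DataFrame]:
        return {"curves": self.curves, "steps_to_90pct": self.steps_to_90pct}


def run_hetero_types(spec: ExperimentSpec) -> HeteroResult:
    """Four-type population on the well-mixed torus.

    The population splits evenly across the four (alpha, beta_H) types;
    beta_L is 1 for everyone.  Per-type mean curves converge to
    beta_H * p_H; per-replicate mean steps to reach 90% of that asymptote
    separate fast from slow learners.
    """
    cfg = spec.config
    n_types = len(HETERO_TYPES)
    per_type = cfg.n_agents // n_types
    n = per_type * n_types
    cfg = cfg.replace(n_agents=n)
    group = np.repeat(np.arange(n_types), per_type)
    alpha = np.array([HETERO_TYPES[g][1] for g in group])
    beta_h = np.array([HETERO_TYPES[g][2] for g in group])
    labels = {i: t[0] for i, t in enumerate(HETERO_TYPES)}
    asymptote = {t[0]: t[2] * cfg.p_high for t in HETERO_TYPES}

    type_curves: dict[str, list[np.ndarray]] = {t[0]: [] for t in HETERO_TYPES}
    rows90, finals, flags = [], {t[0]: [] for t in HETERO_TYPES}, []
    for rep, (env_rng, sim_rng) in enumerate(_replicate_rngs(spec)):
        env = build_well_mixed(cfg.width, cfg.height, seed=env_rng)
        sim = Simulation(
            env, cfg, rng=sim_rng, alpha=alpha, beta_h=beta_h,
            group=group, group_labels=labels,
        )
        thresh90 = 0.9 * beta_h * cfg.p_high
        crossed = np.full(n, CENSORED, dtype=np.int64)
        curves: dict[str, list[float]] = {t[0]: [] for t in HETERO_TYPES}

        def harvest(s: Simulation) -> None:
            first_crossing_update(crossed, s.vhat_h, thresh90, s.step_count)
            for g, lab in labels.items():
                curves[lab].append(float(s.vhat_h[group == g].mean()))

        run_until_equilibrium(sim, callback=harvest)
        flags.append(sim.equilibrated)
        row = {"replicate": rep}
        for g, lab in labels.items():
            type_curves[lab].append(np.array(curves[lab]))
            finals[lab].append(float(sim.vhat_h[group == g].mean()))
            tc = crossed[group == g]
            row[f"steps90_{lab}"] = float(tc[tc != CENSORED].mean())
        rows90.append(row)

    frames = {}
    n_steps = max(len(c) for lab in type_curves for c in type_curves[lab])
    curve_cols: dict[str, np.ndarray] = {"step": np.arange(1, n_steps + 1)}
    for lab, reps in type_curves.items():
        mean, se = _mean_se(_pad_stack(reps))
        pad = np.pad(mean, (0, n_steps - len(mean)), mode="edge")
        pad_se = np.pad(se, (0, n_steps - len(se)), mode="edge")
        curve_cols[f"mean_vhat_H_{lab}"] = pad
        curve_cols[f"se_vhat_H_{lab}"] = pad_se
    return HeteroResult(
        curves=pd.DataFrame(curve_cols),
        final_vhat_h={lab: float(np.mean(v)) for lab, v in finals.items()},
        steps_to_90pct=pd.DataFrame(rows90),
        equilibrium_flags=flags,
    )


# --------------------------------------------------------------------- #
# walled quadrants


@dataclass
class QuadrantsResult:
    curves: pd.DataFrame
    max_se: float
    terminal: pd.DataFrame
    equilibrium_flags: list[bool]

    def frames(self) -> dict[str, pd.DataFrame]:
        return {"curves": self.curves, "terminal": self.terminal}


def run_quadrants(spec: ExperimentSpec) -> QuadrantsResult:
    """Region-locked agents in the four-quadrant environment.

    Agents are seeded evenly across the quadrants and cannot leave them.
    Reported per region: replicate-mean valuation curves for both foods with
    per-step standard errors, and the maximum SE across every reported
    point (the reproducibility figure of merit).
    """
    cfg = spec.config
    region_ids = sorted(QUADRANT_LABELS)
    per_region = cfg.n_agents // len(region_ids)
    n = per_region * len(region_ids)
    cfg = cfg.replace(n_agents=n)
    group = np.repeat(np.arange(len(region_ids)), per_region)
    labels = {i: QUADRANT_LABELS[r] for i, r in enumerate(region_ids)}

    series: dict[str, list[np.ndarray]] = {
        f"{lab}_{food}": [] for lab in labels.values() for food in ("H", "L")
    }
    terminal_rows, flags = [], []
    for rep, (env_rng, sim_rng) in enumerate(_replicate_rngs(spec)):
        env = build_quadrants(cfg.width, cfg.height, seed=env_rng)
        positions = np.vstack(
            [
                _positions_in_region(env, r, per_region, sim_rng)
                for r in region_ids
            ]
        )
        sim = Simulation(
            env, cfg, rng=sim_rng, positions=positions,
            group=group, group_labels=labels,
        )
        curves: dict[str, list[float]] = {k: [] for k in series}

        def harvest(s: Simulation) -> None:
            for g, lab in labels.items():
                sel = group == g
                curves[f"{lab}_H"].append(float(s.vhat_h[sel].mean()))
                curves[f"{lab}_L"].append(float(s.vhat_l[sel].mean()))

        run_until_equilibrium(sim, callback=harvest)
        flags.append(sim.equilibrated)
        for k in series:
            series[k].append(np.array(curves[k]))
        row = {"replicate": rep, "steps": sim.step_count}
        for g, lab in labels.items():
            sel = group == g
            row[f"terminal_vhat_H_{lab}"] = float(sim.vhat_h[sel].mean())
            row[f"terminal_vhat_L_{lab}"] = float(sim.vhat_l[sel].mean())
        terminal_rows.append(row)

    n_steps = max(len(c) for reps in series.values() for c in reps)
    cols: dict[str, np.ndarray] = {"step": np.arange(1, n_steps + 1)}
    max_se = 0.0
    for k, reps in series.items():
        mean, se = _mean_se(_pad_stack(reps))
        cols[f"mean_vhat_{k}"] = np.pad(mean, (0, n_steps - len(mean)), mode="edge")
        cols[f"se_vhat_{k}"] = np.pad(se, (0, n_steps - len(se)), mode="edge")
        max_se = max(max_se, float(se.max()))
    return QuadrantsResult(
        curves=pd.DataFrame(cols),
        max_se=max_se,
        terminal=pd.DataFrame(terminal_rows),
        equilibrium_flags=flags,
    )


# --------------------------------------------------------------------- #
# two-phase movement experiment


@dataclass
class MovementResult:
    """Per-origin learning times and lock-in ratios, aggregated over runs.

    ``ratio_h`` is mean(LL-origin time to learn H after the switch) /
    mean(HH-origin time to learn H during initial exposure); ``ratio_l`` is
    the analogous HH/LL ratio for food L.  ``lockin`` maps each origin group
    to its own second-food/first-food ratio.
    """

    per_replicate: pd.DataFrame
    summary: pd.DataFrame
    ratio_h: float
    ratio_l: float
    lockin: dict[str, float]
    lockin_se: dict[str, float]
    censored: dict[str, int]
    phase1_steps: list[int]
    phase2_flags: list[bool]

    def frames(self) -> dict[str, pd.DataFrame]:
        return {"per_replicate": self.per_replicate, "summary": self.summary}


ORIGIN_REGIONS = {"HH": REGION_HH, "LL": REGION_LL, "HL": REGION_MIX_UR}


def run_movement(spec: ExperimentSpec) -> MovementResult:
    """Two-phase exposure-switch experiment.

    Phase 1: agents seeded evenly in the pure-HH, pure-LL and one mixed
    quadrant learn in place until the HH-origin group's mean valuation of H
    is within ``equilibrium_tol`` of p_H (its asymptote).  Phase 2: both
    pure quadrants flip to uniform one-H-one-L cells and the run continues
    until every origin group has learned its second food (or ``max_steps``
    post-switch, censoring the stragglers).  Second-food clocks start at the
    switch; mixed-origin agents, whose environment never changes, are
    clocked from the start on the food they consumed first vs the other.
    """
    cfg = spec.config
    ttl = spec.time_to_learn_tol
    origins = list(ORIGIN_REGIONS)
    n_groups = len(origins)
    base, extra = divmod(cfg.n_agents, n_groups)
    counts = [base + (1 if i < extra else 0) for i in range(n_groups)]
    labels = dict(enumerate(origins))

    rows, phase1_steps, phase2_flags = [], [], []
    censored = {o: 0 for o in origins}
    for rep, (env_rng, sim_rng) in enumerate(_replicate_rngs(spec)):
        env = build_quadrants(cfg.width, cfg.height, seed=env_rng)
        positions = np.vstack(
            [
                _positions_in_region(env, ORIGIN_REGIONS[o], c, sim_rng)
                for o, c in zip(origins, counts)
            ]
        )
        group = np.repeat(np.arange(n_groups), counts)
        sim = Simulation(
            env, cfg, rng=sim_rng, positions=positions,
            group=group, group_labels=labels,
        )
        n = cfg.n_agents
        thresh_h = cfg.p_high - ttl
        thresh_l = cfg.p_low - ttl
        cross_h = np.full(n, CENSORED, dtype=np.int64)
        cross_l = np.full(n, CENSORED, dtype=np.int64)
        first_food = np.full(n, CENSORED, dtype=np.int8)

        hh = group == origins.index("HH")
        ll = group == origins.index("LL")
        hl = group == origins.index("HL")

        # Phase 1: until HH-origin agents have completed learning H.
        stop_level = cfg.p_high - cfg.equilibrium_tol
        while sim.step_count < cfg.max_steps:
            sim.step()
            if sim.step_count == 1:
                first_food[:] = sim.last_food
            first_crossing_update(cross_h, sim.vhat_h, thresh_h, sim.step_count)
            first_crossing_update(cross_l, sim.vhat_l, thresh_l, sim.step_count)
            if sim.vhat_h[hh].mean() >= stop_level:
                break
        switch_step = sim.step_count
        phase1_steps.append(switch_step)

        sim.set_environment(switch_pure_quadrants_to_mixed(env))

        # Phase 2: until all second foods are learned or the horizon.
        def done() -> bool:
            return bool(
                (cross_l[hh] != CENSORED).all()
                and (cross_h[ll] != CENSORED).all()
                and (cross_h[hl] != CENSORED).all()
                and (cross_l[hl] != CENSORED).all()
            )

        while not done() and sim.step_count - switch_step < cfg.max_steps:
            sim.step()
            first_crossing_update(cross_h, sim.vhat_h, thresh_h, sim.step_count)
            first_crossing_update(cross_l, sim.vhat_l, thresh_l, sim.step_count)
        phase2_flags.append(done())

        def times(mask: np.ndarray, arr: np.ndarray, offset: int = 0) -> np.ndarray:
            t = arr[mask]
            t = t[t != CENSORED] - offset
            return t[t >= 0] if offset else t

        # First/second food learning times per origin group.
        t_first = {
            "HH": times(hh, cross_h),
            "LL": times(ll, cross_l),
        }
        t_second = {
            "HH": times(hh, cross_l, offset=switch_step),
            "LL": times(ll, cross_h, offset=switch_step),
        }
        # Mixed-origin agents: first-consumed food vs the other, both
        # clocked from the start of the run (their exposure never switches).
        hl_first_h = hl & (first_food == 1)
        hl_first_l = hl & (first_food == 0)
        t_first["HL"] = np.concatenate(
            [times(hl_first_h, cross_h), times(hl_first_l, cross_l)]
        )
        t_second["HL"] = np.concatenate(
            [times(hl_first_h, cross_l), times(hl_first_l, cross_h)]
        )

        row: dict[str, float] = {"replicate": rep, "switch_step": switch_step}
        for o, cnt in zip(origins, counts):
            row[f"mean_first_{o}"] = float(t_first[o].mean())
            row[f"mean_second_{o}"] = (
                float(t_second[o].mean()) if len(t_second[o]) else np.nan
            )
            row[f"lockin_{o}"] = row[f"mean_second_{o}"] / row[f"mean_first_{o}"]
            censored[o] += cnt - len(t_second[o])
        row["ratio_h"] = row["mean_second_LL"] / row["mean_first_HH"]
        row["ratio_l"] = row["mean_second_HH"] / row["mean_first_LL"]
        rows.append(row)

    per_rep = pd.DataFrame(rows)
    summary_rows = []
    lockin, lockin_se = {}, {}
    for col in [c for c in per_rep.columns if c not in ("replicate", "switch_step")]:
        vals = per_rep[col].dropna()
        mean, se = replicate_stats(vals) if len(vals) >= 2 else (float(vals.mean()), np.nan)
        summary_rows.append({"metric": col, "mean": mean, "se": se, "n_runs": len(vals)})
        if col.startswith("lockin_"):
            lockin[col.removeprefix("lockin_")] = mean
            lockin_se[col.removeprefix("lockin_")] = se
    summary = pd.DataFrame(summary_rows)
    get = lambda m: float(summary.loc[summary["metric"] == m, "mean"].iloc[0])
    return MovementResult(
        per_replicate=per_rep,
        summary=summary,
        ratio_h=get("ratio_h"),
        ratio_l=get("ratio_l"),
        lockin=lockin,
        lockin_se=lockin_se,
        censored=censored,
        phase1_steps=phase1_steps,
        phase2_flags=phase2_flags,
    )


def run_movement_noise_sweep(
    spec: ExperimentSpec, epsilons=NOISE_SWEEP_EPSILONS
) -> pd.DataFrame:
    """Movement experiment across choice-noise levels (lock-in vs noise).

    Each epsilon gets its own replicate set, seeded independently from the
    master seed.  Returns one row per epsilon with per-origin lock-in
    ratios (mean and SE over replicates) and the cross-origin time ratios.
    """
    rows = []
    for i, eps in enumerate(epsilons):
        sub_seed = (spec.config.seed + 10_007 * (i + 1)) % (2**31)
        sub = ExperimentSpec(
            name="movement",
            n_replicates=spec.n_replicates,
            config=spec.config.replace(epsilon=float(eps), seed=sub_seed),
            time_to_learn_tol=spec.time_to_learn_tol,
        )
        res = run_movement(sub)
        rows.append(
            {
                "epsilon": eps,
                "lockin_HH": res.lockin["HH"],
                "lockin_HH_se": res.lockin_se["HH"],
                "lockin_LL": res.lockin["LL"],
                "lockin_LL_se": res.lockin_se["LL"],
                "lockin_HL": res.lockin["HL"],
                "ratio_h": res.ratio_h,
                "ratio_l": res.ratio_l,
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------- #
# gradient space


@dataclass
class GradientResult:
    by_bin: pd.DataFrame
    per_replicate: pd.DataFrame
    horizon: int

    def frames(self) -> dict[str, pd.DataFrame]:
        return {"by_bin": self.by_bin, "per_replicate": self.per_replicate}


def run_gradient(spec: ExperimentSpec, n_bins: int = 10) -> GradientResult:
    """Gradient-space experiment with neighborhood choice.

    Agents start at uniformly random cells and are binned by the H-item
    probability of their starting column (deciles by default).  The run
    lasts until every agent has learned both foods or ``max_steps`` elapse;
    agents still short of a threshold at the horizon are right-censored at
    the horizon, which biases bin means toward the horizon rather than
    optimistically downward.  Reported per bin: mean time to learn H, and
    the lock-in ratio time(second-consumed food) / time(first-consumed
    food) over agents with both times uncensored.
    """
    cfg = spec.config
    ttl = spec.time_to_learn_tol
    thresh_h = cfg.p_high - ttl
    thresh_l = cfg.p_low - ttl
    rows = []
    for rep, (env_rng, sim_rng) in enumerate(_replicate_rngs(spec)):
        env = build_gradient(cfg.width, cfg.height, seed=env_rng)
        sim = Simulation(env, cfg, rng=sim_rng, choice_rule="neighborhood")
        n = cfg.n_agents
        start_p = sim.cols / (cfg.width - 1)
        bins = np.minimum((start_p * n_bins).astype(int), n_bins - 1)
        cross_h = np.full(n, CENSORED, dtype=np.int64)
        cross_l = np.full(n, CENSORED, dtype=np.int64)
        first_food = np.full(n, CENSORED, dtype=np.int8)
        while sim.step_count < cfg.max_steps and not (
            (cross_h != CENSORED).all() and (cross_l != CENSORED).all()
        ):
            sim.step()
            if sim.step_count == 1:
                first_food[:] = sim.last_food
            first_crossing_update(cross_h, sim.vhat_h, thresh_h, sim.step_count)
            first_crossing_update(cross_l, sim.vhat_l, thresh_l, sim.step_count)
        horizon = sim.step_count
        # Right-censor at the horizon for time-to-learn-H bin means.
        t_h = np.where(cross_h == CENSORED, horizon, cross_h)
        t_first = np.where(first_food == 1, cross_h, cross_l)
        t_second = np.where(first_food == 1, cross_l, cross_h)
        both = (t_first != CENSORED) & (t_second != CENSORED) & (t_first > 0)
        for b in range(n_bins):
            sel = bins == b
            if not sel.any():
                continue
            ok = sel & both
            ratio = (
                float(t_second[ok].mean()) / float(t_first[ok].mean())
                if ok.any() and t_first[ok].mean() > 0
                else np.nan
            )
            rows.append(
                {
                    "replicate": rep,
                    "bin": b,
                    "h_frac_low": b / n_bins,
                    "h_frac_high": (b + 1) / n_bins,
                    "n_agents": int(sel.sum()),
                    "mean_time_H": float(t_h[sel].mean()),
                    "lockin_ratio": ratio,
                    "censored_H": int((cross_h[sel] == CENSORED).sum()),
                }
            )
    per_rep = pd.DataFrame(rows)
    agg_rows = []
    for b, grp in per_rep.groupby("bin"):
        th_mean, th_se = replicate_stats(grp["mean_time_H"])
        ratios = grp["lockin_ratio"].dropna()
        if len(ratios) >= 2:
            lr_mean, lr_se = replicate_stats(ratios)
        else:
            lr_mean, lr_se = (float(ratios.mean()) if len(ratios) else np.nan, np.nan)
        agg_rows.append(
            {
                "bin": b,
                "h_frac_low": grp["h_frac_low"].iloc[0],
                "h_frac_high": grp["h_frac_high"].iloc[0],
                "mean_time_H": th_mean,
                "se_time_H": th_se,
                "mean_lockin": lr_mean,
                "se_lockin": lr_se,
                "censored_H_frac": grp["censored_H"].sum() / grp["n_agents"].sum(),
            }
        )
    return GradientResult(
        by_bin=pd.DataFrame(agg_rows), per_replicate=per_rep, horizon=cfg.max_steps
    )


# --------------------------------------------------------------------- #


def build_replicate(
    spec: ExperimentSpec, rep_index: int, record: bool = False
) -> Simulation:
    """Construct replicate ``rep_index``'s simulation exactly as the
    corresponding experiment driver does (same seed derivation), optionally
    with full trajectory recording.  The two-phase movement scenario manages
    its own phases and is not constructible here.
    """
    cfg = spec.config
    if cfg.scenario == "movement":
        raise ValueError("movement replicates are phase-managed; use run_movement")
    if not 0 <= rep_index < spec.n_replicates:
        raise ValueError(f"rep_index {rep_index} outside 0..{spec.n_replicates - 1}")
    env_rng, sim_rng = _replicate_rngs(spec)[rep_index]
    if cfg.scenario == "base_case":
        env = build_well_mixed(cfg.width, cfg.height, seed=env_rng)
        return Simulation(env, cfg, rng=sim_rng, record=record)
    if cfg.scenario == "hetero_types":
        n_types = len(HETERO_TYPES)
        per_type = cfg.n_agents // n_types
        cfg = cfg.replace(n_agents=per_type * n_types)
        group = np.repeat(np.arange(n_types), per_type)
        env = build_well_mixed(cfg.width, cfg.height, seed=env_rng)
        return Simulation(
            env, cfg, rng=sim_rng,
            alpha=np.array([HETERO_TYPES[g][1] for g in group]),
            beta_h=np.array([HETERO_TYPES[g][2] for g in group]),
            group=group,
            group_labels={i: t[0] for i, t in enumerate(HETERO_TYPES)},
            record=record,
        )
    if cfg.scenario == "quadrants":
        region_ids = sorted(QUADRANT_LABELS)
        per_region = cfg.n_agents // len(region_ids)
        cfg = cfg.replace(n_agents=per_region * len(region_ids))
        env = build_quadrants(cfg.width, cfg.height, seed=env_rng)
        positions = np.vstack(
            [_positions_in_region(env, r, per_region, sim_rng) for r in region_ids]
        )
        group = np.repeat(np.arange(len(region_ids)), per_region)
        return Simulation(
            env, cfg, rng=sim_rng, positions=positions, group=group,
            group_labels={i: QUADRANT_LABELS[r] for i, r in enumerate(region_ids)},
            record=record,
        )
    if cfg.scenario == "gradient":
        env = build_gradient(cfg.width, cfg.height, seed=env_rng)
        return Simulation(env, cfg, rng=sim_rng, choice_rule="neighborhood",
                          record=record)
    raise ValueError(f"unknown scenario {cfg.scenario!r}")


def run_experiment(spec: ExperimentSpec):
    """Dispatch an experiment by its scenario name."""
    driver = {
        "base_case": run_base_case,
        "hetero_types": run_hetero_types,
        "quadrants": run_quadrants,
        "movement": run_movement,
        "gradient": run_gradient,
    }[spec.config.scenario]
    return driver(spec)
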