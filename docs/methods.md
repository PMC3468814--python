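# Methods

## Learning rule

Agents update a scalar valuation per food type by the delta rule
V̂ ← V̂ + α(βp − V̂). This is the single-stimulus special case of
temporal-difference learning: there is no successor-state term, no
discounting within a trial, and no eligibility trace, so each food's
valuation evolves independently given the consumption sequence. The rule
has fixed point βp, approaches it monotonically from below for α ≤ 1, and
admits the closed form βp(1 − (1−α)ⁿ) after n consecutive updates from 0.
The closed form is kept in the package as an analytic oracle: engine tests
force an agent onto a single-food diet and require bit-level agreement with
it, which pins down the scheduler's consume→update bookkeeping.

All valuations are double precision and are never rounded during a run;
rounding (4 decimal places) happens only when trajectory CSVs are written.

## Parameters

| parameter | default | meaning |
|---|---|---|
| p_L, p_H | 0.6, 0.9 | intrinsic palatabilities (abstract reward units); θ = p_H/p_L = 1.5 |
| α | 0.4 | learning rate, fraction of prediction error absorbed per update |
| β | 1.0 | responsivity multiplier; the heterogeneity experiment uses β_H ∈ {2.0, 0.5} with β_L fixed at 1 |
| ε | 0.05 | choice noise, probability of the non-greedy branch |
| grid | 100×100 | cells, two food items each |
| n_agents | 400 | 100 per type/region in the split experiments |
| equilibrium_tol, window | 1e-4, 10 | see below |
| time-to-learn tol | 0.01 | threshold offset below the asymptote |

θ may be set instead of p_H (p_H = θ·p_L). Palatabilities are only required
positive, not ≤ 1, so θ sweeps above 1/p_L are legal.

The agent count is not dictated by the model; 400 was chosen as dense
enough for smooth population curves on a 100×100 grid while keeping every
experiment comfortably below a minute. Replicate counts default to 15, and
every reported curve or ratio carries a 15-run standard error where ≥ 2
replicates exist.

## Scheduler and its simultaneity

Each round: all agents move, all consume, all update. Food never depletes
(a cell's two items are standing options) and cells have no occupancy
limit, so agents never interact — under these assumptions a random
per-phase processing order is observationally equivalent to simultaneous
processing, and the engine vectorises all agents in numpy. One seeded
`numpy.random.Generator` drives every draw, making runs bit-reproducible;
replicate r's stream is spawned from `SeedSequence(master_seed)` and
depends only on (master_seed, r).

Movement draws uniformly from the Moore 8-neighborhood intersected with
the agent's reachable region; the current cell is excluded (configurable
via `allow_stay`). Quadrant walls are enforced by region membership and
outer torus wrapping is disabled in the quadrant scenario; the gradient
space wraps rows but not columns, because wrapping columns would join the
100%-H and 100%-L edges and erase the gradient the scenario exists to
study. On a degenerate 1×1 grid movement is a no-op.

## Choice rules

Two-option cells: a single type present forces the choice; with both
present the higher-valued type is taken with probability 1−ε and the
lower-valued with ε; exact ties (always true at t = 0) split uniformly,
which is what seeds the 50/50 initial lock-in split. In the gradient
scenario the choice set is the 3×3 neighborhood's item pool: greedy over
the types present with probability 1−ε, a uniformly random *item* with
probability ε — so the noise branch is weighted by local food abundance.
These two ε semantics are deliberately different and both are implemented
as stated.

## Equilibrium detection

"No agent still changing its valuations" is operationalised as: every
agent's realised update magnitude |α(βp − V̂)| ≤ 1e-4 for 10 consecutive
steps. With choice noise, exact zero change occurs only at the fixed
points, so a persistence window over the realised deltas is the robust
test. Hitting `max_steps` (default 5000) instead is flagged on the result
and in the manifest, not raised.

## Metrics

**Time to learn** food j: first step at which V̂_j ≥ βp_j − tol (default
tol 0.01); monotone convergence makes the first crossing permanent. Agents
that never cross are censored and reported as such. The reference lock-in
ratios plausibly depend on this threshold, so the movement CLI exposes a
sensitivity sweep over tol ∈ {0.005, 0.01, 0.05}.

**Learning ratio** of a group: mean time to learn the second food ÷ mean
time to learn the first; > 1 quantifies lock-in. In the movement
experiment the first food is the origin region's food with its clock
starting at step 0, and the second food's clock starts at the switch step.
Mixed-origin agents, whose environment never changes, are clocked on the
food they consumed first versus the other, both from step 0 — the same
convention used per-agent in the gradient experiment, where no switch
exists and "first food" is identified by the first consumption.

**Phase-1 stop** in the movement experiment: the pure-H group's mean V̂_H
within equilibrium_tol of p_H ("completed learning"); with deterministic
pure-region exposure this happens at step 18 under the defaults.

**Gradient binning**: agents are binned by the H-item probability of their
starting column into deciles. The run lasts until every agent has crossed
both thresholds or max_steps; stragglers are right-censored *at the
horizon* in bin means of time-to-learn (biasing toward the horizon rather
than optimistically downward), and excluded from ratio numerators with
censor counts reported. The delta-equilibrium criterion is not used to
stop gradient runs: it triggers as soon as every agent's *consumed* foods
converge, which would end the run before far-column agents ever sample H.

## What the generator emulates — and what it does not

The synthetic environments reproduce the structural features the model
isolates: binomial well-mixed composition, hard exposure walls, a linear
exposure gradient, and an abrupt mid-run exposure switch. They do not
emulate real food geography, food depletion or replenishment, homeostatic
hunger or satiety, social influence, or more than two food types (the type
system permits more; the experiments use two). Passing tests therefore
show that the learning dynamics follow from exposure structure under the
stated rules — not that any particular real food environment behaves this
way.

## Numerical and design notes

- Updates never overshoot (α ≤ 1), so 0 ≤ V̂ ≤ βp holds throughout; the
  bound is asserted in property tests.
- Curves from replicates of different lengths are aligned by padding with
  the final (converged) value before averaging.
- The movement noise sweep gives each ε its own independently seeded
  replicate set.
- Cross-origin time ratios and per-origin learning ratios are computed per
  replicate and then averaged (their SE is the 15-run SE of the ratio).
- Exit codes of the CLI: 0 success (including flagged non-convergence),
  1 invalid configuration, 2 internal error.

## Known limitations

- Equilibrium and time-to-learn thresholds are operational choices; the
  lock-in ratios move with the time-to-learn tolerance (see the sweep),
  though their qualitative ordering does not.
- With ε = 0 and an unlucky initial tie-break an agent may never sample
  one food; runs then end by the equilibrium criterion with that valuation
  censored at 0, which is the model's intended behavior, not an error.
- The gradient experiment's extreme-L decile can include agents censored
  at the horizon on long runs with low ε; bin means there are
  horizon-bounded lower estimates.
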