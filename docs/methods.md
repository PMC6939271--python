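# Methods

## Model overview

`bethedge` simulates the evolution of a single continuous gene in [0, 1]
encoding an individual's probability of playing a variance-prone strategy.
Populations are asexual and density-regulated; the gene changes only
through mutation and through selection acting on offspring numbers.

Each season, every adult accumulates payoff over `n` independent decision
events, produces offspring in proportion to its payoff total, and then
survives to the next season with probability `1 − α`. Offspring recruit
uniformly at random — blind to the gene — into the `K − N_surv` vacancies
below the carrying capacity, so by each season's start `N ≤ K`. A
population reaching `N = 0` is recorded as extinct and its replicate stops.

### Model 1: binary environment

Per event, the global resource state `R` is good or bad with equal
probability, and each individual's local condition equals `R` with
probability `0.5 + g_r/2`. An individual labelled a variable player (with
probability equal to its gene, drawn once per season) earns `µ(1+b)` under
a good local condition and `µ(1−b)` under a bad one; constant players earn
`µ(1−a)` regardless. At `g_r = 1` all variable players share one outcome
and genotype fitness fluctuates coherently between seasons; at `g_r = 0`
individual outcomes are independent and average out within a season.

### Model 2: energetic state and a sigmoid utility

Per event, a global environmental quality `E ~ Uniform(0, 1)` is drawn and
each individual receives a state `x` uniform on
`[g_e·E, E + (1−g_e)(1−E)]` — an interval that always contains `E`,
collapses onto it at `g_e = 1`, and spans [0, 1] at `g_e = 0`.
Variance-sensitive carriers in low state (`x < 0.5`, strict) gamble ±0.1
on a resource-condition draw correlated through `g_r` exactly as in model
1; everyone else holds state. The updated state converts to fitness
through `W(x) = 2µ / (1 + e^{−5(x−0.5)})` (slope 5 and inflection 0.5 are
fixed constants of the model). `W` is convex below the inflection, so the
gamble raises arithmetic mean fitness precisely for the individuals
allowed to take it.

Two choices here were genuinely open and are worth recording:

* **No state floor on the gamble.** A failed gamble from `x < 0.1` lands
  below zero, where the sigmoid keeps falling (`W(−0.05) ≈ 0.24µ/2`).
  Flooring such states at zero looks harmless but hands gamblers in the
  worst states a payoff floor with real selective force: with the floor,
  the expected per-season change in log-odds of a sensitive genotype at
  `g_e = g_r = 1`, `n = 1` is +0.002 (weakly favouring the gamble), while
  without it the change is −0.021. Because `log W` is concave everywhere,
  the unclamped gamble always carries a geometric-mean penalty under fully
  shared outcomes — the mechanism that lets coarse grain select for
  variance aversion at all. The gamble step is therefore left unclamped;
  the utility accepts states one gamble step beyond [0, 1]. Gene values,
  by contrast, are hard-clamped to [0, 1] after mutation (they are
  probabilities).
* **Per-event scaling.** Each event contributes `W(x′)/n` by default, so
  lifetime expected payoff stays near `µ` whatever `n`; this keeps
  absolute recruit numbers (and hence extinction risk) comparable across
  `n`. The unscaled variant is available via
  `SimConfig(fitness_scaling="per_event")`; within-season relative fitness
  — and therefore the evolutionary endpoint — is unaffected by the common
  factor.

States are redrawn from `E` at every event; `x′` does not carry over
between events within a season. The state source (`E`) and the gamble
outcome (`R`) are independent. The distribution of `E` is uniform on its
stated support — the maximum-entropy choice — and `E`/`R` are redrawn
independently at every event.

### Analytic layer

Under fully shared payoffs the lineage payoff of the variable strategy is
the probability-weighted geometric mean over the binomial number of
successful events,

    G_var,n = µ · Π_{m=0..n} [(1−b)(n−m) + (1+b)m]^{C(n,m)·0.5ⁿ},

computed as the exponential of a weighted log sum with exact log-gamma
binomial weights (stable for any `n`). At `b = 1` the all-failure lifetime
pays zero and the geometric mean is defined as exactly 0, making the
maximum safe penalty `a* = 1 − G_var,n/(µn)` equal to 1 there; for `b < 1`
the bound lies strictly inside [0, 1). `a*` is independent of `µ`, rises
with `b` and falls with `n` — at `b = 0.9` the bound crosses 0.1 at
`n = 5`, which is why the baseline payoff geometry (µ = 2, a = 0.1,
b = 0.9) puts the two strategies at approximate parity there.

## Parameters and defaults

| parameter | meaning | default | notes |
|---|---|---|---|
| `mu` | expected per-event payoff of the variable strategy | 2 | resource units |
| `a` | constant-strategy payoff penalty | 0.1 | fraction in [0, 1) |
| `b` | variable-strategy payoff variability | 0.9 | fraction in (0, 1] |
| `g_r` | grain of resources (payoff correlation) | — | swept over {0, 0.25, 0.5, 0.75, 1} |
| `g_e` | grain of environment (state correlation) | — | model 2 only, same sweep values |
| `n` | decision events per season | — | swept over {1, 2, 5, 10} |
| `alpha` | between-season adult mortality | 1 or 0.5 | 1 = discrete generations |
| `K` | carrying capacity | 5000 | baseline; 500 in scaled-down checks |
| `m_p` | per-offspring mutation probability | 0.005 | |
| `m_sigma` | mutation SD on the gene scale | 0.05 | clamped to [0, 1] after mutation |
| `seasons` | run length | 2000 | 1000 in scaled-down checks |
| `replicates` | independent populations per cell | 100 | 20 in scaled-down checks |

## Numerical and procedural choices

* **Offspring integerization.** Real payoff totals become integer
  offspring counts by unbiased stochastic rounding (`floor(W)` plus a
  Bernoulli on the fraction), so each adult's expected offspring equals
  its payoff exactly; `Poisson(W)` is available behind
  `offspring_rounding="poisson"` and satisfies the same proportionality
  contract with more variance.
* **Lifecycle order.** Payoff accumulation → reproduction → mutation →
  adult mortality → recruitment. Mortality strikes adults after they have
  reproduced; orphaned offspring recruit normally.
* **Strategy labels** are drawn once per individual per season and held
  across the season's events (the gene encodes a whole-individual type); a
  per-event redraw is exposed as `redraw_strategy_per_event` for
  sensitivity analysis.
* **Randomness.** One master seed; each replicate's generator derives from
  `(master_seed, cell_key, replicate_index)` via numpy `SeedSequence`
  spawn keys, where `cell_key` hashes the cell's own parameter values.
  Replicates are individually reproducible, and adding cells to a sweep
  never changes existing cells' results.
* **Aggregation.** Endpoint gene statistics (mean, SD of the final
  population-mean gene) are computed over surviving replicates only;
  survival proportion is reported as its own column.

## What the scaled-down checks show — and what they do not

The endpoint-pattern tests run the full lifecycle at `K = 500`,
1000 seasons, 20 replicates per cell (model 1: `g_r × n × α` grid, 40
cells; model 2: `g_e × g_r × n` grid at `α = 0.5`, 48 cells with
`g_e, g_r ∈ {0, 0.5, 0.75, 1}` and `n ∈ {1, 2, 10}`). At the baseline
selection differentials, mutation–selection–drift balance equilibrates
well before 1000 seasons, so these runs probe the same endpoint surface as
full-scale runs with more replicate noise — across-replicate SDs of
0.1–0.25 in model 2, where selection is weak (the gamble's arithmetic
advantage is only 5–10%). A cell is therefore read as showing variance
aversion when its across-replicate mean gene lies below 0.5 by more than
two standard errors of that mean; trend checks allow wiggles up to one
across-replicate SD.

The checks establish orderings and thresholds (where proneness fixes,
where aversion appears, that generation overlap is immaterial, that the
neutral control stays at 0.5), not point estimates of evolved gene values.
The simulated environments are i.i.d. across seasons with no spatial
structure, no autocorrelation and no state carry-over; real systems with
temporally autocorrelated environments or persistent condition differences
may place the aversion boundary elsewhere.

## Known limitations

* Bounds for `g_r < 1` have no closed form here; that regime is explored
  only by simulation.
* Model 2's utility shape is fixed; other slopes or inflections, learned
  patch choice, and diversified (phenotype-randomizing) bet-hedging are
  out of scope.
* Sexual reproduction, age structure and juvenile density dependence are
  not modelled.
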