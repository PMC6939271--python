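"""Model 2: variance-sensitive foraging with explicit energetic state.

Each decision event draws a global environmental quality E ~ Uniform(0, 1)
and gives every individual an energetic state x_i uniform on
[g_e*E, E + (1-g_e)*(1-E)]. Individuals carrying the variance-sensitive
strategy who land in low state (x < 0.5, the inflection point of the
utility curve) gamble at a variable patch, moving their state up or down
by 0.1 according to a resource-condition draw correlated through g_r
exactly as in model 1; everyone else forages at a constant patch that
holds state unchanged. The updated state converts to fitness through the
sigmoid utility

    W(x) = 2*mu / (1 + exp(-5*(x - 0.5))),

which is convex below 0.5 (gambling raises expected fitness there, by
Jensen's inequality) and concave above. Per-event fitness contributions
add over the n events; by default each contributes W(x')/n so that the
lifetime expectation stays near mu regardless of n.

States are redrawn from E at every event — there is no carry-over of x'
between events within a season. The state draw (E) and the gamble outcome
(R) are independent stochastic sources.
"""

from __future__ import annotations

from typing import Union

import numpy as np

from .core import (
    GrainParams,
    ParameterError,
    PayoffParams,
    Population,
    SimConfig,
    sample_resource_conditions,
    sample_states,
)
from .model1 import assign_strategies

__all__ = ["utility", "foraging_step", "run_season_model2"]

#: slope and inflection of the utility sigmoid (fixed model constants)
UTILITY_SLOPE = 5.0
UTILITY_INFLECTION = 0.5
#: energetic-state change from one gamble at the variable patch
GAMBLE_STEP = 0.1


def utility(x: Union[float, np.ndarray], mu: float) -> Union[float, np.ndarray]:
    """Sigmoid map from energetic state to fitness-acquiring resources.

    ``W(x) = 2*mu / (1 + exp(-5*(x - 0.5)))``: strictly increasing, equal
    to ``mu`` at the inflection x = 0.5, bounded in (0, 2*mu), convex
    below the inflection and concave above it. States are drawn in
    [0, 1] but a failed gamble can leave an individual one step below
    zero, so the accepted domain is one gamble step beyond the unit
    interval.
    """
    if not mu > 0:
        raise ParameterError(f"mu must be positive, got {mu}")
    xa = np.asarray(x, dtype=float)
    if np.any(xa < -GAMBLE_STEP) or np.any(xa > 1 + GAMBLE_STEP):
        raise ParameterError("state x must lie within one gamble step of [0, 1]")
    w = 2.0 * mu / (1.0 + np.exp(-UTILITY_SLOPE * (xa - UTILITY_INFLECTION)))
    return float(w) if np.isscalar(x) else w


def foraging_step(
    x: Union[float, np.ndarray],
    is_sensitive: Union[bool, np.ndarray],
    success: Union[int, np.ndarray],
) -> Union[float, np.ndarray]:
    """One foraging decision: gamble if sensitive and in low state.

    Variance-sensitive individuals with ``x < 0.5`` move to ``x + 0.1`` on
    success and ``x - 0.1`` on failure. Everyone else (variance-averse
    individuals, and sensitive ones already at or above the inflection)
    forages at the constant patch and keeps their state.

    The step is not clamped: a failed gamble from ``x < 0.1`` lands below
    zero, where the utility sigmoid keeps falling. Flooring such outcomes
    at zero would hand gamblers in the worst states a free payoff floor
    strong enough to cancel the geometric-mean penalty of gambling under
    coarse grain, reversing the direction of selection there.
    """
    xa = np.asarray(x, dtype=float)
    gamble = np.asarray(is_sensitive, dtype=bool) & (xa < UTILITY_INFLECTION)
    delta = np.where(np.asarray(success, dtype=bool), GAMBLE_STEP, -GAMBLE_STEP)
    out = np.where(gamble, xa + delta, xa)
    return float(out) if np.isscalar(x) else out


def run_season_model2(
    population: Population,
    grain: GrainParams,
    params: PayoffParams,
    config: SimConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Accumulate lifetime payoffs W_i over the season's n decision events.

    Per event: draw states from E (grain g_e), draw gamble outcomes
    (grain g_r), apply the foraging step, and accrue the utility of the
    updated state — divided by n under the default per-event-over-n
    scaling.
    """
    if population.extinct:
        raise ValueError("population is empty")
    N = population.size
    is_sensitive = assign_strategies(population, rng)
    scale = 1.0 / config.n if config.fitness_scaling == "per_event_over_n" else 1.0
    W = np.zeros(N)
    for _ in range(config.n):
        if config.redraw_strategy_per_event:
            is_sensitive = assign_strategies(population, rng)
        states = sample_states(grain.g_e, N, rng)
        resources = sample_resource_conditions(grain.g_r, N, rng)
        x_new = foraging_step(states.x, is_sensitive, resources.r)
        W += scale * utility(x_new, params.mu)
    return W
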