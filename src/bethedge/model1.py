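"""Model 1: constant versus variable payoffs in a binary-quality environment.

Each season, every individual is labelled a variable player with probability
equal to its gene value. Over ``n`` independent decision events, variable
players receive ``mu*(1+b)`` when their local resource condition is good and
``mu*(1-b)`` when it is bad; constant players receive ``mu*(1-a)`` always.
The grain of resources ``g_r`` correlates the local conditions through the
shared global state R (see :func:`bethedge.core.sample_resource_conditions`).
Lifetime payoff is the additive total over the n events.
"""

from __future__ import annotations

import numpy as np

from .core import (
    GrainParams,
    PayoffParams,
    Population,
    SimConfig,
    sample_resource_conditions,
)

__all__ = ["assign_strategies", "event_payoff", "event_payoffs", "run_season_model1"]

VARIABLE = "variable"
CONSTANT = "constant"


def assign_strategies(population: Population, rng: np.random.Generator) -> np.ndarray:
    """Label each individual variable (True) with probability equal to its
    gene value, independently. Drawn once per season and held across the
    season's events unless the config requests per-event redraw."""
    return rng.random(population.size) < population.genes


def event_payoff(strategy: str, r_i: int, params: PayoffParams) -> float:
    """Per-event payoff of one individual.

    Constant players earn ``mu*(1-a)`` regardless of the resource
    condition; variable players earn ``mu*(1-b)`` when ``r_i = 0`` (bad)
    and ``mu*(1+b)`` when ``r_i = 1`` (good).
    """
    if strategy == CONSTANT:
        return params.mu * (1.0 - params.a)
    if strategy == VARIABLE:
        return params.mu * (1.0 + params.b) if r_i else params.mu * (1.0 - params.b)
    raise ValueError(f"unknown strategy label {strategy!r}")


def event_payoffs(
    is_variable: np.ndarray, r: np.ndarray, params: PayoffParams
) -> np.ndarray:
    """Vectorized :func:`event_payoff` over a population."""
    w_const = params.mu * (1.0 - params.a)
    w_var = np.where(
        r.astype(bool), params.mu * (1.0 + params.b), params.mu * (1.0 - params.b)
    )
    return np.where(is_variable, w_var, w_const)


def run_season_model1(
    population: Population,
    grain: GrainParams,
    params: PayoffParams,
    config: SimConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Accumulate lifetime payoffs W_i over the season's n decision events.

    Each event draws a fresh global resource state and per-individual
    conditions (independent across events); payoffs add within the season.
    """
    if population.extinct:
        raise ValueError("population is empty")
    N = population.size
    is_variable = assign_strategies(population, rng)
    W = np.zeros(N)
    for _ in range(config.n):
        if config.redraw_strategy_per_event:
            is_variable = assign_strategies(population, rng)
        draw = sample_resource_conditions(grain.g_r, N, rng)
        W += event_payoffs(is_variable, draw.r, params)
    return W
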