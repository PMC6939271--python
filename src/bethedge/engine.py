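"""The shared evolutionary lifecycle.

One season runs, in order: model-specific payoff accumulation over n
decision events; asexual reproduction proportional to each adult's payoff
total; mutation of a fraction m_p of offspring; between-season adult
mortality alpha; and density-regulated recruitment of offspring into the
vacancies below the carrying capacity K. Recruitment is uniform over the
offspring pool — random with respect to the gene — so selection acts only
through offspring numbers. The adult population therefore never exceeds K
at a season start, and a population that reaches N = 0 is recorded as
extinct rather than raising.

Offspring counts are integerized by unbiased stochastic rounding
(floor(W) plus a Bernoulli on the fractional part), so each adult's
expected offspring number equals its payoff total exactly; a Poisson(W)
alternative is available via ``SimConfig.offspring_rounding``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .core import (
    GrainParams,
    PayoffParams,
    Population,
    SimConfig,
    replicate_rng,
)
from .model1 import run_season_model1
from .model2 import run_season_model2

__all__ = [
    "ReplicateSummary",
    "initialize_population",
    "reproduce",
    "mutate",
    "survive_adults",
    "recruit",
    "run_replicate",
]

_SEASON_RUNNERS: dict[str, Callable] = {
    "model1": run_season_model1,
    "model2": run_season_model2,
}


@dataclass
class ReplicateSummary:
    """Endpoint statistics of one replicate population.

    ``final_mean_gene``/``final_sd_gene`` are NaN when the population went
    extinct (``survived`` False, ``extinction_season`` set, ``final_N`` 0).
    """

    replicate_id: int
    survived: bool
    extinction_season: Optional[int]
    final_mean_gene: float
    final_sd_gene: float
    final_N: int
    gene_trajectory: Optional[np.ndarray] = None


def initialize_population(config: SimConfig, rng: np.random.Generator) -> Population:
    """K individuals with genes i.i.d. Uniform(0, 1)."""
    return Population(genes=rng.random(config.K), season=0)


def reproduce(
    genes: np.ndarray,
    payoffs: np.ndarray,
    rng: np.random.Generator,
    rounding: str = "stochastic",
) -> np.ndarray:
    """Offspring gene pool with counts proportional to payoff totals.

    Each adult with payoff total W contributes floor(W) offspring plus one
    more with probability frac(W) ("stochastic"), or Poisson(W) offspring
    ("poisson"); either way the expected count is exactly W. Offspring
    inherit the parent gene unchanged (mutation is a separate step).
    """
    if np.any(payoffs < 0):
        raise ValueError("payoff totals must be non-negative")
    if rounding == "stochastic":
        base = np.floor(payoffs)
        counts = (base + (rng.random(payoffs.size) < payoffs - base)).astype(np.int64)
    elif rounding == "poisson":
        counts = rng.poisson(payoffs)
    else:
        raise ValueError(f"unknown rounding {rounding!r}")
    return np.repeat(genes, counts)


def mutate(
    pool: np.ndarray, m_p: float, m_sigma: float, rng: np.random.Generator
) -> np.ndarray:
    """Mutate each offspring independently with probability m_p.

    A mutated gene is the parent value plus Gaussian(0, m_sigma) noise,
    clamped to [0, 1] (the gene is a probability; negative draws pile up
    at exactly 0 and draws above 1 at exactly 1).
    """
    if pool.size == 0:
        return pool.copy()
    out = pool.copy()
    hit = rng.random(pool.size) < m_p
    k = int(hit.sum())
    if k:
        out[hit] = np.clip(out[hit] + rng.normal(0.0, m_sigma, k), 0.0, 1.0)
    return out


def survive_adults(
    genes: np.ndarray, alpha: float, rng: np.random.Generator
) -> np.ndarray:
    """Adults surviving the between-season mortality alpha.

    Each adult independently survives with probability 1 - alpha;
    alpha = 1 leaves no survivors (discrete generations).
    """
    if not 0 <= alpha <= 1:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    if genes.size == 0:
        return genes.copy()
    return genes[rng.random(genes.size) < 1.0 - alpha]


def recruit(
    pool: np.ndarray, survivors: np.ndarray, K: int, rng: np.random.Generator
) -> np.ndarray:
    """Fill vacancies below K with offspring drawn uniformly from the pool.

    Recruit count is min(pool size, K - survivors); recruitment is blind
    to gene values. Returns next season's adult gene vector (possibly
    empty — extinction — never exceeding K).
    """
    if K < 1:
        raise ValueError(f"K must be positive, got {K}")
    vacancies = max(0, K - survivors.size)
    k = min(pool.size, vacancies)
    if k == 0:
        return survivors.copy()
    if k == pool.size:
        recruits = pool
    else:
        recruits = rng.choice(pool, size=k, replace=False)
    return np.concatenate([survivors, recruits])


def run_replicate(
    config: SimConfig,
    grain: GrainParams,
    params: PayoffParams,
    rng: Optional[np.random.Generator] = None,
    replicate_id: int = 0,
) -> ReplicateSummary:
    """Simulate one replicate population for ``config.seasons`` seasons.

    Stops early on extinction, which is a recorded outcome. With no rng
    given, an independent stream is derived from
    ``(config.master_seed, replicate_id)``.
    """
    if rng is None:
        rng = replicate_rng(config.master_seed, replicate_id)
    season_fn = _SEASON_RUNNERS[config.model]
    pop = initialize_population(config, rng)
    trajectory = [] if config.track_trajectory else None

    for season in range(config.seasons):
        assert pop.size <= config.K
        if trajectory is not None:
            trajectory.append(float(pop.genes.mean()))
        payoffs = season_fn(pop, grain, params, config, rng)
        pool = reproduce(pop.genes, payoffs, rng, config.offspring_rounding)
        pool = mutate(pool, config.m_p, config.m_sigma, rng)
        survivors = survive_adults(pop.genes, config.alpha, rng)
        next_genes = recruit(pool, survivors, config.K, rng)
        pop = Population(genes=next_genes, season=season + 1)
        if pop.extinct:
            return ReplicateSummary(
                replicate_id=replicate_id,
                survived=False,
                extinction_season=pop.season,
                final_mean_gene=float("nan"),
                final_sd_gene=float("nan"),
                final_N=0,
                gene_trajectory=np.asarray(trajectory) if trajectory is not None else None,
            )

    assert pop.genes.size == 0 or (
        pop.genes.min() >= 0.0 and pop.genes.max() <= 1.0
    )
    if trajectory is not None:
        trajectory.append(float(pop.genes.mean()))
    return ReplicateSummary(
        replicate_id=replicate_id,
        survived=True,
        extinction_season=None,
        final_mean_gene=float(pop.genes.mean()),
        final_sd_gene=float(pop.genes.std(ddof=1)) if pop.size > 1 else 0.0,
        final_N=pop.size,
        gene_trajectory=np.asarray(trajectory) if trajectory is not None else None,
    )
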