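"""Shared domain types, the random-number contract, and grain-correlated
environment sampling.

Two kinds of environmental grain control how strongly a single global draw
is shared among individuals:

* ``g_r`` (grain of resources) sets the correlation among the binary
  resource conditions experienced by individuals playing the variable
  strategy: each individual matches the global state ``R`` with probability
  ``0.5 + g_r/2``.
* ``g_e`` (grain of the environment) sets how tightly individual energetic
  states cluster around the global environmental quality ``E``: states are
  uniform on ``[g_e*E, E + (1 - g_e)*(1 - E)]``, which collapses to the
  point ``E`` at ``g_e = 1`` and widens to ``[0, 1]`` at ``g_e = 0``.

Both samplers return an :class:`EnvironmentDraw`; the per-individual fields
are numpy arrays so downstream season loops stay vectorized.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "PayoffParams",
    "GrainParams",
    "SimConfig",
    "EnvironmentDraw",
    "Population",
    "sample_resource_conditions",
    "sample_states",
    "replicate_rng",
    "cell_key",
]


class ParameterError(ValueError):
    """A parameter lies outside its stated domain."""


@dataclass(frozen=True)
class PayoffParams:
    """Payoff geometry of the constant versus the variable strategy.

    Parameters
    ----------
    mu : float
        Expected per-event payoff of the variable strategy (resource units).
    a : float
        Proportional penalty of the constant strategy: it pays ``mu*(1-a)``
        per event. Must lie in ``[0, 1)``.
    b : float
        Proportional variability of the variable strategy: it pays
        ``mu*(1-b)`` under a bad resource condition and ``mu*(1+b)`` under a
        good one. Must lie in ``(0, 1]``; the degenerate ``b = 0`` (payoffs
        identical to the mean) is also accepted for neutrality controls.
    """

    mu: float = 2.0
    a: float = 0.1
    b: float = 0.9

    def __post_init__(self) -> None:
        if not self.mu > 0:
            raise ParameterError(f"mu must be positive, got {self.mu}")
        if not 0 <= self.a < 1:
            raise ParameterError(f"a must lie in [0, 1), got {self.a}")
        if not 0 <= self.b <= 1:
            raise ParameterError(f"b must lie in [0, 1], got {self.b}")


@dataclass(frozen=True)
class GrainParams:
    """Among-individual correlation structure of the environment.

    ``g_r`` correlates variable-strategy payoffs; ``g_e`` correlates
    energetic states (model 2 only; ignored by model 1). Both are fractions
    in ``[0, 1]``: 0 means fully independent individuals (fine grain), 1
    means one shared global draw (coarse grain).
    """

    g_r: float = 0.0
    g_e: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.g_r <= 1:
            raise ParameterError(f"g_r must lie in [0, 1], got {self.g_r}")
        if not 0 <= self.g_e <= 1:
            raise ParameterError(f"g_e must lie in [0, 1], got {self.g_e}")


@dataclass(frozen=True)
class SimConfig:
    """Lifecycle and run control for the evolutionary simulation.

    Parameters
    ----------
    n : int
        Decision events per season prior to reproduction.
    alpha : float
        Between-season adult mortality probability. ``alpha = 1`` gives
        discrete generations; ``alpha = 0.5`` overlapping generations.
    K : int
        Carrying capacity: the maximum adult population size at the start
        of each season.
    m_p : float
        Per-offspring mutation probability.
    m_sigma : float
        Standard deviation of the Gaussian mutation kernel on the gene
        scale (the gene is a probability, so mutated values are clamped to
        ``[0, 1]``).
    seasons, replicates : int
        Run length and number of independent replicate populations.
    master_seed : int
        Root of the reproducibility contract; see :func:`replicate_rng`.
    model : {"model1", "model2"}
        Which per-season payoff model the engine runs.
    fitness_scaling : {"per_event_over_n", "per_event"}
        Model 2 only: whether each event's utility contributes ``W(x')/n``
        (default, so lifetime expectation stays near ``mu`` across n) or
        ``W(x')`` unscaled.
    offspring_rounding : {"stochastic", "poisson"}
        How a real-valued payoff total is turned into an integer offspring
        count; both are unbiased (expected offspring equals the payoff).
    redraw_strategy_per_event : bool
        Sensitivity switch: redraw each individual's strategy label at
        every event instead of once per season.
    track_trajectory : bool
        Record the per-season mean gene series in the replicate summary.
    """

    n: int = 5
    alpha: float = 1.0
    K: int = 5000
    m_p: float = 0.005
    m_sigma: float = 0.05
    seasons: int = 2000
    replicates: int = 100
    master_seed: int = 0
    model: str = "model1"
    fitness_scaling: str = "per_event_over_n"
    offspring_rounding: str = "stochastic"
    redraw_strategy_per_event: bool = False
    track_trajectory: bool = False

    def __post_init__(self) -> None:
        if not (isinstance(self.n, (int, np.integer)) and self.n >= 1):
            raise ParameterError(f"n must be a positive integer, got {self.n}")
        if not 0 <= self.alpha <= 1:
            raise ParameterError(f"alpha must lie in [0, 1], got {self.alpha}")
        if not (isinstance(self.K, (int, np.integer)) and self.K >= 1):
            raise ParameterError(f"K must be a positive integer, got {self.K}")
        if not 0 <= self.m_p <= 1:
            raise ParameterError(f"m_p must lie in [0, 1], got {self.m_p}")
        if self.m_sigma < 0:
            raise ParameterError(f"m_sigma must be non-negative, got {self.m_sigma}")
        if self.seasons < 0:
            raise ParameterError(f"seasons must be non-negative, got {self.seasons}")
        if self.replicates < 1:
            raise ParameterError(f"replicates must be positive, got {self.replicates}")
        if self.model not in ("model1", "model2"):
            raise ParameterError(f"model must be 'model1' or 'model2', got {self.model!r}")
        if self.fitness_scaling not in ("per_event", "per_event_over_n"):
            raise ParameterError(
                f"fitness_scaling must be 'per_event' or 'per_event_over_n', "
                f"got {self.fitness_scaling!r}"
            )
        if self.offspring_rounding not in ("stochastic", "poisson"):
            raise ParameterError(
                f"offspring_rounding must be 'stochastic' or 'poisson', "
                f"got {self.offspring_rounding!r}"
            )


@dataclass
class EnvironmentDraw:
    """One realization of the environment for a decision event.

    ``R`` is the overall binary resource state (0 bad, 1 good) and ``r``
    the per-individual resource conditions; ``E`` is the overall continuous
    environmental quality and ``x`` the per-individual energetic states
    (model 2 only). Fields not produced by a given sampler are ``None``.
    """

    R: Optional[int] = None
    r: Optional[np.ndarray] = None
    E: Optional[float] = None
    x: Optional[np.ndarray] = None


@dataclass
class Population:
    """An asexual population, vectorized over individuals.

    ``genes[i]`` is individual *i*'s probability of playing the variable
    (model 1) or variance-sensitive (model 2) strategy; always in [0, 1].
    Energetic states and accumulated payoffs are transient per-season
    arrays produced by the model season loops, not stored here.
    """

    genes: np.ndarray
    season: int = 0

    @property
    def size(self) -> int:
        return int(self.genes.size)

    @property
    def extinct(self) -> bool:
        return self.genes.size == 0


def sample_resource_conditions(
    g_r: float, N: int, rng: np.random.Generator, R: Optional[int] = None
) -> EnvironmentDraw:
    """Draw the global resource state and per-individual resource conditions.

    The global state ``R`` is Bernoulli(0.5) (good or bad with equal
    probability) unless supplied. Each individual's condition ``r_i``
    independently equals ``R`` with probability ``0.5 + g_r/2`` and the
    opposite state otherwise, so ``g_r = 1`` yields perfectly shared
    conditions and ``g_r = 0`` independent coin flips.
    """
    if not 0 <= g_r <= 1:
        raise ParameterError(f"g_r must lie in [0, 1], got {g_r}")
    if N < 1:
        raise ParameterError(f"N must be at least 1, got {N}")
    if R is None:
        R = int(rng.random() < 0.5)
    match = rng.random(N) < 0.5 + g_r / 2.0
    r = np.where(match, R, 1 - R).astype(np.int8)
    return EnvironmentDraw(R=R, r=r)


def sample_states(
    g_e: float, N: int, rng: np.random.Generator, E: Optional[float] = None
) -> EnvironmentDraw:
    """Draw the global environmental quality and per-individual states.

    ``E`` is uniform on [0, 1] unless supplied. Each state ``x_i`` is
    uniform on ``[g_e*E, E + (1 - g_e)*(1 - E)]``, an interval that always
    contains ``E``, narrows onto it as ``g_e`` rises, and spans [0, 1] at
    ``g_e = 0``.
    """
    if not 0 <= g_e <= 1:
        raise ParameterError(f"g_e must lie in [0, 1], got {g_e}")
    if N < 1:
        raise ParameterError(f"N must be at least 1, got {N}")
    if E is None:
        E = float(rng.random())
    lo = g_e * E
    hi = E + (1.0 - g_e) * (1.0 - E)
    x = rng.uniform(lo, hi, N) if hi > lo else np.full(N, E)
    return EnvironmentDraw(E=E, x=x)


def cell_key(**params: object) -> int:
    """Stable 32-bit key for a parameter-grid cell.

    Hashes the sorted (name, value) pairs, so the key depends only on the
    cell's own parameter values — adding or reordering cells in a sweep
    never changes another cell's random streams.
    """
    canon = ";".join(f"{k}={params[k]!r}" for k in sorted(params))
    return zlib.crc32(canon.encode())


def replicate_rng(
    master_seed: int, replicate_index: int, cell: int = 0
) -> np.random.Generator:
    """Independent child generator for one replicate.

    Children are derived from ``(master_seed, cell, replicate_index)`` via
    :class:`numpy.random.SeedSequence` spawn keys, so replicates are
    reproducible individually and independent of execution order.
    """
    ss = np.random.SeedSequence(master_seed, spawn_key=(cell, replicate_index))
    return np.random.default_rng(ss)
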