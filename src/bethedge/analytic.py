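"""Closed-form long-term fitness of the constant versus variable strategy
under fully shared payoffs (g_r = 1), and the penalty bound separating them.

When every individual playing the variable strategy draws the same outcome,
genotype fitness accumulates multiplicatively across generations and the
long-term growth of a lineage is governed by a probability-weighted
geometric mean of its lifetime payoff totals. With ``n`` independent
Bernoulli(1/2) decision events per lifetime and per-event payoffs
``mu*(1 -/+ b)``, a lifetime with ``m`` successes totals
``mu*[(1-b)*(n-m) + (1+b)*m]`` and occurs with probability
``C(n, m) * 0.5**n``, giving

    G_var,n = mu * prod_m [(1-b)(n-m) + (1+b)m] ** (C(n,m) 0.5^n).

The constant strategy pays ``mu*(1-a)`` per event deterministically, so its
lifetime total is ``G_const,n = mu*n*(1-a)``. Setting G_const,n > G_var,n
and solving for ``a`` yields the maximum penalty ``a*`` the safe strategy
can bear and still be favoured; ``a*`` is independent of ``mu``.

All products are evaluated as exponentials of weighted log sums, with
binomial weights from log-gamma, so the functions stay accurate for large
``n``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .core import ParameterError

__all__ = [
    "geometric_mean_variable",
    "constant_lifetime_payoff",
    "max_safe_penalty",
    "penalty_bound_grid",
    "PenaltyBoundGrid",
]


def _check_bn(b: float, n: int) -> None:
    if not 0 <= b <= 1:
        raise ParameterError(f"b must lie in [0, 1], got {b}")
    if not n >= 1:
        raise ParameterError(f"n must be at least 1, got {n}")


def _log_binom_weights(n: int) -> np.ndarray:
    # C(n, m) * 0.5^n for m = 0..n, in log space (exact via log-gamma)
    m = np.arange(n + 1)
    return gammaln(n + 1) - gammaln(m + 1) - gammaln(n - m + 1) - n * np.log(2.0)


def geometric_mean_variable(mu: float, b: float, n: int) -> float:
    """Weighted geometric mean of lifetime payoff totals for the variable
    strategy under fully shared outcomes.

    At ``b = 1`` the all-failure lifetime pays exactly zero, which drags
    the geometric mean to zero: the function returns 0.0 rather than
    raising on the log singularity. As ``b -> 0`` the payoffs degenerate
    to ``mu`` per event and the result approaches the arithmetic total
    ``mu*n``.
    """
    if not mu > 0:
        raise ParameterError(f"mu must be positive, got {mu}")
    _check_bn(b, n)
    m = np.arange(n + 1)
    totals = (1.0 - b) * (n - m) + (1.0 + b) * m
    if np.any(totals == 0.0):
        # b = 1: the all-failure lifetime has positive weight on a zero total
        return 0.0
    logw = _log_binom_weights(n)
    return float(mu * np.exp(np.sum(np.exp(logw) * np.log(totals))))


def constant_lifetime_payoff(mu: float, a: float, n: int) -> float:
    """Deterministic lifetime payoff total of the constant strategy,
    ``mu * n * (1 - a)``."""
    if not mu > 0:
        raise ParameterError(f"mu must be positive, got {mu}")
    if not 0 <= a < 1:
        raise ParameterError(f"a must lie in [0, 1), got {a}")
    if not n >= 1:
        raise ParameterError(f"n must be at least 1, got {n}")
    return mu * n * (1.0 - a)


def max_safe_penalty(b: float, n: int) -> float:
    """Largest constant-strategy penalty ``a*`` at which the constant
    strategy still beats the variable one under fully shared payoffs.

    ``a* = 1 - G_var,n / (mu * n)``; the ``mu`` factors cancel, so the
    bound depends only on ``b`` and ``n``. The constant strategy has the
    higher lineage payoff iff ``a < a*``.
    """
    _check_bn(b, n)
    return 1.0 - geometric_mean_variable(1.0, b, n) / n


@dataclass(frozen=True)
class PenaltyBoundGrid:
    """Matrix of maximum safe penalties a* over a (b, n) grid.

    ``bound[i, j] = max_safe_penalty(b_values[i], n_values[j])``. The bound
    grows with payoff variability ``b`` and shrinks with the number of
    decision events ``n``.
    """

    b_values: np.ndarray
    n_values: np.ndarray
    bound: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with columns (b, n, a_max)."""
        bb, nn = np.meshgrid(self.b_values, self.n_values, indexing="ij")
        return pd.DataFrame(
            {"b": bb.ravel(), "n": nn.ravel(), "a_max": self.bound.ravel()}
        )


DEFAULT_B_GRID = np.round(np.arange(0.05, 1.0001, 0.05), 10)
DEFAULT_N_GRID = np.arange(1, 11)


def penalty_bound_grid(
    b_values: Sequence[float] = DEFAULT_B_GRID,
    n_values: Sequence[int] = DEFAULT_N_GRID,
) -> PenaltyBoundGrid:
    """Evaluate :func:`max_safe_penalty` over a (b, n) grid for contour
    rendering."""
    b_arr = np.asarray(b_values, dtype=float)
    n_arr = np.asarray(n_values, dtype=int)
    if b_arr.size == 0 or n_arr.size == 0:
        raise ParameterError("b_values and n_values must be non-empty")
    bound = np.empty((b_arr.size, n_arr.size))
    for i, b in enumerate(b_arr):
        for j, n in enumerate(n_arr):
            bound[i, j] = max_safe_penalty(float(b), int(n))
    return PenaltyBoundGrid(b_values=b_arr, n_values=n_arr, bound=bound)
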