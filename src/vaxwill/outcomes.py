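"""Exact distribution of the number of vaccinated agents.

Given steady-state vaccination probabilities ``p_1..p_n``, the jab
decisions are independent Bernoulli trials, so the number of vaccinated
agents follows a Poisson-binomial law.  The pmf is computed exactly by
iterative convolution (dynamic programming over agents, ``O(n^2)``),
which is numerically stable well past ``n = 10^4``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "OutcomeDistribution",
    "poisson_binomial",
    "expected_fraction",
    "fraction_variance",
    "tail_probability",
]


@dataclass(frozen=True)
class OutcomeDistribution:
    """Poisson-binomial pmf over vaccination counts ``0..n``."""

    pmf: np.ndarray
    n: int

    def __post_init__(self):
        pmf = np.ascontiguousarray(self.pmf, dtype=float)
        object.__setattr__(self, "pmf", pmf)
        if pmf.shape != (self.n + 1,):
            raise ValueError("pmf must have length n + 1")

    @property
    def mean(self) -> float:
        """Expected vaccination count, equal to ``sum(p_i)``."""
        return float(np.arange(self.n + 1) @ self.pmf)

    @property
    def variance(self) -> float:
        """Variance of the count, equal to ``sum(p_i (1 - p_i))``."""
        k = np.arange(self.n + 1)
        return float((k - self.mean) ** 2 @ self.pmf)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"count": np.arange(self.n + 1), "probability": self.pmf}).to_csv(
            path, index=False
        )


def _validate_probs(p) -> np.ndarray:
    p = np.ascontiguousarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("expected a non-empty 1-D probability vector")
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    return p


def poisson_binomial(p) -> OutcomeDistribution:
    """Exact pmf of the sum of independent Bernoulli(p_i) variables.

    Agents are folded in one at a time:
    ``pmf_new[k] = (1 - p_i) pmf[k] + p_i pmf[k-1]``.  All terms are
    nonnegative, so no catastrophic cancellation occurs.
    """
    p = _validate_probs(p)
    n = p.size
    pmf = np.zeros(n + 1)
    pmf[0] = 1.0
    for i, pi in enumerate(p):
        # touch only the populated prefix 0..i+1
        head = pmf[: i + 2]
        head[1:] = head[1:] * (1.0 - pi) + head[:-1] * pi
        head[0] *= 1.0 - pi
    return OutcomeDistribution(pmf=pmf, n=n)


def expected_fraction(p) -> float:
    """Expected fraction of the population vaccinated, ``mean(p)``."""
    p = _validate_probs(p)
    return float(p.mean())


def fraction_variance(p) -> float:
    """Variance of the vaccinated fraction, ``sum p_i(1-p_i) / n^2``.

    Bounded by ``1/(4n)``, hence vanishing as the population grows: the
    expected fraction is a reliable summary for country-scale populations.
    """
    p = _validate_probs(p)
    return float(np.sum(p * (1.0 - p)) / p.size**2)


def tail_probability(dist: OutcomeDistribution, fraction: float) -> float:
    """Probability that at least ``fraction`` of the population vaccinates.

    Computed as ``P(count >= ceil(fraction * n))`` from the exact pmf.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction threshold must lie in [0, 1]")
    k_min = int(np.ceil(fraction * dist.n))
    return float(dist.pmf[k_min:].sum())
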