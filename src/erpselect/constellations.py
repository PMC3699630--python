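"""Beta-distribution model of random-constellation performance.

The balanced accuracies of uniformly sampled sensor constellations of a fixed
size are modelled as Beta(alpha, beta).  From the fit, the probability that a
random constellation reaches a given accuracy — and hence the expected number
of random draws needed to match a selected constellation — follows from the
beta survival function.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import comb
from typing import Optional, Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger("erpselect")

BOUNDARY_CLAMP = 1e-6
MIN_SAMPLES = 10


@dataclass
class BetaFit:
    """Fitted shape parameters of the constellation-performance distribution."""

    alpha: float
    beta: float
    n_samples: int
    size: Optional[int] = None  # constellation size m, if known

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("beta shape parameters must be positive")

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)


def clamp_accuracies(values: Sequence[float], eps: float = BOUNDARY_CLAMP) -> np.ndarray:
    """Pull exact 0/1 accuracies just inside (0,1), where the likelihood exists."""
    return np.clip(np.asarray(values, dtype=float), eps, 1.0 - eps)


def fit_beta(accuracies: Sequence[float], size: Optional[int] = None) -> BetaFit:
    """Maximum-likelihood beta fit with method-of-moments start values.

    Values must lie strictly inside (0, 1); callers holding exact 0/1 scores
    clamp them explicitly with :func:`clamp_accuracies` first.
    """
    x = np.asarray(accuracies, dtype=float)
    if len(x) < MIN_SAMPLES:
        raise ValueError(f"need at least {MIN_SAMPLES} accuracy values, got {len(x)}")
    if np.any(x <= 0) or np.any(x >= 1):
        raise ValueError(
            "accuracies must lie strictly in (0, 1); "
            "clamp boundary values explicitly with clamp_accuracies()"
        )
    m, v = float(x.mean()), float(x.var())
    if v <= 0:
        raise ValueError("accuracies are all identical; no beta fit possible")
    # method-of-moments starting point
    common = m * (1 - m) / v - 1.0
    a0 = max(m * common, 1e-3)
    b0 = max((1 - m) * common, 1e-3)
    a, b, loc, scale = stats.beta.fit(x, a0, b0, floc=0.0, fscale=1.0)
    return BetaFit(alpha=float(a), beta=float(b), n_samples=len(x), size=size)


def exceedance(fit: BetaFit, q: float) -> float:
    """P(bACC >= q) for a random constellation under the fitted model."""
    if not 0.0 <= q <= 1.0:
        raise ValueError("q must be in [0, 1]")
    return float(stats.beta.sf(q, fit.alpha, fit.beta))


def expected_random_draws(fit: BetaFit, q: float) -> float:
    """Expected number of random constellations to draw before one reaches q.

    The reciprocal of the exceedance probability; infinite when the fitted
    model puts no mass at or above q.
    """
    p = exceedance(fit, q)
    return float("inf") if p == 0 else 1.0 / p


def best_constellation_probability(n_sensors: int, size: int) -> float:
    """Probability of sampling the (unknown) best size-m constellation: 1/C(n,m)."""
    if not 0 < size <= n_sensors:
        raise ValueError("size must be in 1..n_sensors")
    return 1.0 / comb(n_sensors, size)
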