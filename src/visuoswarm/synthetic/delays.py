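"""Population delay sampling.

Individual visuomotor transport delays vary across a population; the
measured distribution is summarized by a Gaussian with mean 22 ms and
standard deviation 40 ms, restricted to positive delays.  The sampler draws
from that truncated Gaussian N(tau > 0 | mu, sigma) — truncation, not
clipping, so no probability mass piles up at zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["DelayPopulationSpec", "sample_population_delays", "truncated_gaussian_mean"]

#: Measured population summary: mean / SD of the delay distribution in ms.
MEASURED_DELAY_MEAN_MS = 22.0
MEASURED_DELAY_SD_MS = 40.0


@dataclass
class DelayPopulationSpec:
    """Gaussian delay population truncated to positive delays.

    mu, sigma in milliseconds; n is the number of individuals.
    """

    mu: float = MEASURED_DELAY_MEAN_MS
    sigma: float = MEASURED_DELAY_SD_MS
    n: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("population size must be >= 1")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


def sample_population_delays(spec: DelayPopulationSpec) -> np.ndarray:
    """Draw n strictly positive delays (ms) from N(tau > 0 | mu, sigma).

    Deterministic under a fixed seed.  sigma = 0 returns n copies of mu
    (which must then be positive).
    """
    if spec.sigma == 0:
        if spec.mu <= 0:
            raise ValueError("sigma=0 requires a positive mu")
        return np.full(spec.n, float(spec.mu))
    a = (0.0 - spec.mu) / spec.sigma  # lower truncation bound in SD units
    rng = np.random.default_rng(spec.seed)
    draws = stats.truncnorm.rvs(
        a, np.inf, loc=spec.mu, scale=spec.sigma, size=spec.n, random_state=rng
    )
    return np.asarray(draws, dtype=float)


def truncated_gaussian_mean(mu: float, sigma: float) -> float:
    """Mean of the positive-truncated Gaussian (closed form)."""
    if sigma == 0:
        return mu
    a = (0.0 - mu) / sigma
    return float(stats.truncnorm.mean(a, np.inf, loc=mu, scale=sigma))
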