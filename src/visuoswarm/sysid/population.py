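"""Population summary of identified delays."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DelayPopulation", "fit_population_gaussian"]


@dataclass
class DelayPopulation:
    """Per-individual delays (ms) with a fitted Gaussian summary."""

    delays_ms: np.ndarray
    mu_ms: float
    sigma_ms: float

    def histogram(self, bin_width_ms: float = 10.0) -> tuple[np.ndarray, np.ndarray]:
        """Histogram (counts, bin edges) with a configurable bin width."""
        d = self.delays_ms
        lo = np.floor(d.min() / bin_width_ms) * bin_width_ms
        hi = np.ceil(d.max() / bin_width_ms) * bin_width_ms + bin_width_ms
        edges = np.arange(lo, hi + bin_width_ms / 2, bin_width_ms)
        counts, edges = np.histogram(d, bins=edges)
        return counts, edges


def fit_population_gaussian(delays_ms: np.ndarray) -> DelayPopulation:
    """Gaussian summary (sample mean and SD) of per-individual delays in ms."""
    d = np.asarray(delays_ms, dtype=float)
    if len(d) < 2:
        raise ValueError("need at least two delays to fit a population")
    return DelayPopulation(
        delays_ms=d, mu_ms=float(d.mean()), sigma_ms=float(d.std(ddof=0))
    )
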