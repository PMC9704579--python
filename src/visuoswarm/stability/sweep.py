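"""Delay-distribution stability map and measured-delay runs.

For each (mu, sigma) cell of a grid, per-agent delays are sampled from the
positive-truncated Gaussian N(tau > 0 | mu, sigma), the swarm is simulated,
and the barycenter is classified stable/unstable; the cell label is the
majority over replicates.  A cubic polynomial sigma_boundary(mu) is fitted
to the stable cells that touch unstable ones, describing the boundary
between the two regions.

Delay values enter the (dimensionless) swarm model numerically as model
time units; see the methods note on units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..swarm.config import SwarmConfig
from ..swarm.simulate import SwarmResult, run_swarm
from ..synthetic.delays import DelayPopulationSpec, sample_population_delays
from .classify import StabilityVerdict, barycenter_stability

__all__ = ["StabilityMap", "delay_stability_sweep", "run_measured_delays"]

_SEED_MOD = 2**31 - 1


def _cell_seed(base: int, i: int, j: int, rep: int) -> int:
    return (base * 100_003 + i * 10_007 + j * 1_009 + rep * 101 + 7) % _SEED_MOD


@dataclass
class StabilityMap:
    """Grid of (mu, sigma) delay-distribution parameters with labels."""

    mu_grid: np.ndarray
    sigma_grid: np.ndarray
    stable: np.ndarray  # (n_mu, n_sigma) bool
    unstable_votes: np.ndarray  # (n_mu, n_sigma) int
    replicates: int
    failed: np.ndarray  # cells where every replicate diverged before settling
    boundary_coeffs: np.ndarray | None  # cubic, highest power first
    boundary_residual: float
    classifier_params: dict = field(default_factory=dict)

    def boundary_sigma(self, mu: np.ndarray) -> np.ndarray:
        if self.boundary_coeffs is None:
            raise ValueError("no stable/unstable boundary was found to fit")
        return np.polyval(self.boundary_coeffs, np.asarray(mu, dtype=float))

    def cell(self, mu: float, sigma: float) -> bool:
        """Stable label of the cell nearest to (mu, sigma)."""
        i = int(np.argmin(np.abs(self.mu_grid - mu)))
        j = int(np.argmin(np.abs(self.sigma_grid - sigma)))
        return bool(self.stable[i, j])

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for i, mu in enumerate(self.mu_grid):
            for j, sig in enumerate(self.sigma_grid):
                rows.append(
                    {
                        "mu": mu,
                        "sigma": sig,
                        "label": "stable" if self.stable[i, j] else "unstable",
                        "unstable_votes": int(self.unstable_votes[i, j]),
                        "replicates": self.replicates,
                    }
                )
        return pd.DataFrame(rows)


def _boundary_fit(
    mu_grid: np.ndarray, sigma_grid: np.ndarray, stable: np.ndarray
) -> tuple[np.ndarray | None, float]:
    """Cubic fit sigma(mu) through stable cells 4-adjacent to unstable ones."""
    n_mu, n_sig = stable.shape
    pts = []
    for i in range(n_mu):
        for j in range(n_sig):
            if not stable[i, j]:
                continue
            for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                ii, jj = i + di, j + dj
                if 0 <= ii < n_mu and 0 <= jj < n_sig and not stable[ii, jj]:
                    pts.append((mu_grid[i], sigma_grid[j]))
                    break
    if len(pts) < 4:
        return None, np.nan
    pts = np.asarray(pts, dtype=float)
    coeffs = np.polyfit(pts[:, 0], pts[:, 1], deg=3)
    resid = float(np.sqrt(np.mean((np.polyval(coeffs, pts[:, 0]) - pts[:, 1]) ** 2)))
    return coeffs, resid


def delay_stability_sweep(
    base_config: SwarmConfig,
    mu_grid: np.ndarray | None = None,
    sigma_grid: np.ndarray | None = None,
    replicates: int = 3,
    seed: int = 0,
    settle_fraction: float = 0.5,
    slope_tol: float | None = None,
    osc_tol: float | None = None,
) -> StabilityMap:
    """Sweep the Gaussian delay-distribution parameters and label each cell.

    Defaults: mu and sigma in {0, 10, ..., 100} delay units, 3 replicates.
    A diverged run counts as an unstable vote.  Bit-reproducible under fixed
    ``seed`` (per-cell seeds are derived deterministically).
    """
    mu_grid = np.arange(0.0, 101.0, 10.0) if mu_grid is None else np.asarray(mu_grid, float)
    sigma_grid = (
        np.arange(0.0, 101.0, 10.0) if sigma_grid is None else np.asarray(sigma_grid, float)
    )
    if replicates < 1:
        raise ValueError("need at least one replicate per cell")

    n_mu, n_sig = len(mu_grid), len(sigma_grid)
    votes = np.zeros((n_mu, n_sig), dtype=int)
    failed = np.zeros((n_mu, n_sig), dtype=bool)
    for i, mu in enumerate(mu_grid):
        for j, sigma in enumerate(sigma_grid):
            n_fail = 0
            for rep in range(replicates):
                cseed = _cell_seed(seed, i, j, rep)
                if sigma == 0:
                    delays = np.full(base_config.n, float(mu))
                else:
                    delays = sample_population_delays(
                        DelayPopulationSpec(mu=mu, sigma=sigma, n=base_config.n,
                                            seed=cseed)
                    )
                cfg = SwarmConfig(
                    **{**base_config.__dict__, "delays": delays, "seed": cseed}
                )
                res = run_swarm(cfg)
                if res.diverged_at is not None and len(res.times) < 3:
                    n_fail += 1
                    votes[i, j] += 1
                    continue
                verdict = barycenter_stability(
                    res, settle_fraction=settle_fraction,
                    slope_tol=slope_tol, osc_tol=osc_tol,
                )
                votes[i, j] += int(not verdict.stable)
            failed[i, j] = n_fail == replicates
    stable = votes <= replicates // 2
    coeffs, resid = _boundary_fit(mu_grid, sigma_grid, stable & ~failed)
    scale = max(base_config.r, base_config.cr)
    return StabilityMap(
        mu_grid=mu_grid,
        sigma_grid=sigma_grid,
        stable=stable,
        unstable_votes=votes,
        replicates=replicates,
        failed=failed,
        boundary_coeffs=coeffs,
        boundary_residual=resid,
        classifier_params={
            "settle_fraction": settle_fraction,
            "slope_tol": 0.01 * scale if slope_tol is None else slope_tol,
            "osc_tol": 0.01 * scale if osc_tol is None else osc_tol,
        },
    )


def run_measured_delays(
    config: SwarmConfig,
    delays: np.ndarray,
    seed: int | None = None,
    settle_fraction: float = 0.5,
) -> tuple[SwarmResult, StabilityVerdict]:
    """Assign measured per-individual delays to agents, run, and classify.

    When the swarm has more agents than measured individuals, delays are
    resampled with replacement (seeded); with fewer agents a random subset
    is used.  Delays must be strictly positive.
    """
    delays = np.asarray(delays, dtype=float)
    if delays.size == 0:
        raise ValueError("empty delay list")
    if np.any(delays <= 0):
        raise ValueError("measured delays must be strictly positive")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    if len(delays) != config.n:
        delays = rng.choice(delays, size=config.n, replace=len(delays) < config.n)
    cfg = SwarmConfig(**{**config.__dict__, "delays": delays})
    res = run_swarm(cfg)
    verdict = barycenter_stability(res, settle_fraction=settle_fraction)
    return res, verdict
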