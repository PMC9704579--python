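"""Barycenter position-stability classification of completed swarm runs.

The delayed swarm has no closed-form stability criterion, so stability is
assessed from simulation: the swarm barycenter R_C(t) is *position stable*
when its norm settles — no residual trend and no sustained fluctuation over
the tail of the run.  Concretely, a line is fitted to ||R_C||(t) over the
final (1 - settle_fraction) of the horizon and the run is unstable when

* the run lost finiteness (divergence), or
* |slope| of the fitted line exceeds ``slope_tol`` (drift), or
* the residual SD around the line exceeds ``osc_tol`` (sustained
  oscillation), or
* max ||R_C(t) - R_C(0)|| exceeds ``drift_tol`` times the initial
  agent-cloud radius (gross displacement).

Defaults put the slope and oscillation tolerances at 1% of the pattern
length scale max(r, C_r) — per time unit for the slope — and drift_tol = 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..swarm.simulate import SwarmResult

__all__ = ["StabilityVerdict", "barycenter_stability"]


@dataclass
class StabilityVerdict:
    stable: bool
    slope: float  # trend of ||R_C|| over the settle window, per time unit
    oscillation: float  # residual SD around the trend
    max_excursion: float  # max ||R_C(t) - R_C(0)||
    slope_tol: float
    osc_tol: float
    drift_limit: float
    diverged: bool

    @property
    def label(self) -> str:
        return "stable" if self.stable else "unstable"


def barycenter_stability(
    result: SwarmResult,
    settle_fraction: float = 0.5,
    slope_tol: float | None = None,
    osc_tol: float | None = None,
    drift_tol: float = 2.0,
) -> StabilityVerdict:
    """Classify a completed run as barycenter stable or unstable."""
    cfg = result.config
    scale = max(cfg.r, cfg.cr)
    slope_tol = 0.01 * scale if slope_tol is None else slope_tol
    osc_tol = 0.01 * scale if osc_tol is None else osc_tol

    t = result.times
    horizon = t[-1] if len(t) else 0.0
    sel = t >= settle_fraction * horizon
    if sel.sum() < 3:
        raise ValueError("horizon too short for the requested settle window")

    rn = result.barycenter_norm
    A = np.column_stack([t[sel], np.ones(sel.sum())])
    coef, *_ = np.linalg.lstsq(A, rn[sel], rcond=None)
    slope = float(coef[0])
    osc = float((rn[sel] - A @ coef).std())

    r0 = result.positions[0]
    cloud_radius = float(
        np.linalg.norm(r0 - r0.mean(axis=0), axis=1).max()
    )
    excursion = float(
        np.linalg.norm(result.barycenter - result.barycenter[0], axis=1).max()
    )
    diverged = result.diverged_at is not None

    unstable = (
        diverged
        or abs(slope) > slope_tol
        or osc > osc_tol
        or excursion > drift_tol * cloud_radius
    )
    return StabilityVerdict(
        stable=not unstable,
        slope=slope,
        oscillation=osc,
        max_excursion=excursion,
        slope_tol=slope_tol,
        osc_tol=osc_tol,
        drift_limit=drift_tol * cloud_radius,
        diverged=diverged,
    )
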