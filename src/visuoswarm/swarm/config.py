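"""Swarm model configuration.

Second-order attraction-repulsion dynamics for N visually interconnected
agents: each agent accelerates down the gradient of an attractive potential
(quadratic-quartic in the mean displacement from its delayed view of the
others, with coupling rho and target radius r) plus an exponential
short-range repulsion (amplitude Br, length Cr), damped by friction beta.
Neighbour positions are perceived with per-agent transport delays and,
optionally, through each agent's identified transfer function.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ..sysid.models import TransferFunctionModel

__all__ = ["SwarmConfig", "PATTERN_PARAMS"]

#: Parameter rows generating the three characteristic patterns
#: (N, rho, r, Br, Cr, beta).
PATTERN_PARAMS = {
    "ring": dict(n=30, rho=-4.0, r=3.0, br=1.0, cr=0.5, beta=10.0),
    "double_ring": dict(n=50, rho=1.5, r=3.0, br=1.0, cr=0.5, beta=10.0),
    "cluster": dict(n=50, rho=-4.0, r=0.0, br=1.0, cr=0.5, beta=10.0),
}


@dataclass
class SwarmConfig:
    """Full parameterization of the delayed swarm simulation.

    ``delays`` may be a scalar (common delay), a length-N array (the
    perceiving agent's processing delay, applied to every neighbour it
    observes), or an (N, N) matrix of per-link delays; units are the
    simulation time unit.  ``filters`` optionally assigns each agent an
    identified transfer-function model through which its broadcast position
    is perceived.
    """

    n: int = 50
    rho: float = -4.0
    r: float = 0.0
    br: float = 1.0
    cr: float = 0.5
    beta: float = 10.0
    mass: float = 1.0
    dim: int = 2
    delays: float | Sequence[float] | np.ndarray = 0.0
    filters: Optional[Sequence[Optional[TransferFunctionModel]]] = None
    dt: float = 0.001
    horizon: float = 10.0
    init_radius: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("need at least two agents")
        if self.dt <= 0 or self.horizon <= 0:
            raise ValueError("dt and horizon must be positive")
        if self.cr <= 0:
            raise ValueError("repulsion length Cr must be positive")
        if self.mass <= 0:
            raise ValueError("mass must be positive")
        if self.dim not in (2, 3):
            raise ValueError("dimension must be 2 or 3")
        if self.filters is not None and len(self.filters) != self.n:
            raise ValueError("filters must give one entry (or None) per agent")

    def delay_matrix_or_vector(self) -> np.ndarray:
        """Normalize ``delays`` to a (n,) per-agent vector or (n, n) matrix."""
        d = np.asarray(self.delays, dtype=float)
        if d.ndim == 0:
            d = np.full(self.n, float(d))
        if d.ndim == 1 and len(d) != self.n:
            raise ValueError(f"expected {self.n} per-agent delays, got {len(d)}")
        if d.ndim == 2 and d.shape != (self.n, self.n):
            raise ValueError("delay matrix must be (n, n)")
        if np.any(d < 0):
            raise ValueError("delays must be non-negative")
        return d

    @property
    def n_steps(self) -> int:
        return int(round(self.horizon / self.dt))

    def initial_positions(self) -> np.ndarray:
        """Seeded initial condition: positions uniform in a disc (or ball)
        of ``init_radius``, velocities zero."""
        rng = np.random.default_rng(self.seed)
        pts = np.empty((self.n, self.dim))
        k = 0
        while k < self.n:
            cand = rng.uniform(-self.init_radius, self.init_radius, self.dim)
            if np.linalg.norm(cand) <= self.init_radius:
                pts[k] = cand
                k += 1
        return pts
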