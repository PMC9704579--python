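"""Delayed swarm integration and consensus metrics.

The model, per agent i with position x_i and velocity v_i:

    dx_i/dt = v_i
    m dv_i/dt = -grad_i A^a - grad_i A^r - beta v_i

with the attraction gradient I * unit(X_i) where
X_i = sum_{j != i} (x_i(t) - x_j(t - tau_ij)) and
I = -rho (||X_i/N|| - r) + (||X_i/N|| - r)^3, and the repulsion gradient
summing (Br/Cr) e^{-d/Cr} along the unit vector from each delayed neighbour
to the agent.  The delay differential system is integrated with fixed-step
RK4; delayed positions are linearly interpolated in the stored position
history (constant pre-history x_j(t)=x_j(0) for t<0); delays shorter than a
stage offset fall back to the first-order extrapolation x - tau*v.

Consensus metrics: X_m(t) and V_m(t) are the maximum pairwise position and
velocity differences; R_C(t) is the barycenter.  Bounded X_m with vanishing
V_m is the flocking-type consensus criterion; boundedness of ||R_C|| is the
position-stability criterion examined under measured delay distributions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import SwarmConfig
from .filters import AgentFilterBank

__all__ = [
    "SwarmResult",
    "SwarmDivergence",
    "run_swarm",
    "attraction_gradient",
    "repulsion_gradient",
    "lyapunov_energy",
]


class SwarmDivergence(RuntimeError):
    """Raised when the state stops being finite; carries the failure time."""

    def __init__(self, t: float):
        super().__init__(f"swarm state became non-finite at t = {t:.4f}")
        self.t = t


@dataclass
class SwarmResult:
    """Trajectory record and consensus metrics of one simulation."""

    times: np.ndarray  # (n_rec,)
    positions: np.ndarray  # (n_rec, N, dim)
    velocities: np.ndarray  # (n_rec, N, dim)
    x_m: np.ndarray  # max pairwise displacement
    v_m: np.ndarray  # max pairwise velocity difference
    barycenter: np.ndarray  # (n_rec, dim)
    config: SwarmConfig
    diverged_at: float | None = None

    @property
    def barycenter_norm(self) -> np.ndarray:
        return np.linalg.norm(self.barycenter, axis=1)

    def consensus_reached(self, v_tol: float = 1e-3) -> bool:
        """Bounded X_m and V_m(T) below tolerance."""
        return bool(np.all(np.isfinite(self.x_m)) and self.v_m[-1] < v_tol)

    def radii(self, at: int = -1) -> np.ndarray:
        """Agent distances from the barycenter at a recorded step."""
        return np.linalg.norm(
            self.positions[at] - self.barycenter[at][None, :], axis=1
        )


# ---------------------------------------------------------------------------
# force terms (exposed for unit tests and direct inspection)
# ---------------------------------------------------------------------------

def _attraction_from_X(X: np.ndarray, n: int, rho: float, r: float) -> np.ndarray:
    """Force -I*unit(X) from the summed delayed displacement X, per agent."""
    u = np.linalg.norm(X, axis=-1) / n
    I = -rho * (u - r) + (u - r) ** 3
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(
            (u > 0)[..., None], X / (n * u[..., None]).clip(min=1e-300), 0.0
        )
    return -I[..., None] * unit


def attraction_gradient(
    x_i: np.ndarray,
    delayed_neighbours: np.ndarray,
    n: int,
    rho: float,
    r: float,
) -> np.ndarray:
    """Attraction force on one agent given its delayed view of the others.

    ``delayed_neighbours`` has shape (n-1, dim).  Coincident configurations
    (X_i = 0) give a zero force — the direction is undefined there.
    """
    X = (n - 1) * x_i - delayed_neighbours.sum(axis=0)
    return _attraction_from_X(X, n, rho, r)


def repulsion_gradient(
    x_i: np.ndarray,
    delayed_neighbours: np.ndarray,
    br: float,
    cr: float,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Repulsive force on one agent: (Br/Cr) e^{-d/Cr} away from each
    delayed neighbour.  A coincident pair gets a random direction (seeded
    generator) at magnitude Br/Cr."""
    diff = x_i[None, :] - delayed_neighbours
    dist = np.linalg.norm(diff, axis=1)
    force = np.zeros_like(x_i)
    for k in range(len(diff)):
        mag = (br / cr) * np.exp(-dist[k] / cr)
        if dist[k] < 1e-12:
            rng = rng or np.random.default_rng(0)
            direction = rng.normal(size=len(x_i))
            direction /= np.linalg.norm(direction)
        else:
            direction = diff[k] / dist[k]
        force += mag * direction
    return force


def lyapunov_energy(x: np.ndarray, v: np.ndarray, config: SwarmConfig) -> float:
    """Energy functional that decreases along delay-free, repulsion-free
    trajectories: relative kinetic energy plus the attraction potential.

    Because every agent's force depends only on its displacement from the
    barycenter, the dissipation identity involves velocities relative to the
    mean: E = sum_i (m/2)|v_i|^2 - (N m/2)|v_mean|^2 + sum_i A^a(u_i),
    with A^a(u) = -(rho/2)(u-r)^2 + (1/4)(u-r)^4 and u_i the distance of
    agent i from the barycenter.
    """
    n = config.n
    vbar = v.mean(axis=0)
    u = np.linalg.norm(x - x.mean(axis=0), axis=1)
    pot = -0.5 * config.rho * (u - config.r) ** 2 + 0.25 * (u - config.r) ** 4
    kin = 0.5 * config.mass * (np.sum(v**2) - n * np.sum(vbar**2))
    return float(kin + pot.sum())


# ---------------------------------------------------------------------------
# integrator
# ---------------------------------------------------------------------------

def _max_pairwise(a: np.ndarray) -> float:
    diff = a[:, None, :] - a[None, :, :]
    return float(np.sqrt((diff**2).sum(-1)).max())


class _Integrator:
    def __init__(self, config: SwarmConfig):
        self.cfg = config
        self.n = config.n
        self.dim = config.dim
        delays = config.delay_matrix_or_vector()
        self.per_agent = delays.ndim == 1
        self.delays = delays
        self.rng = np.random.default_rng(config.seed + 1)
        n_steps = config.n_steps
        self.history = np.empty((n_steps + 1, self.n, self.dim))
        self.filters = (
            AgentFilterBank(config.filters, config.dt)
            if config.filters is not None
            else None
        )

    # -- delayed position lookup -------------------------------------------
    def _snapshot(self, t_stage: float, tau: np.ndarray, n_stored: int,
                  x_stage: np.ndarray, v_stage: np.ndarray) -> np.ndarray:
        """Positions of all agents as perceived with per-row delays tau.

        Returns (len(tau), n, dim): row i is the full position array at time
        t_stage - tau[i], linearly interpolated in the stored history
        (constant pre-history before t=0).  Delays shorter than the stage
        offset would need not-yet-stored history; those rows use the
        first-order extrapolation x_stage - tau*v_stage instead.
        """
        dt = self.cfg.dt
        t_newest = (n_stored - 1) * dt
        tq = t_stage - tau
        out = np.empty((len(tau), self.n, self.dim))
        beyond = tq >= t_newest - 1e-15
        inside = ~beyond
        if inside.any():
            tqi = np.clip(tq[inside], 0.0, None)
            idx = np.clip((tqi / dt).astype(int), 0, max(0, n_stored - 2))
            w = np.clip(tqi / dt - idx, 0.0, 1.0)
            hi = np.minimum(idx + 1, n_stored - 1)
            wi = w[:, None, None]
            out[inside] = (1 - wi) * self.history[idx] + wi * self.history[hi]
        if beyond.any():
            lag = tau[beyond][:, None, None]
            out[beyond] = x_stage[None] - lag * v_stage[None]
        return out

    def _delayed_views(self, t_stage: float, n_stored: int,
                       x_stage: np.ndarray, v_stage: np.ndarray) -> np.ndarray:
        if self.per_agent:
            return self._snapshot(
                t_stage, self.delays, n_stored, x_stage, v_stage
            )
        # full per-link matrix: one lookup per perceiving agent row
        out = np.empty((self.n, self.n, self.dim))
        eye = np.arange(self.n)
        for i in range(self.n):
            snap = self._snapshot(
                t_stage, self.delays[i], n_stored, x_stage, v_stage
            )
            out[i] = snap[eye, eye]
        return out

    # -- forces -------------------------------------------------------------
    def _accel(self, x: np.ndarray, v: np.ndarray, t_stage: float,
               n_stored: int) -> np.ndarray:
        cfg = self.cfg
        delayed = self._delayed_views(t_stage, n_stored, x, v)  # (n, n, dim)
        eye = np.arange(self.n)
        own = delayed[eye, eye]  # delayed self-positions, excluded from sums

        X = (self.n - 1) * x - (delayed.sum(axis=1) - own)
        f_att = _attraction_from_X(X, self.n, cfg.rho, cfg.r)

        diff = x[:, None, :] - delayed  # (n, n, dim)
        dist = np.sqrt((diff**2).sum(-1))
        np.fill_diagonal(dist, np.inf)  # self-pairs contribute nothing
        coincident = dist < 1e-12
        if coincident.any():
            rnd = self.rng.normal(size=(int(coincident.sum()), self.dim))
            rnd /= np.linalg.norm(rnd, axis=1, keepdims=True)
            diff[coincident] = rnd
            dist[coincident] = 1.0  # direction random, magnitude Br/Cr
        mag = (cfg.br / cfg.cr) * np.exp(-dist / cfg.cr)
        f_rep = (mag[..., None] * diff / dist[..., None]).sum(axis=1)

        return (f_att + f_rep - cfg.beta * v) / cfg.mass

    # -- main loop ----------------------------------------------------------
    def run(self) -> SwarmResult:
        cfg = self.cfg
        dt = cfg.dt
        x = cfg.initial_positions()
        v = np.zeros_like(x)
        self.history[0] = self._broadcast(x)
        n_steps = cfg.n_steps

        times = np.empty(n_steps + 1)
        xs = np.empty((n_steps + 1, self.n, self.dim))
        vs = np.empty_like(xs)
        xm = np.empty(n_steps + 1)
        vm = np.empty(n_steps + 1)
        rc = np.empty((n_steps + 1, self.dim))
        diverged_at = None

        def record(k, t):
            times[k] = t
            xs[k], vs[k] = x, v
            xm[k] = _max_pairwise(x)
            vm[k] = _max_pairwise(v)
            rc[k] = x.mean(axis=0)

        record(0, 0.0)
        for k in range(n_steps):
            t = k * dt
            n_stored = k + 1
            with np.errstate(over="ignore", invalid="ignore"):
                a1 = self._accel(x, v, t, n_stored)
                x2, v2 = x + 0.5 * dt * v, v + 0.5 * dt * a1
                a2 = self._accel(x2, v2, t + 0.5 * dt, n_stored)
                x3, v3 = x + 0.5 * dt * v2, v + 0.5 * dt * a2
                a3 = self._accel(x3, v3, t + 0.5 * dt, n_stored)
                x4, v4 = x + dt * v3, v + dt * a3
                a4 = self._accel(x4, v4, t + dt, n_stored)
                x = x + dt / 6.0 * (v + 2 * v2 + 2 * v3 + v4)
                v = v + dt / 6.0 * (a1 + 2 * a2 + 2 * a3 + a4)
            if not (np.all(np.isfinite(x)) and np.all(np.isfinite(v))):
                diverged_at = t + dt
                break
            self.history[k + 1] = self._broadcast(x)
            record(k + 1, t + dt)

        if diverged_at is not None:
            keep = slice(0, k + 1)
            return SwarmResult(
                times[keep], xs[keep], vs[keep], xm[keep], vm[keep], rc[keep],
                cfg, diverged_at=diverged_at,
            )
        return SwarmResult(times, xs, vs, xm, vm, rc, cfg)

    def _broadcast(self, x: np.ndarray) -> np.ndarray:
        """Position each agent broadcasts: raw, or filtered through its
        identified transfer function (recursive difference equation)."""
        if self.filters is None:
            return x
        return self.filters.step(x)


def run_swarm(config: SwarmConfig) -> SwarmResult:
    """Integrate the delayed swarm model and return trajectories + metrics.

    Raises :class:`SwarmDivergence` never — a run that loses finiteness is
    returned truncated with ``diverged_at`` set, so sweeps can classify it.
    """
    return _Integrator(config).run()
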