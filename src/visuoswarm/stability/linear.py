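"""Closed-form equilibrium and eigenvalue analysis of the long-range model.

At long range the repulsion term vanishes and the per-agent dynamics reduce
to motion in the quadratic-quartic attraction potential
A(u) = -(rho/2)(u - r)^2 + (1/4)(u - r)^4 of the displacement magnitude u.
The gradient -rho (u - r) + (u - r)^3 vanishes at u = r always, and
additionally at u = r +/- sqrt(rho) when rho > 0 — a supercritical
pitchfork in the coupling strength rho.  (The radicand is sqrt(rho): the
quartic potential's stationarity condition is (u - r)^2 = rho.)

Linearizing [u, v] about an equilibrium gives the 2x2 Jacobian
[[0, 1], [J21, -beta]] with J21 = -A''(u*): J21 = rho on the central branch
and J21 = -2 rho on the outer branches, so the eigenvalue pairs are
lambda = -beta/2 +/- (1/2) sqrt(beta^2 + 4 J21).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EquilibriumBranch",
    "EquilibriumReport",
    "equilibria",
    "eigenvalues",
    "jacobian",
    "classify",
]

BRANCH_CENTER = "center"  # X* = r
BRANCH_OUTER = "outer"  # X* = r +/- sqrt(rho), only for rho > 0


@dataclass
class EquilibriumBranch:
    """One equilibrium of the long-range dynamics with its local analysis."""

    position: float  # X*
    branch: str  # "center" | "outer"
    j21: float  # Jacobian element -A''(X*)
    curvature: float  # A''(X*) = -j21
    eigenvalues: tuple[complex, complex]
    label: str  # "stable min" | "unstable max" | "degenerate"


@dataclass
class EquilibriumReport:
    rho: float
    r: float
    beta: float
    branches: list[EquilibriumBranch]

    @property
    def positions(self) -> list[float]:
        return [b.position for b in self.branches]


def jacobian(rho: float, beta: float, branch: str = BRANCH_CENTER) -> np.ndarray:
    """2x2 Jacobian [[0, 1], [J21, -beta]] for the requested branch."""
    j21 = rho if branch == BRANCH_CENTER else -2.0 * rho
    return np.array([[0.0, 1.0], [j21, -beta]])


def eigenvalues(
    rho: float, beta: float, branch: str = BRANCH_CENTER
) -> tuple[complex, complex]:
    """Closed-form eigenvalue pair -beta/2 +/- (1/2) sqrt(beta^2 + 4 J21)."""
    if beta < 0:
        raise ValueError("friction beta must be non-negative")
    j21 = rho if branch == BRANCH_CENTER else -2.0 * rho
    disc = np.lib.scimath.sqrt(beta**2 + 4.0 * j21)
    lam1 = -beta / 2.0 + 0.5 * disc
    lam2 = -beta / 2.0 - 0.5 * disc
    return (complex(lam1), complex(lam2))


def equilibria(rho: float, r: float, beta: float = 10.0) -> EquilibriumReport:
    """All equilibria of the attraction-only dynamics with local stability.

    rho < 0: the single equilibrium u = r (stable minimum).
    rho > 0: u = r becomes an unstable maximum and two stable minima appear
    at u = r +/- sqrt(rho).
    rho = 0: degenerate triple root at u = r (pitchfork point).
    """
    if r < 0:
        raise ValueError("target radius r must be non-negative")
    branches: list[EquilibriumBranch] = []

    def add(pos: float, branch: str) -> None:
        j21 = rho if branch == BRANCH_CENTER else -2.0 * rho
        lam = eigenvalues(rho, beta, branch)
        curv = -j21
        if curv > 0:
            label = "stable min"
        elif curv < 0:
            label = "unstable max"
        else:
            label = "degenerate"
        branches.append(
            EquilibriumBranch(
                position=pos, branch=branch, j21=j21, curvature=curv,
                eigenvalues=lam, label=label,
            )
        )

    add(r, BRANCH_CENTER)
    if rho > 0:
        add(r + np.sqrt(rho), BRANCH_OUTER)
        add(r - np.sqrt(rho), BRANCH_OUTER)
    return EquilibriumReport(rho=rho, r=r, beta=beta, branches=branches)


def classify(rho: float, r: float = 0.0, beta: float = 10.0) -> list[dict]:
    """Pitchfork summary: (equilibrium, curvature sign, stability label) rows.

    Mirrors the closed-form table: a single stable minimum for rho < 0; for
    rho > 0 an unstable maximum at r flanked by two stable minima at
    r +/- sqrt(rho).
    """
    rep = equilibria(rho, r, beta)
    return [
        {
            "equilibrium": b.position,
            "curvature_sign": int(np.sign(b.curvature)),
            "stability": b.label,
            "eigenvalues": b.eigenvalues,
        }
        for b in rep.branches
    ]
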