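"""Radial shell counting for converged swarm patterns.

The pitchfork in the coupling strength rho shows up geometrically: for
rho < 0 agents settle on a single shell at radius r from the barycenter;
for rho > 0 the shell splits into two at r +/- sqrt(rho).  The shell count
of a converged configuration is estimated by k-means clustering of the
final agent radii for k in {2, 3}, keeping the best silhouette score; a
best score below the strong-structure threshold (0.7 in Rousseeuw's
guidelines) means the radii form a single unimodal shell.
"""

from __future__ import annotations

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

__all__ = ["count_radial_shells", "shell_radii"]


def count_radial_shells(
    radii: np.ndarray,
    k_candidates: tuple[int, ...] = (2, 3),
    strong_structure: float = 0.7,
    seed: int = 0,
) -> tuple[int, np.ndarray]:
    """Estimate the number of radial shells in a set of agent radii.

    Returns (k, shell centers sorted ascending).  k = 1 when no multi-shell
    split reaches the silhouette threshold.
    """
    radii = np.asarray(radii, dtype=float).reshape(-1, 1)
    if len(radii) < 3:
        return 1, np.array([float(radii.mean())])
    best_k, best_score, best_centers = 1, -np.inf, np.array([float(radii.mean())])
    for k in k_candidates:
        if len(radii) <= k:
            continue
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(radii)
        if len(np.unique(km.labels_)) < k:
            continue
        score = silhouette_score(radii, km.labels_)
        if score > best_score:
            best_k, best_score = k, score
            best_centers = np.sort(km.cluster_centers_.ravel())
    if best_score < strong_structure:
        return 1, np.array([float(radii.mean())])
    return best_k, best_centers


def shell_radii(positions: np.ndarray) -> np.ndarray:
    """Agent distances from the configuration barycenter."""
    pos = np.asarray(positions, dtype=float)
    return np.linalg.norm(pos - pos.mean(axis=0), axis=1)
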