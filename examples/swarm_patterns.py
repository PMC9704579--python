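"""Cluster, ring and double-ring patterns of the attraction-repulsion swarm.

The coupling strength rho acts as a pitchfork bifurcation parameter: for
rho < 0 agents settle on a single shell at radius r from the barycenter
(a cluster when r = 0); for rho > 0 the shell splits into two at
r +/- sqrt(rho).  Each run prints the observed shell structure next to the
closed-form prediction.
"""

import numpy as np

from visuoswarm.stability import count_radial_shells, equilibria
from visuoswarm.swarm import PATTERN_PARAMS, SwarmConfig, run_swarm

HORIZONS = {"cluster": 10.0, "ring": 10.0, "double_ring": 25.0}

for name, params in PATTERN_PARAMS.items():
    cfg = SwarmConfig(**params, dt=0.002, horizon=HORIZONS[name], seed=3)
    res = run_swarm(cfg)
    k, centers = count_radial_shells(res.radii())
    predicted = equilibria(cfg.rho, cfg.r).positions
    print(f"{name:12s} rho={cfg.rho:+.1f} r={cfg.r}: "
          f"{k} shell(s) at {np.round(centers, 2)}  "
          f"(equilibria: {np.round(predicted, 2)}), "
          f"V_m(T)={res.v_m[-1]:.3g}")

# Expected: the cluster and ring produce one shell (near 0.9 and 3.05 — the
# short-range repulsion inflates the pure-attraction radius slightly), the
# double ring two shells near 3 -/+ 1.22. V_m is the largest pairwise speed
# difference at the end of the run: small values mean the pattern has frozen.
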