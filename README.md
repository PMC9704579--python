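# visuoswarm

Tools for measuring individual visuomotor transport delays from
stimulus-tracking flight trajectories, and for propagating the measured
delay distribution into a visually interconnected swarm model.

Flying insects tracking a moving target act, to first order, like a linear
closed-loop system with a processing lag: the animal position `y(t)`
follows the stimulus `u(t)` through a rational transfer function and a
transport delay,

    Y(s) = G(s) e^{−sτ} U(s).

`visuoswarm` covers the whole chain needed to estimate τ per individual and
ask what a population of such individuals does collectively:

* **`visuoswarm.synthetic`** — ground-truth generators: multisine stimuli,
  simulated closed-loop tracker responses (with intermittent tracking,
  noise, and known G and τ), positive-truncated Gaussian delay
  populations, and rendered multi-camera blob scenes with known 3×4
  projection matrices.
* **`visuoswarm.tracking`** — the vision pipeline: running-average
  background subtraction, auto-thresholded segmentation, blob centroids,
  constant-velocity Kalman filtering across occlusions, and SVD (DLT)
  triangulation with reprojection gating.
* **`visuoswarm.sysid`** — identification: tracking-section extraction,
  FFT/chirp-z spectra, Welch coherence with a γ² > 0.7 trust band, and a
  grid search over 2–4 pole / 1–4 zero transfer functions with pure
  (e^{−sτ}) or first-order (1/(1+τs)) delay structures on a 1 ms delay
  grid, scored by FIT / MSE / final prediction error.
* **`visuoswarm.swarm`** — a second-order attraction–repulsion swarm,

      m dv_i/dt = −∇A^a(x_i; ρ, r) − ∇A^r(x_i; B_r, C_r) − β v_i,

  where each agent sees its neighbours with its own transport delay and,
  optionally, through its identified transfer function.
* **`visuoswarm.stability`** — closed-form equilibrium/eigenvalue analysis
  (the coupling ρ is a supercritical pitchfork parameter: one shell at
  radius r for ρ < 0, two shells at r ± √ρ for ρ > 0), and a
  simulation-driven (μ, σ) stability map for Gaussian-distributed delays
  with a cubic boundary fit.

A thin CLI (`visuoswarm synth|track|sysid|swarm|stability-map|
analyze-equilibria|pipeline`) wraps the same library calls for batch use;
`examples/` contains one narrative script per capability.

## Worked example

`examples/identify_tracking_delay.py` synthesizes a noiseless tracking
trajectory from a known second-order model with a 21 ms transport delay —
G(s) = (9.204 − 0.285 s)/(8.098 + 2.098 s + s²) driven by eight sinusoids
spanning 0.1–1.7 Hz for 60 s at 0.02 s — and runs the full identification
pipeline on it:

```
tracking sections        : 1
coherent band            : 0.07-2.27 Hz
best structure           : 2 poles, 1 zero(s), pure delay
transport delay          : 21.0 ms
numerator  (ascending s) : [ 9.204 -0.285]
denominator (ascending s): [8.098 2.098 1.   ]
fit                      : 100.00%
```

The grid search separates the rational dynamics from the delay factor and
returns the generating model exactly: right structure, delay on the 1 ms
grid, coefficients to better than 1%.

`examples/swarm_patterns.py` shows the pitchfork geometrically:

```
ring         rho=-4.0 r=3.0: 1 shell(s) at [3.05]  (equilibria: [3.]), V_m(T)=0.0799
double_ring  rho=+1.5 r=3.0: 2 shell(s) at [1.98 4.18]  (equilibria: [3.   4.22 1.78]), V_m(T)=0.0528
cluster      rho=-4.0 r=0.0: 1 shell(s) at [0.93]  (equilibria: [0.]), V_m(T)=0.0151
```

Agents settle within a few percent of the predicted shells; the short-range
repulsion accounts for the small outward bias.  Finally,
`examples/delay_stability_map.py` draws per-agent delays from the measured
population summary (Gaussian with mean 22 and SD 40, truncated positive)
and classifies the swarm barycenter: the delay-free cluster settles, while
the measured distribution typically leaves the barycenter drifting or
oscillating — delays alone, at their measured heterogeneity, fail to
stabilize the swarm's centre of mass.

## Layout

```
src/visuoswarm/     library (synthetic, tracking, sysid, swarm, stability)
examples/           one narrative script per capability
scripts/            acceptance script
tests/              pytest suite (unit, property and end-to-end tests)
docs/methods.md     models, assumptions, defaults, limitations
```
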