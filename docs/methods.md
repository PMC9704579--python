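# Methods

This note documents the models and procedures implemented in `visuoswarm`,
the assumptions behind them, the defaults and why they were chosen, and what
the synthetic-data generators do and do not emulate.

## 1. The measurement problem

A flying insect tracking a moving visual target closes a loop: target
motion → visual processing → motor response → body motion.  Treating the
stimulus position `u(t)` and the animal position `y(t)` along the driven
axis as input and output of a linear time-invariant system, the closed-loop
behaviour is summarized by a rational transfer function with a transport
delay,

    Y(s) = G(s) · M(s, τ) · U(s),
    M(s, τ) = e^{−sτ}  (pure delay)  or  1/(1 + τs)  (first-order approx.),

and the headline quantity is τ, the visuomotor processing delay.  A
representative identified model used throughout the docs and tests is

    G(s) e^{−0.021 s},  G(s) = (9.204 − 0.285 s) / (8.098 + 2.098 s + s²),

i.e. second-order closed-loop dynamics with a 21 ms transport delay.

## 2. Stimulus design and synthetic tracking data

The stimulus is a sum of sinusoids (multisine), by default eight components
evenly spanning 0.1–1.7 Hz with unit amplitudes, sampled at the recording
frame interval δt = 0.02 s for 60 s.  Multisine excitation concentrates the
input power at known lines, which is what makes the frequency response
estimable.  Choices not fixed by the experimental description, made once:

* **Phases** are drawn from a seeded uniform [0, 2π): deterministic phases
  would align the component peaks and produce large crest factors.
* **Frequencies snap to the record grid** (integer cycles over the
  duration): a periodic multisine has zero spectral leakage at its own
  lines, the standard design in frequency-domain identification.
* **Amplitudes** are unit; only ratios matter for a linear system.

The tracker simulator produces the animal signal two ways:

* a generic time-domain path — G(s) discretized by the bilinear transform,
  transport delay applied as a fractional-sample shift with a
  Blackman-windowed sinc interpolator (sub-sample delays such as 21 ms ≈
  1.05 samples remain representable) — which carries the usual filter
  start-up transient; and
* an exact steady-state path for multisine inputs, where each component is
  scaled and phase-shifted analytically.  This emulates an animal joining
  an already-running periodic stimulus and is the default for synthesis.

Intermittent tracking is emulated with tracking windows; between windows
the animal follows a seeded mean-reverting Ornstein–Uhlenbeck wander offset
away from the stimulus so that section extraction rejects those spans.
Measurement noise is white Gaussian on the tracked samples.

Per-individual delays are drawn from a Gaussian truncated to positive
values, N(τ > 0 | μ, σ), with the measured population summary μ = 22,
σ = 40 (ms) as the default.  Sampling uses the inverse-CDF method
(`scipy.stats.truncnorm`), which is exact under arbitrarily heavy
truncation; truncation (not clipping) avoids a spurious mass at zero.

**What the generators do not emulate:** body pose and wing kinematics,
saccadic or discrete tracking strategies, nonlinear or time-varying
tracking gains, sensor dropout correlated with flight manoeuvres, and
photorealistic appearance.  Passing tests therefore demonstrate the
correctness of the analysis chain on data that satisfy its assumptions,
not that real insects satisfy them.

## 3. Vision pipeline

* **Background**: per-pixel exponential moving average
  E_t = (1 − η_μ) E_{t−1} + η_μ F_t with η_μ = 0.1; the initial background
  is the mean of the first 10 frames (configurable).  The EMA is a convex
  combination, hence bounded by its inputs.
* **Segmentation**: binary mask |F − E| ≥ η_α with η_α = 10 grey levels by
  default, or automatically η_α = η_λ · mean|F − E| clamped to [10, 30].
  Gaussian blur (σ = kernel/6, kernel 5 px) and a 3×3 morphological closure
  clean the mask.  Known artifact of the moving-average method: a target
  that lingers gets absorbed into E and leaves a decaying "ghost" after
  moving on; the synthetic fixtures use a blob-free lead-in (background
  learned before the target enters, as in real recordings) and a target
  contrast/speed for which the one-frame residue η_μ·I falls below the
  threshold.
* **Centroids**: connected components (8-connectivity) within configurable
  area bounds, intensity-unweighted pixel centroids, sorted by area.
  Pixel convention: (u, v) = (column, row), origin top-left, 0-based.
* **Kalman gap filling**: constant-velocity model per camera with process
  noise built from the acceleration SD ε_a (position SD ε_a δt²/2, velocity
  SD ε_a δt) and measurement noise diag(ε_x², ε_y²); defaults
  ε_a = ε_x = ε_y = 0.5.  Association gates the nearest detection within a
  15 px radius of the prediction, ties broken by larger area; with no
  detection the prediction itself is used for up to 10 frames.
* **Triangulation**: per frame, each camera contributes the rows
  [v·P₃ − P₂; u·P₃ − P₁] to a homogeneous system solved by SVD (≥2 cameras);
  the point is accepted iff the maximum reprojection error is ≤ η_ψ =
  0.5 px.  Rank-deficient geometries (near-identical cameras) are reported,
  not solved.  No RANSAC: with 2–3 cameras the reprojection gate is the
  outlier control.

## 4. Identification

1. **Tracking sections**: maximal runs with |u − y| < tolerance on the
   driven axis, at least 30 samples long.
2. **Coherence**: Welch magnitude-squared coherence (Hann, 50% overlap,
   window = ¼ record) on the concatenated sections; the identification
   trusts only frequencies with γ² > 0.7.
3. **Response samples**: with line excitation, the ratio D₂/D₁ is
   meaningful only at the excited lines; between lines both spectra are
   leakage tails and their ratio blends neighbouring line responses.  The
   fitted response is therefore the ratio of *masked line spectra*: each
   signal is transformed on its original timeline with a taper that is zero
   outside tracking sections (rectangular when one section spans the whole
   record — exact for a periodic multisine — otherwise a Hann taper per
   section, whose sidelobes suppress cross-line leakage through the mask).
   Concatenating the sections and transforming the joined record, the
   obvious alternative, re-times the samples and smears the lines; it is
   retained for the coherence estimate and the time-domain criteria, where
   it is harmless.  The chirp z-transform supplies dense band-limited
   spectra (default band 0.01–0.2 Hz, 256 points) for line localization
   and reporting.
4. **Grid search**: structures 2–4 poles × 1–4 zeros (zeros ≤ poles), both
   delay forms, delay grid 1 ms over [0, 200] ms.  For each candidate the
   delay factor is divided out and the rational coefficients are fitted by
   complex equation-error least squares (monic denominator) with one
   Sanathanan–Koerner reweighting pass.  Candidates whose poles land more
   than 10× beyond the analysis band are discarded: such fits emulate a
   lower-order model with near-cancelling far singularities and are
   unidentifiable from the data.  A later grid delay must improve the
   summed absolute response mismatch by more than numerical noise to
   displace an earlier one (determinism among numerically equal optima).
5. **Scoring and selection**: normalized fit percentage on the frequency
   response; time-domain MSE/FIT from simulating the candidate on the
   stimulus record; Akaike final prediction error through an ARX surrogate
   at orders (n_a, n_b) = (poles, zeros + 1) sampled at δt.  Selection is
   by maximum fit; candidates within 0.5 percentage points are treated as
   tied, and ties resolve to numerically perfect fits first, then fewer
   parameters, then smaller delay.  A flag records whether max-FIT,
   min-MSE and min-FPE would disagree.  Parameter standard errors come
   from the weighted least-squares normal equations.

**Delay identifiability.** Transport delay and rational phase are strongly
correlated over a narrow band: at 20 dB SNR *per frequency point* the delay
is only determined to ~±10 ms even with the true structure fixed.  In the
pipeline the SNR that matters is per line after the transform, which gains
~10·log₁₀(N/2) dB over the time-domain SNR; with 60–240 s records the ±1–2
ms regime is reached.  The parameter-recovery tests use 20 dB time-domain
noise with 20 excitation lines over 240 s for this reason.

## 5. Swarm model

N agents with positions x_i and velocities v_i in 2-D or 3-D:

    dx_i/dt = v_i
    m dv_i/dt = −∇_i A^a − ∇_i A^r − β v_i

with the attraction gradient I·unit(X_i), where
X_i = Σ_{j≠i} (x_i(t) − x_j(t − τ_ij)), u_i = ‖X_i/N‖ and
I = −ρ(u_i − r) + (u_i − r)³, and the repulsion
Σ_{j≠i} (B_r/C_r) e^{−d_ij/C_r} along the unit vector from the delayed
neighbour to the agent.  Delay-free, X_i = N(x_i − x̄): each agent is
attracted to the shell of radius r around the barycenter, and ρ is a
pitchfork bifurcation parameter (§6).

Default pattern parameters (N, ρ, r, B_r, C_r, β): ring (30, −4, 3, 1, 0.5,
10), double ring (50, 1.5, 3, 1, 0.5, 10), cluster (50, −4, 0, 1, 0.5, 10).
Mass is not specified anywhere; m = 1.

Design choices where the model description is open:

* **Delay semantics**: τ_ij = τ_i — the perceiving agent's processing delay
  applies to every neighbour it observes; a full per-link matrix is also
  accepted.
* **Delay units**: the model is dimensionless; delay *values* from the
  population analysis enter the simulation numerically as model time units.
  This is the only reading under which distributed delays in the 0–100
  range interact with the swarm's dynamical timescales at all (the slowest
  linearized mode decays at ≈0.9/time-unit, so delays three orders of
  magnitude smaller would be invisible) and under which the
  delay-distribution stability structure exists.
* **Integrator**: fixed-step classical RK4, default dt = 1 ms, with linear
  interpolation into the stored position history for delayed arguments;
  constant pre-history x_j(t) = x_j(0) for t < 0.  Delays shorter than a
  stage offset use the first-order extrapolation x − τv, which restores the
  delay-free ODE continuously as τ → 0.
* **Initial conditions**: positions uniform in a disc (ball) of radius 5,
  velocities zero, seeded.
* **Coincident agents**: the repulsion direction for a zero-distance pair
  is randomized (seeded) at magnitude B_r/C_r; the attraction is zero when
  X_i = 0 (direction undefined).
* **Per-agent response filtering**: an agent's broadcast position can pass
  through its identified rational dynamics G_ei(s), discretized at dt by
  the bilinear transform and run as an online IIR filter primed at DC.
  Since the filter and the transport delay are both LTI they commute, so
  "filter then delay" and "delay then filter" define the same perceived
  signal; only the former is implemented.

**Energy dissipation.** With delays and repulsion off, the dynamics
dissipate E = Σ ½m|v_i|² − ½Nm|v̄|² + Σ A^a(u_i): dE/dt =
−β Σ|v_i − v̄|² ≤ 0.  The barycenter kinetic term is necessary because the
forces depend only on barycentric displacements and exert a net impulse on
the mean; the tests assert monotone decay of this functional.

## 6. Stability analysis

**Closed form (long range).** For r ≫ C_r the repulsion is negligible and
the scalar displacement dynamics linearize to the Jacobian
[[0, 1], [J21, −β]] with J21 = −A''(u*):

| ρ     | equilibrium u*      | A''   | character      |
|-------|---------------------|-------|----------------|
| ρ < 0 | r                   | −ρ > 0| stable min     |
| ρ > 0 | r                   | −ρ < 0| unstable max   |
| ρ > 0 | r ± √ρ              | 2ρ > 0| stable min     |

Eigenvalues: λ = −β/2 ± ½√(β² + 4J21).  A supercritical pitchfork at
ρ = 0: the single shell splits into two at r ± √ρ.  (The radicand is √ρ —
stationarity of the quartic potential gives (u − r)² = ρ.)  Shell counting
in converged configurations uses k-means over agent radii for k ∈ {2, 3}
with silhouette selection; a best silhouette below 0.7 (the conventional
"strong structure" threshold) means a single shell.

**Delay effects (simulation only).** No closed-form criterion is attempted
for the delayed system; stability under delay distributions is assessed by
simulation, classified on the barycenter norm ‖R_C‖(t): a run is *stable*
when the norm settles — over the final half of the horizon, the fitted
linear trend |slope| and the residual SD around it must both stay below 1%
of the pattern length scale max(r, C_r), the maximum excursion must stay
below 2× the initial cloud radius, and the state must remain finite.  The
fluctuation term matters because delay-induced instability appears as a
sustained bounded oscillation of the barycenter rather than a clean drift.
Thresholds are recorded in every stability map.

The (μ, σ) sweep samples per-agent delays from N(τ > 0 | μ, σ) per cell
(σ = 0 cells use the common delay μ), labels cells by majority over
replicates with deterministically derived per-cell seeds, and fits a cubic
polynomial σ(μ) through stable cells 4-adjacent to unstable ones.
Phenomenology of this model: the no-delay origin is stable; delays
comparable to the dynamical timescales (roughly 1–8 time units, directly
or through the spread σ) destabilize the barycenter; delays far beyond the
horizon freeze the perceived positions and re-stabilize.  The measured
population summary (μ = 22, σ = 40) mixes all three regimes and is
classified unstable in the majority of seeded runs, while the delay-free
cluster is robustly stable.

## 7. Numerical choices and problem sizes

* Delay grid 1 ms; CZT band [0.01, 0.2] Hz with 256 points; Welch window ¼
  of the record with 50% overlap; line-spectrum mask threshold 1e−8 of the
  peak input magnitude.
* Swarm dt = 1 ms for production runs; scaled-down studies in the test
  suite use N = 8–20, dt = 2–5 ms and horizons of 10 s (the stability-map
  reproducibility check runs an 11×11 grid at N = 8, one replicate), chosen
  as the smallest sizes at which the qualitative findings are stable.
* Double-ring convergence needs ~25 s: agents starting near the unstable
  central shell leave it at a rate of only ≈0.15/s.
* All randomness flows through `numpy.random.default_rng` with explicit
  seeds; sweeps derive per-cell seeds from the base seed, so maps are
  bit-reproducible.

## 8. Known limitations

* The equation-error fit (even with SK reweighting) is not a maximum-
  likelihood estimator; at low SNR it biases towards minimizing the
  weighted equation error, and with both delay structures in the grid a
  flexible structure can out-fit the true one on noisy data (the criteria-
  disagreement flag marks such cases).
* Segmentation follows the absolute frame-background difference, so a
  slow bright target drags a ghost; practical deployments either learn the
  background before the animal enters or keep η_μ·(target contrast) below
  the threshold, and the fixtures do the same.
* The barycenter classifier is horizon-dependent by construction: runs
  whose transient has not finished inside the settle window can be flagged
  unstable; scaled-down sweeps therefore use horizons ≥ 10 time units.
* Consensus in large clusters is asymptotic: soft rearrangement modes keep
  the maximum pairwise speed difference at ~1e−2 for a long time even
  though the pattern is visually frozen.
* The delay-distribution stability map is a Monte-Carlo object: cell labels
  near the boundary flip between replicates, and the cubic boundary fit is
  only as meaningful as the grid is fine.
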