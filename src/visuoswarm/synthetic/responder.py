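"""Closed-loop tracker simulation from known ground-truth dynamics.

A :class:`GroundTruthResponder` is a rational transfer function G(s) plus a
transport delay tau: the animal's position is the G-filtered stimulus,
delayed by tau, observed through additive measurement noise — but only
inside "tracking windows".  Outside those windows the simulated animal
performs a smooth non-tracking excursion (a mean-reverting random wander
with amplitude larger than any sensible tracking tolerance) so that the
section-extraction stage downstream rejects those spans by construction.

Two synthesis paths are provided:

* :func:`simulate_tracker_response` — generic time-domain path: bilinear
  discretization of G(s) plus a windowed-sinc fractional-sample delay.
  Carries the usual filter startup transient.
* :meth:`GroundTruthResponder.steady_state_response` — exact frequency-domain
  path for multisine stimuli: each sinusoid is scaled and phase-shifted by
  G(j*omega)e^{-j*omega*tau} analytically.  This emulates an animal joining
  an already-running periodic stimulus (no startup transient), which is how
  the tracking recordings are actually framed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .._dsp import ctf_eval, filter_continuous, fractional_delay
from ..trajectory import Trajectory
from .stimulus import StimulusSpec

__all__ = ["GroundTruthResponder", "simulate_tracker_response", "HONEYBEE_EXAMPLE"]


@dataclass
class GroundTruthResponder:
    """Known tracking dynamics: G(s) = num(s)/den(s) with transport delay tau.

    Coefficients are in ascending powers of s.  ``windows`` is a list of
    (start, stop) tracking intervals in seconds; ``None`` means the animal
    tracks for the whole record.
    """

    num: np.ndarray
    den: np.ndarray
    tau: float = 0.0
    noise_sd: float = 0.0
    windows: list[tuple[float, float]] | None = None
    seed: int = 0
    wander_sd: float = 2.0
    wander_corr_time: float = 2.0

    def __post_init__(self) -> None:
        self.num = np.atleast_1d(np.asarray(self.num, dtype=float))
        self.den = np.atleast_1d(np.asarray(self.den, dtype=float))
        if len(self.num) > len(self.den):
            raise ValueError("denominator degree must be >= numerator degree")
        if self.tau < 0:
            raise ValueError("transport delay must be non-negative")
        if self.windows is not None:
            w = sorted(self.windows)
            for (a0, b0), (a1, b1) in zip(w, w[1:]):
                if b0 > a1:
                    raise ValueError("tracking windows must not overlap")
            for a, b in w:
                if b <= a:
                    raise ValueError(f"empty tracking window ({a}, {b})")

    def freq_response(self, freq_hz: np.ndarray) -> np.ndarray:
        """G(j*omega)*e^{-j*omega*tau} at the given frequencies in Hz."""
        omega = 2.0 * np.pi * np.asarray(freq_hz, dtype=float)
        return ctf_eval(self.num, self.den, omega) * np.exp(-1j * omega * self.tau)

    def steady_state_response(self, spec: StimulusSpec) -> Trajectory:
        """Exact steady-state response to a multisine stimulus (noiseless core).

        Measurement noise and non-tracking windows are still applied; only
        the linear filtering + delay is computed analytically.
        """
        t = spec.dt * np.arange(spec.n_samples)
        y = np.zeros_like(t)
        for f, a, p in zip(spec.frequencies, spec.amplitudes, spec.phases):
            g = self.freq_response(np.array([f]))[0]
            y += a * np.abs(g) * np.sin(2.0 * np.pi * f * t + p + np.angle(g))
        return self._observe(Trajectory(y, spec.dt))

    # -- internals -----------------------------------------------------------
    def _window_mask(self, n: int, dt: float) -> np.ndarray:
        if self.windows is None:
            return np.ones(n, dtype=bool)
        t = dt * np.arange(n)
        mask = np.zeros(n, dtype=bool)
        for a, b in self.windows:
            if b - a < 30 * dt:
                raise ValueError(
                    f"tracking window ({a}, {b}) shorter than 30 samples at dt={dt}"
                )
            mask |= (t >= a) & (t < b)
        return mask

    def _wander(self, n: int, dt: float, rng: np.random.Generator) -> np.ndarray:
        """Mean-reverting smooth random wander (discretized OU process)."""
        from scipy.signal import lfilter

        theta = 1.0 / self.wander_corr_time
        sigma = self.wander_sd * np.sqrt(2.0 * theta)
        drive = sigma * np.sqrt(dt) * rng.normal(size=n)
        drive[0] = rng.normal(0.0, self.wander_sd)
        # AR(1) recursion x[k] = (1 - theta*dt) x[k-1] + drive[k]
        return lfilter([1.0], [1.0, -(1.0 - theta * dt)], drive)

    def _observe(self, tracked: Trajectory) -> Trajectory:
        n, dt = tracked.n_samples, tracked.dt
        rng = np.random.default_rng(self.seed)
        mask = self._window_mask(n, dt)
        y = tracked.values.copy()
        if self.noise_sd > 0:
            y = y + rng.normal(0.0, self.noise_sd, n) * mask
        if not mask.all():
            # offset the wander so it sits clearly away from the tracked path
            excursion = self._wander(n, dt, rng)
            excursion += np.where(excursion >= 0, self.wander_sd, -self.wander_sd)
            y[~mask] = (tracked.values + excursion)[~mask]
        return Trajectory(y, dt)


def simulate_tracker_response(
    stimulus: Trajectory, responder: GroundTruthResponder
) -> tuple[Trajectory, Trajectory]:
    """Simulate the animal's response to an arbitrary sampled stimulus.

    Returns the (stimulus, animal) trajectory pair.  The animal signal is
    the bilinear-discretized G(s) applied to the stimulus, delayed by tau via
    fractional-sample sinc interpolation, with noise / non-tracking wander
    per the responder spec.  Reproducible under a fixed responder seed.
    """
    if responder.tau >= stimulus.duration:
        raise ValueError(
            f"transport delay {responder.tau} s must be shorter than the "
            f"stimulus duration {stimulus.duration} s"
        )
    x = stimulus.component(0)
    unity = len(responder.num) == 1 and len(responder.den) == 1 and (
        responder.num[0] == responder.den[0]
    )
    y = x.copy() if unity else filter_continuous(responder.num, responder.den, stimulus.dt, x)
    if responder.tau > 0:
        y = fractional_delay(y, responder.tau / stimulus.dt)
    animal = responder._observe(Trajectory(y, stimulus.dt))
    return stimulus, animal


#: Representative closed-loop honeybee pursuit model used throughout the
#: docs and tests: second-order dynamics with one zero and a 21 ms transport
#: delay, G(s) = e^{-0.021 s} (-0.285 s + 9.204) / (s^2 + 2.098 s + 8.098).
HONEYBEE_EXAMPLE = GroundTruthResponder(
    num=np.array([9.204, -0.285]),
    den=np.array([8.098, 2.098, 1.0]),
    tau=0.021,
)
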