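"""Sum-of-sinusoids (multisine) stimulus generation.

The tracking experiments drive a visual target along one world axis with a
sum of sinusoids — here eight components spanning 0.1–1.7 Hz by default,
sampled at the 0.02 s frame interval of the recording system.  A multisine
excites the tracked system at a known, sparse set of frequencies, which is
what makes the later frequency-domain identification well posed: the
empirical frequency response is trusted only at the excited lines.

``multisine_spec`` optionally snaps the component frequencies onto the
Fourier grid of the record (integer numbers of cycles over the duration), a
standard periodic-multisine design that removes spectral leakage at the
excited bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..trajectory import Trajectory

__all__ = ["StimulusSpec", "generate_stimulus", "multisine_spec"]


@dataclass
class StimulusSpec:
    """Specification of a sum-of-sinusoids stimulus.

    frequencies, amplitudes, phases must have equal length; frequencies are
    in Hz, amplitudes in length units, phases in radians.  ``duration/dt``
    must be an integer number of samples.
    """

    frequencies: np.ndarray
    amplitudes: np.ndarray
    phases: np.ndarray
    duration: float
    dt: float = 0.02

    def __post_init__(self) -> None:
        self.frequencies = np.atleast_1d(np.asarray(self.frequencies, dtype=float))
        self.amplitudes = np.atleast_1d(np.asarray(self.amplitudes, dtype=float))
        self.phases = np.atleast_1d(np.asarray(self.phases, dtype=float))
        if not (len(self.frequencies) == len(self.amplitudes) == len(self.phases)):
            raise ValueError("frequencies, amplitudes and phases must have equal length")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        nyq = 0.5 / self.dt
        for f in self.frequencies:
            if f <= 0:
                raise ValueError(f"stimulus frequency {f} Hz must be positive")
            if f >= nyq:
                raise ValueError(
                    f"stimulus frequency {f} Hz is at or above the Nyquist "
                    f"frequency {nyq} Hz for dt={self.dt}"
                )
        n = self.duration / self.dt
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"duration {self.duration} s is not an integer number of "
                f"samples at dt={self.dt}"
            )

    @property
    def n_samples(self) -> int:
        return int(round(self.duration / self.dt))


def generate_stimulus(spec: StimulusSpec) -> Trajectory:
    """Generate the 1-D stimulus x(t) = sum_k a_k sin(2*pi*f_k*t + phi_k).

    Deterministic; an empty frequency list yields a constant-zero signal.
    """
    t = spec.dt * np.arange(spec.n_samples)
    x = np.zeros_like(t)
    for f, a, p in zip(spec.frequencies, spec.amplitudes, spec.phases):
        x += a * np.sin(2.0 * np.pi * f * t + p)
    return Trajectory(x, spec.dt)


def multisine_spec(
    f_min: float = 0.1,
    f_max: float = 1.7,
    n_components: int = 8,
    duration: float = 60.0,
    dt: float = 0.02,
    amplitude: float = 1.0,
    seed: int | None = 0,
    snap_to_record_grid: bool = True,
) -> StimulusSpec:
    """Build a multisine spec with components evenly spanning [f_min, f_max].

    With ``snap_to_record_grid`` each component frequency is rounded to the
    nearest multiple of ``1/duration`` so every sinusoid completes an integer
    number of cycles over the record (periodic multisine).  Phases are drawn
    once from a seeded uniform [0, 2*pi) to avoid pathological peak
    alignment; ``seed=None`` gives zero phases.
    """
    freqs = np.linspace(f_min, f_max, n_components)
    if snap_to_record_grid:
        df = 1.0 / duration
        freqs = np.round(freqs / df) * df
        if len(np.unique(freqs)) != len(freqs):
            raise ValueError(
                "record too short to separate the requested frequencies on its grid"
            )
    if seed is None:
        phases = np.zeros(n_components)
    else:
        phases = np.random.default_rng(seed).uniform(0.0, 2.0 * np.pi, n_components)
    return StimulusSpec(
        frequencies=freqs,
        amplitudes=np.full(n_components, float(amplitude)),
        phases=phases,
        duration=duration,
        dt=dt,
    )
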