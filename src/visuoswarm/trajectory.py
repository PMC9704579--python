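"""Uniformly sampled trajectory container.

A :class:`Trajectory` is the basic currency of the package: a uniformly
sampled time series of positions, either scalar (the stimulus moves along a
single world axis) or 3-D (a reconstructed flight path).  Values are stored
as a ``(n,)`` or ``(n, d)`` float array together with the sample interval
``dt``; time is implicit, ``t_k = t0 + k*dt``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Trajectory"]


@dataclass
class Trajectory:
    """Uniformly sampled position signal.

    Parameters
    ----------
    values : ndarray, shape (n,) or (n, d)
        Position samples, in length units (metres by convention).
    dt : float
        Sample interval in seconds.
    t0 : float, optional
        Time of the first sample, seconds.
    """

    values: np.ndarray
    dt: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim not in (1, 2):
            raise ValueError("trajectory values must be 1-D or 2-D")
        if not np.isfinite(self.dt) or self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")

    # -- basic introspection -------------------------------------------------
    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def ndim(self) -> int:
        """Spatial dimension of the samples (1 for a scalar signal)."""
        return 1 if self.values.ndim == 1 else self.values.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples * self.dt

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n_samples)

    @property
    def nyquist(self) -> float:
        """Nyquist frequency 1/(2*dt) in Hz."""
        return 0.5 / self.dt

    def component(self, axis: int = 0) -> np.ndarray:
        """Return one spatial coordinate as a flat array (X axis by default)."""
        if self.values.ndim == 1:
            if axis != 0:
                raise IndexError("scalar trajectory has only axis 0")
            return self.values
        return self.values[:, axis]

    def with_values(self, values: np.ndarray) -> "Trajectory":
        return Trajectory(np.asarray(values, dtype=float), self.dt, self.t0)
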