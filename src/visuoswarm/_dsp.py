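"""Shared signal-processing primitives.

Continuous transfer functions are stored with coefficients in ascending
powers of s (a_0 + a_1 s + ...), matching how the identification module
reports them; scipy wants descending order, so conversions happen here.
"""

from __future__ import annotations

import numpy as np
from numpy.polynomial import polynomial as P
from scipy import signal

__all__ = [
    "ctf_eval",
    "bilinear_discretize",
    "filter_continuous",
    "fractional_delay",
]


def ctf_eval(num: np.ndarray, den: np.ndarray, omega: np.ndarray) -> np.ndarray:
    """Evaluate G(j*omega) for ascending-power coefficient arrays."""
    s = 1j * np.asarray(omega, dtype=float)
    return P.polyval(s, np.asarray(num, dtype=float)) / P.polyval(
        s, np.asarray(den, dtype=float)
    )


def bilinear_discretize(
    num: np.ndarray, den: np.ndarray, dt: float
) -> tuple[np.ndarray, np.ndarray]:
    """Discretize a continuous transfer function at dt via the bilinear map.

    Returns (b, a) digital filter coefficients for scipy.signal.lfilter.
    """
    num_d = np.asarray(num, dtype=float)[::-1]
    den_d = np.asarray(den, dtype=float)[::-1]
    b, a = signal.bilinear(num_d, den_d, fs=1.0 / dt)
    return b, a


def filter_continuous(
    num: np.ndarray, den: np.ndarray, dt: float, x: np.ndarray
) -> np.ndarray:
    """Apply a continuous-time filter to a sampled signal (bilinear transform).

    The filter starts from rest (zero initial conditions), so the output
    carries the usual startup transient.
    """
    b, a = bilinear_discretize(num, den, dt)
    return signal.lfilter(b, a, np.asarray(x, dtype=float))


def fractional_delay(x: np.ndarray, delay_samples: float, taps: int = 81) -> np.ndarray:
    """Delay a signal by a (possibly fractional) number of samples.

    Integer part by shifting, fractional part by a Blackman-windowed sinc
    interpolator — this keeps sub-sample transport delays representable
    (21 ms is only ~1.05 samples at a 0.02 s frame interval).  Samples
    shifted in from before the record start repeat the first sample.
    """
    x = np.asarray(x, dtype=float)
    if delay_samples < 0:
        raise ValueError("delay must be non-negative")
    d_int = int(np.floor(delay_samples))
    frac = delay_samples - d_int

    if frac > 1e-12:
        half = taps // 2
        k = np.arange(-half, half + 1)
        kernel = np.sinc(k - frac) * np.blackman(len(k))
        kernel /= kernel.sum()
        # edge-pad so the interpolator sees a continued signal at both ends
        xp = np.pad(x, half, mode="edge")
        y = np.convolve(xp, kernel, mode="valid")
    else:
        y = x.copy()

    if d_int > 0:
        y = np.concatenate([np.full(d_int, y[0]), y[:-d_int]])
    return y
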