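"""Frequency-domain transforms: FFT, chirp-z, coherence, tracking error.

The empirical frequency response H(s) = D2(s)/D1(s) is the ratio of the
animal and stimulus spectra.  The FFT gives the standard one-sided spectrum;
the chirp z-transform (CZT) evaluates the z-transform on equally spaced
unit-circle points confined to a narrow band, densifying the frequency
resolution where the tracking is coherent (the DFT's grid is fixed at 1/T).

With multisine excitation the ratio is exact only at the excited lines;
in between, both spectra are leakage-dominated and the ratio blends the
responses at neighbouring lines.  ``empirical_response`` therefore masks
bins where the stimulus has no appreciable power.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = [
    "FrequencyResponse",
    "CoherenceSpectrum",
    "fft_response",
    "czt_response",
    "empirical_response",
    "coherence",
    "coherent_band",
    "tracking_error",
]


@dataclass
class FrequencyResponse:
    """Complex spectrum or frequency-response samples on a frequency grid."""

    freqs: np.ndarray  # Hz, strictly increasing
    values: np.ndarray  # complex
    method: str = "fft"  # "fft" | "czt" | "ratio"
    source: str = ""  # "D1" | "D2" | "H"

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.values = np.asarray(self.values, dtype=complex)
        if len(self.freqs) != len(self.values):
            raise ValueError("frequency grid and values must have equal length")
        if len(self.freqs) > 1 and np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequency grid must be strictly increasing")


@dataclass
class CoherenceSpectrum:
    freqs: np.ndarray
    gamma2: np.ndarray

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.gamma2 = np.asarray(self.gamma2, dtype=float)


def fft_response(x: np.ndarray, dt: float, source: str = "") -> FrequencyResponse:
    """One-sided FFT spectrum of a real signal."""
    x = np.asarray(x, dtype=float)
    spec = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(len(x), d=dt)
    return FrequencyResponse(freqs, spec, method="fft", source=source)


def czt_response(
    x: np.ndarray,
    dt: float,
    f_start: float,
    f_stop: float,
    n_points: int = 256,
    source: str = "",
) -> FrequencyResponse:
    """Chirp z-transform on [f_start, f_stop] with n_points samples.

    Evaluates the z-transform of the record along equally spaced points of
    the unit circle restricted to the band; with f_start=0, f_stop=Nyquist
    and n_points=N/2+1 it reproduces the one-sided DFT exactly.
    """
    x = np.asarray(x, dtype=float)
    nyq = 0.5 / dt
    if not (0.0 <= f_start < f_stop <= nyq + 1e-12):
        raise ValueError(
            f"CZT band [{f_start}, {f_stop}] Hz must lie inside [0, {nyq}] Hz"
        )
    if n_points < 2:
        raise ValueError("need at least two CZT points")
    freqs = np.linspace(f_start, f_stop, n_points)
    step = (f_stop - f_start) / (n_points - 1)
    w = np.exp(-2j * np.pi * step * dt)
    a = np.exp(2j * np.pi * f_start * dt)
    vals = signal.czt(x, m=n_points, w=w, a=a)
    return FrequencyResponse(freqs, vals, method="czt", source=source)


def line_spectrum(
    x: np.ndarray,
    dt: float,
    freqs: np.ndarray,
    weight: np.ndarray | None = None,
    source: str = "",
) -> FrequencyResponse:
    """Exact-frequency spectrum of a (possibly gappy) record at given lines.

    Evaluates sum_m w[m] x[m] e^{-2*pi*i*f*m*dt} directly at each requested
    frequency on the record's original timeline.  ``weight`` is a taper that
    is zero outside tracked spans (e.g. a Hann window per tracking section);
    keeping samples at their true times preserves the excitation lines that
    concatenation would smear.  The weighted mean is removed first.
    """
    x = np.asarray(x, dtype=float)
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    w = np.ones_like(x) if weight is None else np.asarray(weight, dtype=float)
    if len(w) != len(x):
        raise ValueError("weight must match the record length")
    if w.sum() <= 0:
        raise ValueError("weight must have positive mass")
    xc = x - np.sum(w * x) / np.sum(w)
    t = dt * np.arange(len(x))
    vals = np.array([np.sum(w * xc * np.exp(-2j * np.pi * f * t)) for f in freqs])
    return FrequencyResponse(freqs, vals, method="line", source=source)


def empirical_response(
    d1: FrequencyResponse,
    d2: FrequencyResponse,
    mask_rel: float = 1e-8,
) -> FrequencyResponse:
    """Bin-wise ratio H = D2/D1 on a shared grid, guarding empty input bins.

    Bins where |D1| falls below ``mask_rel`` times its maximum are dropped
    (the ratio there is numerically meaningless).
    """
    if len(d1.freqs) != len(d2.freqs) or not np.allclose(d1.freqs, d2.freqs):
        raise ValueError("D1 and D2 must share the same frequency grid")
    mag = np.abs(d1.values)
    keep = mag >= mask_rel * mag.max()
    return FrequencyResponse(
        d1.freqs[keep], d2.values[keep] / d1.values[keep], method=d1.method, source="H"
    )


def coherence(
    stimulus: np.ndarray,
    animal: np.ndarray,
    dt: float,
    window_len: int | None = None,
    overlap: float = 0.5,
) -> CoherenceSpectrum:
    """Magnitude-squared coherence |S_xy|^2 / (S_x S_y), Welch-averaged.

    Defaults: Hann window, 50% overlap, window length a quarter of the
    record.  Requires at least two averaged windows — coherence from a
    single segment is identically one and thus undefined as an estimate.
    """
    stimulus = np.asarray(stimulus, dtype=float)
    animal = np.asarray(animal, dtype=float)
    if len(stimulus) != len(animal):
        raise ValueError("stimulus and animal records must have equal length")
    n = len(stimulus)
    if window_len is None:
        window_len = max(8, n // 4)
    noverlap = int(window_len * overlap)
    hop = window_len - noverlap
    n_windows = 1 + max(0, (n - window_len) // hop)
    if n_windows < 2:
        raise ValueError(
            f"only {n_windows} window(s) of length {window_len} fit the record; "
            "coherence needs at least two"
        )
    freqs, g2 = signal.coherence(
        stimulus,
        animal,
        fs=1.0 / dt,
        window="hann",
        nperseg=window_len,
        noverlap=noverlap,
    )
    return CoherenceSpectrum(freqs, np.clip(g2, 0.0, 1.0))


def coherent_band(
    coh: CoherenceSpectrum, threshold: float = 0.7, f_min: float | None = None
) -> tuple[float, float]:
    """Contiguous coherent band scanning upward from the lowest frequency.

    Starts at ``f_min`` (default: the lowest non-DC grid point) and extends
    while gamma^2 > threshold; returns (f_lo, f_hi), or (nan, nan) when even
    the first point fails the threshold.
    """
    if len(coh.freqs) == 0:
        raise ValueError("empty coherence spectrum")
    start = 1 if (f_min is None and coh.freqs[0] == 0.0 and len(coh.freqs) > 1) else 0
    if f_min is not None:
        start = int(np.searchsorted(coh.freqs, f_min))
    above = coh.gamma2[start:] > threshold
    if len(above) == 0 or not above[0]:
        return (np.nan, np.nan)
    stop = np.argmin(above) if not above.all() else len(above)
    return (float(coh.freqs[start]), float(coh.freqs[start + stop - 1]))


def tracking_error(H: FrequencyResponse) -> np.ndarray:
    """Per-frequency deviation from ideal tracking e(s) = |H(s) - (1+0j)|."""
    return np.abs(H.values - (1.0 + 0.0j))
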