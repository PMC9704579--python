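"""Transfer-function model containers and fit reports."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .._dsp import ctf_eval

__all__ = ["TransferFunctionModel", "FitReport", "DELAY_PURE", "DELAY_LINEAR"]

DELAY_PURE = "pure"  # e^{-s tau}
DELAY_LINEAR = "linear"  # 1 / (1 + tau s)

MAX_DELAY_S = 0.200


@dataclass
class TransferFunctionModel:
    """Rational transfer function G(s) with a transport-delay factor.

    ``num`` and ``den`` are ascending-power coefficient arrays; ``den`` is
    monic in its leading coefficient.  ``delay_structure`` selects how the
    processing delay enters: a pure delay e^{-s tau} or its first-order
    linear approximation 1/(1 + tau s).  ``uncertainties`` are one-sigma
    standard errors of the fitted coefficients, ordered as
    [num..., den[:-1]...], when the model came from a fit.
    """

    num: np.ndarray
    den: np.ndarray
    delay: float = 0.0
    delay_structure: str = DELAY_PURE
    uncertainties: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.num = np.atleast_1d(np.asarray(self.num, dtype=float))
        self.den = np.atleast_1d(np.asarray(self.den, dtype=float))
        if self.n_zeros >= self.n_poles + 1:
            raise ValueError("zero count must be < pole count + 1")
        if not (0.0 <= self.delay <= MAX_DELAY_S + 1e-12):
            raise ValueError(f"delay {self.delay} s outside [0, {MAX_DELAY_S}] s")
        if self.delay_structure not in (DELAY_PURE, DELAY_LINEAR):
            raise ValueError(f"unknown delay structure {self.delay_structure!r}")

    @property
    def n_poles(self) -> int:
        return len(self.den) - 1

    @property
    def n_zeros(self) -> int:
        return len(self.num) - 1

    @property
    def n_parameters(self) -> int:
        """Fitted coefficient count (monic denominator) plus the delay."""
        return len(self.num) + len(self.den) - 1 + 1

    def delay_factor(self, freqs_hz: np.ndarray) -> np.ndarray:
        s = 2j * np.pi * np.asarray(freqs_hz, dtype=float)
        if self.delay_structure == DELAY_PURE:
            return np.exp(-s * self.delay)
        return 1.0 / (1.0 + self.delay * s)

    def rational_response(self, freqs_hz: np.ndarray) -> np.ndarray:
        """G(j*omega) without the delay factor."""
        return ctf_eval(self.num, self.den, 2.0 * np.pi * np.asarray(freqs_hz))

    def freq_response(self, freqs_hz: np.ndarray) -> np.ndarray:
        """Full response G(j*omega) * M(j*omega, tau)."""
        return self.rational_response(freqs_hz) * self.delay_factor(freqs_hz)

    @property
    def dc_gain(self) -> float:
        return float(self.num[0] / self.den[0])

    def to_dict(self) -> dict:
        d = {
            "num": self.num.tolist(),
            "den": self.den.tolist(),
            "delay_s": float(self.delay),
            "delay_structure": self.delay_structure,
            "n_poles": self.n_poles,
            "n_zeros": self.n_zeros,
        }
        if self.uncertainties is not None:
            d["uncertainties"] = np.asarray(self.uncertainties).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TransferFunctionModel":
        unc = d.get("uncertainties")
        return cls(
            num=np.asarray(d["num"], dtype=float),
            den=np.asarray(d["den"], dtype=float),
            delay=float(d["delay_s"]),
            delay_structure=d.get("delay_structure", DELAY_PURE),
            uncertainties=None if unc is None else np.asarray(unc, dtype=float),
        )


@dataclass
class FitReport:
    """Goodness-of-fit summary for one candidate model.

    ``fit_pct`` is the normalized fit percentage on the frequency-domain
    response (100 = zero residual); ``fit_time_pct``/``mse`` are the
    time-domain analogues from simulating the model on the stimulus record;
    ``fpe`` is Akaike's final prediction error computed through an ARX
    surrogate at matching orders; ``objective`` is the summed absolute
    frequency-response mismatch that the delay/coefficient search minimizes.
    """

    fit_pct: float
    objective: float
    mse: float = np.nan
    fit_time_pct: float = np.nan
    fpe: float = np.nan

    def to_dict(self) -> dict:
        return {
            "fit_pct": float(self.fit_pct),
            "objective": float(self.objective),
            "mse": float(self.mse),
            "fit_time_pct": float(self.fit_time_pct),
            "fpe": float(self.fpe),
        }
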