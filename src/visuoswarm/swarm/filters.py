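"""Per-agent transfer-function filtering of broadcast positions.

Each agent's identified rational dynamics G_ei(s) can be interposed between
its true position and what its neighbours perceive: the continuous model is
discretized at the simulation step via the bilinear transform and applied
as a recursive (IIR) filter to the agent's broadcast position, one sample
per integration step.  The transport delay is not part of this filter — it
is handled by the delay machinery of the simulator; since both operations
are linear and time-invariant they commute, so "filter then delay" and
"delay then filter" produce the same perceived signal.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from scipy import signal

from .._dsp import bilinear_discretize
from ..sysid.models import TransferFunctionModel

__all__ = ["apply_agent_filter", "AgentFilterBank"]


def apply_agent_filter(
    model: TransferFunctionModel, series: np.ndarray, dt: float
) -> np.ndarray:
    """Filter a position series through an agent's rational dynamics.

    A unity model (G=1) is the identity.  Works on (n,) or (n, dim) arrays;
    filtering starts from rest.
    """
    series = np.asarray(series, dtype=float)
    b, a = bilinear_discretize(model.num, model.den, dt)
    return signal.lfilter(b, a, series, axis=0)


class AgentFilterBank:
    """Online per-agent IIR filters advanced one sample per simulation step.

    Filter states are primed so that a constant input passes through at the
    filter's DC gain from the first sample (the pre-history convention:
    agents have been broadcasting their initial position forever).
    """

    def __init__(
        self,
        models: Sequence[Optional[TransferFunctionModel]],
        dt: float,
    ):
        self._coeffs: list[tuple[np.ndarray, np.ndarray] | None] = []
        self._zi: list[np.ndarray | None] = []
        for m in models:
            if m is None:
                self._coeffs.append(None)
                self._zi.append(None)
                continue
            b, a = bilinear_discretize(m.num, m.den, dt)
            # flag unstable discretizations but keep going, as a warning
            poles = np.roots(a)
            if np.any(np.abs(poles) > 1.0 + 1e-9):
                import warnings

                warnings.warn(
                    "discretized agent filter is unstable; simulation continues",
                    RuntimeWarning,
                    stacklevel=2,
                )
            self._coeffs.append((b, a))
            self._zi.append(None)  # primed on first sample

    def step(self, x: np.ndarray) -> np.ndarray:
        """Advance every filter by one sample of broadcast positions (n, dim)."""
        out = x.copy()
        for i, coeffs in enumerate(self._coeffs):
            if coeffs is None:
                continue
            b, a = coeffs
            if self._zi[i] is None:
                zi1 = signal.lfilter_zi(b, a)  # steady state for unit input
                self._zi[i] = zi1[:, None] * x[i][None, :]
            y, self._zi[i] = signal.lfilter(
                b, a, x[i][None, :], axis=0, zi=self._zi[i]
            )
            out[i] = y[0]
        return out
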