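"""Identify an individual's visuomotor transport delay from tracking data.

Builds a periodic multisine stimulus (eight sinusoids spanning 0.1-1.7 Hz,
60 s at the 0.02 s frame interval), synthesizes a noiseless closed-loop
tracking response from a known second-order model with a 21 ms transport
delay, and runs the full identification pipeline: tracking-section
extraction, coherence gating, line spectra, and the delayed transfer-
function grid search (2-4 poles, 1-4 zeros, both delay structures, 1 ms
delay grid over 0-200 ms).
"""

import numpy as np

from visuoswarm.synthetic import HONEYBEE_EXAMPLE, generate_stimulus, multisine_spec
from visuoswarm.sysid import IdentificationConfig, identify_tracking

spec = multisine_spec(f_min=0.1, f_max=1.7, n_components=8, duration=60.0, dt=0.02)
stimulus = generate_stimulus(spec)
animal = HONEYBEE_EXAMPLE.steady_state_response(spec)

report = identify_tracking(
    stimulus, animal,
    IdentificationConfig(tolerance=20.0, excited_freqs=spec.frequencies),
)

print(f"tracking sections        : {len(report.sections)}")
print(f"coherent band            : {report.coherent_band[0]:.2f}-"
      f"{report.coherent_band[1]:.2f} Hz")
print(f"best structure           : {report.model.n_poles} poles, "
      f"{report.model.n_zeros} zero(s), {report.model.delay_structure} delay")
print(f"transport delay          : {report.delay_ms:.1f} ms")
print(f"numerator  (ascending s) : {np.round(report.model.num, 3)}")
print(f"denominator (ascending s): {np.round(report.model.den, 3)}")
print(f"fit                      : {report.report.fit_pct:.2f}%")

# The delay is the headline number: the lag between stimulus motion and the
# animal's tracking response. The printed coefficients reproduce the
# ground-truth model (9.204 - 0.285 s) / (8.098 + 2.098 s + s^2) to <1%,
# confirming the grid search separates the rational dynamics from the pure
# transport-delay factor.
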