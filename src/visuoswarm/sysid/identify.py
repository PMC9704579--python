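"""End-to-end delay identification from paired stimulus/animal trajectories.

Pipeline: extract tracking sections, concatenate them, compute coherence and
spectra, form the empirical frequency response at the excited stimulus
frequencies, grid-search delayed transfer-function structures, and select
the best model.

With multisine excitation the stimulus has power only at its component
lines, so the spectral ratio D2/D1 is meaningful exactly there; between
lines both spectra are leakage tails and their ratio blends neighbouring
line responses.  The fit therefore uses the response at the excited lines
(gated by coherence), while the chirp-z transform provides the dense
band-limited spectra used to localize lines and report the response at high
resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _sig

from ..trajectory import Trajectory
from .fit import ModelSelection, fit_transfer_function, select_best_model
from .models import FitReport, TransferFunctionModel
from .sections import TrackingSection, concatenate_sections, find_tracking_sections
from .spectra import (
    CoherenceSpectrum,
    FrequencyResponse,
    coherence,
    coherent_band,
    czt_response,
    empirical_response,
    fft_response,
    line_spectrum,
)

__all__ = ["IdentificationConfig", "IdentificationReport", "identify_tracking"]


@dataclass
class IdentificationConfig:
    """Tunable parameters of the identification pipeline (defaults mirror the
    data-collection thresholds: 0.02 s frame interval, tracking tolerance
    eta_gamma, coherence threshold 0.7, CZT band capped at 0.2 Hz)."""

    tolerance: float = 0.1
    min_section_len: int = 30
    remove_section_means: bool = True
    coherence_threshold: float = 0.7
    czt_band: tuple[float, float] = (0.01, 0.2)
    czt_points: int = 256
    delay_step_ms: float = 1.0
    delay_max_ms: float = 200.0
    structures: list[tuple[int, int]] | None = None
    excited_freqs: np.ndarray | None = None  # known stimulus lines, Hz
    peak_rel_height: float = 0.1  # line detection threshold if lines unknown


@dataclass
class IdentificationReport:
    """Everything the identification stage produces for one individual."""

    model: TransferFunctionModel
    report: FitReport
    criteria_disagree: bool
    candidates: list[tuple[TransferFunctionModel, FitReport]]
    sections: list[TrackingSection]
    coherence: CoherenceSpectrum
    coherent_band: tuple[float, float]
    response: FrequencyResponse  # fitted H samples at excited lines
    czt_h: FrequencyResponse | None

    @property
    def delay_ms(self) -> float:
        return 1e3 * self.model.delay

    def to_dict(self) -> dict:
        return {
            "model": self.model.to_dict(),
            "delay_ms": self.delay_ms,
            "fit": self.report.to_dict(),
            "criteria_disagree": bool(self.criteria_disagree),
            "coherent_band_hz": [float(v) for v in self.coherent_band],
            "n_sections": len(self.sections),
            "n_response_points": len(self.response.freqs),
            "candidates": [
                {"model": m.to_dict(), "fit": r.to_dict()}
                for m, r in self.candidates
            ],
        }


def _detect_lines(d1: np.ndarray, dt: float, rel_height: float) -> np.ndarray:
    """Locate excited stimulus lines as peaks of the stimulus spectrum."""
    spec = fft_response(d1, dt)
    mag = np.abs(spec.values)
    peaks, _ = _sig.find_peaks(mag, height=rel_height * mag.max())
    return spec.freqs[peaks]


def identify_tracking(
    stimulus: Trajectory,
    animal: Trajectory,
    config: IdentificationConfig | None = None,
) -> IdentificationReport:
    """Run the full identification pipeline on one trajectory pair."""
    cfg = config or IdentificationConfig()

    sections = find_tracking_sections(
        stimulus, animal, tolerance=cfg.tolerance, min_len=cfg.min_section_len
    )
    if not sections:
        raise ValueError("no tracking sections found at the given tolerance")
    d1, d2, dt = concatenate_sections(
        sections, remove_section_means=cfg.remove_section_means
    )

    coh = coherence(d1, d2, dt)
    band = coherent_band(coh, threshold=cfg.coherence_threshold)

    lines = (
        np.asarray(cfg.excited_freqs, dtype=float)
        if cfg.excited_freqs is not None
        else _detect_lines(d1, dt, cfg.peak_rel_height)
    )
    if len(lines) == 0:
        raise ValueError("no excited stimulus lines found in the record")

    # empirical response at the excited lines, evaluated on the original
    # timeline with per-section tapering: chopping out tracking sections and
    # repositioning them would smear the excitation lines, while a masked
    # transform keeps every sample at its true time.  One section covering
    # the whole record keeps a rectangular taper (exact for a periodic
    # multisine); gappy records get a Hann taper per section to suppress
    # cross-line leakage through the mask.
    n = stimulus.n_samples
    whole = len(sections) == 1 and sections[0].length == n
    weight = np.zeros(n)
    for sec in sections:
        taper = np.ones(sec.length) if whole else np.hanning(sec.length)
        weight[sec.start : sec.start + sec.length] = taper
    s_full = stimulus.component(0)
    a_full = animal.component(0)
    spec1 = line_spectrum(s_full, stimulus.dt, lines, weight, source="D1")
    spec2 = line_spectrum(a_full, stimulus.dt, lines, weight, source="D2")
    mag = np.abs(spec1.values)
    keep = mag >= 1e-8 * mag.max()
    # gate each line by the coherence at its nearest Welch bin
    coh_at = np.interp(lines, coh.freqs, coh.gamma2)
    keep &= coh_at > cfg.coherence_threshold
    if not keep.any():
        raise ValueError("no excited line passes the coherence threshold")
    H = FrequencyResponse(
        lines[keep],
        spec2.values[keep] / spec1.values[keep],
        method="line",
        source="H",
    )

    czt_h = None
    f_lo, f_hi = cfg.czt_band
    if f_hi <= 0.5 / dt:
        czt1 = czt_response(d1, dt, f_lo, f_hi, cfg.czt_points, source="D1")
        czt2 = czt_response(d2, dt, f_lo, f_hi, cfg.czt_points, source="D2")
        czt_h = empirical_response(czt1, czt2)

    delay_grid = np.arange(0.0, cfg.delay_max_ms + cfg.delay_step_ms / 2,
                           cfg.delay_step_ms) * 1e-3
    candidates = fit_transfer_function(
        H,
        structures=cfg.structures,
        delay_grid=delay_grid,
        time_data=(d1, d2, dt),
    )
    sel: ModelSelection = select_best_model(candidates)

    return IdentificationReport(
        model=sel.model,
        report=sel.report,
        criteria_disagree=sel.criteria_disagree,
        candidates=candidates,
        sections=sections,
        coherence=coh,
        coherent_band=band,
        response=H,
        czt_h=czt_h,
    )
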