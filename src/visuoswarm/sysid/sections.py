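"""Tracking-section extraction and concatenation.

Animals track the stimulus intermittently.  A tracking section is a maximal
run of consecutive samples on which the stimulus and animal X positions
agree within a tolerance, with a minimum length of 30 samples; only those
runs enter the frequency-domain analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..trajectory import Trajectory

__all__ = ["TrackingSection", "find_tracking_sections", "concatenate_sections"]

MIN_SECTION_LEN = 30


@dataclass
class TrackingSection:
    """Paired stimulus/animal sub-trajectory where the animal tracks."""

    stimulus: np.ndarray
    animal: np.ndarray
    start: int  # index q into the parent trajectory
    dt: float

    def __post_init__(self) -> None:
        if len(self.stimulus) != len(self.animal):
            raise ValueError("stimulus and animal columns must have equal length")

    @property
    def length(self) -> int:
        return len(self.stimulus)


def find_tracking_sections(
    stimulus: Trajectory,
    animal: Trajectory,
    tolerance: float,
    min_len: int = MIN_SECTION_LEN,
    axis: int = 0,
) -> list[TrackingSection]:
    """Identify maximal tracking runs |stimulus - animal| < tolerance.

    Sections are returned in time order, non-overlapping, each at least
    ``min_len`` samples long.  X coordinates are compared by default.
    """
    if stimulus.n_samples != animal.n_samples:
        raise ValueError(
            f"length mismatch: stimulus has {stimulus.n_samples} samples, "
            f"animal has {animal.n_samples}"
        )
    if stimulus.dt != animal.dt:
        raise ValueError("stimulus and animal must share the same dt")
    s = stimulus.component(axis)
    a = animal.component(axis)
    within = np.abs(s - a) < tolerance

    sections: list[TrackingSection] = []
    # boundaries of runs of True
    padded = np.concatenate([[False], within, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    for q, stop in zip(edges[::2], edges[1::2]):
        if stop - q >= min_len:
            sections.append(
                TrackingSection(
                    stimulus=s[q:stop].copy(),
                    animal=a[q:stop].copy(),
                    start=int(q),
                    dt=stimulus.dt,
                )
            )
    return sections


def concatenate_sections(
    sections: list[TrackingSection], remove_section_means: bool = True
) -> tuple[np.ndarray, np.ndarray, float]:
    """Join tracking sections into paired 1-D records (D1(t), D2(t)).

    Per-section mean removal (default on) suppresses the broadband join
    artifacts that raw concatenation injects into the spectra; switch it off
    to reproduce a literal raw join.  Returns (stimulus, animal, dt).
    """
    if not sections:
        raise ValueError("cannot concatenate an empty list of sections")
    dt = sections[0].dt
    d1, d2 = [], []
    for sec in sorted(sections, key=lambda s: s.start):
        if sec.dt != dt:
            raise ValueError("sections have inconsistent dt")
        s, a = sec.stimulus, sec.animal
        if remove_section_means:
            s = s - s.mean()
            a = a - a.mean()
        d1.append(s)
        d2.append(a)
    return np.concatenate(d1), np.concatenate(d2), dt
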