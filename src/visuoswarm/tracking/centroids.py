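"""Connected-component centroid extraction from binary foreground masks."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure

__all__ = ["Detection2D", "extract_centroids"]


@dataclass
class Detection2D:
    """One detected blob in one camera frame.

    Centroid is in (u, v) = (column, row) pixels, origin top-left, 0-based.
    ``source`` records whether it was measured from pixels or predicted by
    the Kalman filter across a gap.
    """

    frame: int
    camera_id: str
    u: float
    v: float
    area: float
    source: str = "measured"  # "measured" | "kalman-predicted"

    @property
    def uv(self) -> np.ndarray:
        return np.array([self.u, self.v])


def extract_centroids(
    mask: np.ndarray,
    frame: int = 0,
    camera_id: str = "cam0",
    min_area: float = 0.0,
    max_area: float = np.inf,
) -> list[Detection2D]:
    """Blob centroids of a binary mask, largest area first.

    Components outside [min_area, max_area] pixels^2 are dropped.  Centroids
    are intensity-unweighted pixel means of each component.
    """
    labels = measure.label(np.asarray(mask, dtype=bool), connectivity=2)
    out = []
    for region in measure.regionprops(labels):
        if not (min_area <= region.area <= max_area):
            continue
        row, col = region.centroid
        out.append(
            Detection2D(
                frame=frame, camera_id=camera_id,
                u=float(col), v=float(row), area=float(region.area),
            )
        )
    out.sort(key=lambda d: -d.area)
    return out
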