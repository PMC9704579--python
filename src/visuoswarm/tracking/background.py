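"""Running-average background model, automatic threshold, segmentation.

Foreground extraction for slowly varying scenes: the background estimate is
a per-pixel exponential moving average E_t = (1 - eta_mu) E_{t-1} +
eta_mu F_t, updated every frame with weight eta_mu (0.1 by default).  The
binary foreground mask keeps pixels where |F - E| exceeds a grey-level
threshold eta_alpha, which may be fixed (default 10) or derived
automatically as eta_lambda times the mean absolute frame-background
difference, clamped into the working range [10, 30].  Gaussian blur and
morphological closure clean the mask before centroid extraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import morphology

__all__ = [
    "BackgroundModel",
    "SegmentationParams",
    "update_background",
    "auto_threshold",
    "segment_foreground",
]

AUTO_THRESHOLD_RANGE = (10.0, 30.0)


@dataclass
class BackgroundModel:
    """Exponential-moving-average background estimate."""

    estimate: np.ndarray
    eta_mu: float = 0.1
    frames_absorbed: int = 0

    def __post_init__(self) -> None:
        self.estimate = np.asarray(self.estimate, dtype=float)
        if not (0.0 <= self.eta_mu <= 1.0):
            raise ValueError("update weight eta_mu must lie in [0, 1]")

    @classmethod
    def from_initial_frames(
        cls, frames: np.ndarray, eta_mu: float = 0.1, n_init: int = 10
    ) -> "BackgroundModel":
        """Initial background = mean of the first few frames (default 10)."""
        frames = np.asarray(frames, dtype=float)
        init = frames[: min(n_init, len(frames))].mean(axis=0)
        return cls(estimate=init, eta_mu=eta_mu, frames_absorbed=min(n_init, len(frames)))


def update_background(model: BackgroundModel, frame: np.ndarray) -> BackgroundModel:
    """One EMA update E_t = (1 - eta_mu) E_{t-1} + eta_mu F_t."""
    frame = np.asarray(frame, dtype=float)
    if frame.shape != model.estimate.shape:
        raise ValueError(
            f"frame shape {frame.shape} does not match background "
            f"{model.estimate.shape}"
        )
    est = (1.0 - model.eta_mu) * model.estimate + model.eta_mu * frame
    return BackgroundModel(est, model.eta_mu, model.frames_absorbed + 1)


def auto_threshold(
    frame: np.ndarray,
    background: np.ndarray,
    eta_lambda: float = 1.0,
    clamp: tuple[float, float] = AUTO_THRESHOLD_RANGE,
) -> float:
    """Automatic threshold: eta_lambda * mean |F - E|, clamped to [10, 30]."""
    frame = np.asarray(frame, dtype=float)
    background = np.asarray(background, dtype=float)
    if frame.shape != background.shape:
        raise ValueError("frame and background shapes differ")
    raw = eta_lambda * np.abs(frame - background).mean()
    return float(np.clip(raw, *clamp))


@dataclass
class SegmentationParams:
    """Segmentation thresholds and mask post-processing settings."""

    eta_alpha: float = 10.0  # fixed grey-level threshold
    eta_lambda: float = 1.0  # inhibition coefficient for the auto threshold
    auto: bool = False
    blur_kernel: int = 5  # Gaussian kernel size, pixels (odd); 0 disables
    closure_kernel: int = 3  # morphological closing footprint (odd); 0 disables
    min_area: float = 3.0  # blob area bounds, pixels^2
    max_area: float = np.inf

    def __post_init__(self) -> None:
        for name in ("blur_kernel", "closure_kernel"):
            k = getattr(self, name)
            if k and (k < 0 or k % 2 == 0):
                raise ValueError(f"{name} must be odd and positive (or 0 to disable)")


def segment_foreground(
    frame: np.ndarray,
    background: np.ndarray,
    params: SegmentationParams | float = 10.0,
) -> np.ndarray:
    """Binary foreground mask K = 1 where |F - E| >= eta_alpha.

    Accepts either a bare threshold or full :class:`SegmentationParams`
    (enabling the auto threshold, Gaussian blur of the difference image and
    morphological closure of the mask).
    """
    if not isinstance(params, SegmentationParams):
        params = SegmentationParams(eta_alpha=float(params), blur_kernel=0,
                                    closure_kernel=0)
    frame = np.asarray(frame, dtype=float)
    background = np.asarray(background, dtype=float)
    if frame.shape != background.shape:
        raise ValueError("frame and background shapes differ")

    diff = np.abs(frame - background)
    if params.blur_kernel:
        # sigma = kernel/6 so the kernel spans ~3 sigma each side
        diff = ndimage.gaussian_filter(diff, sigma=params.blur_kernel / 6.0)
    thr = (
        auto_threshold(frame, background, params.eta_lambda)
        if params.auto
        else params.eta_alpha
    )
    mask = diff >= thr
    if params.closure_kernel:
        footprint = np.ones((params.closure_kernel,) * 2, dtype=bool)
        mask = morphology.closing(mask, footprint)
    return mask.astype(bool)
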