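"""Rendered multi-camera image sequences of a moving bright blob.

Test fixture for the vision stages: each frame is a slowly drifting grey
background plus a Gaussian bright blob at the projection of a known 3-D
point, plus pixel noise.  The renderer returns the true projected centroids
so downstream detection and triangulation can be asserted against ground
truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..tracking.cameras import CameraModel
from ..trajectory import Trajectory

__all__ = ["SceneSpec", "RenderedSequence", "render_image_sequence"]


@dataclass
class SceneSpec:
    """Synthetic scene parameters for the blob renderer."""

    cameras: list[CameraModel]
    image_size: tuple[int, int] = (64, 64)  # (n_h, n_v) = (width, height)
    blob_radius: float = 2.0  # Gaussian sigma, pixels
    blob_intensity: float = 120.0  # grey levels above background
    background_level: float = 40.0
    background_drift: float = 0.0  # grey levels per frame
    noise_sd: float = 0.0
    seed: int = 0
    blob_absent_frames: int = 0  # blob-free lead-in while the background learns

    def __post_init__(self) -> None:
        if len(self.cameras) < 2:
            raise ValueError("need at least two cameras")
        if not (0 <= self.background_level <= 255):
            raise ValueError("background level outside 8-bit range")


@dataclass
class RenderedSequence:
    """Per-camera image stacks plus ground-truth 2-D centroids."""

    frames: dict[str, np.ndarray]  # camera_id -> (n_frames, n_v, n_h) uint8
    centroids: dict[str, np.ndarray]  # camera_id -> (n_frames, 2) float (u, v)
    points3d: np.ndarray  # (n_frames, 3)


def render_image_sequence(path3d: Trajectory, scene: SceneSpec) -> RenderedSequence:
    """Render the moving point through every camera.

    Raises if the point projects outside any image (with the frame index);
    the blob must stay fully visible for the fixture to be meaningful.
    """
    pts = np.atleast_2d(path3d.values)
    if pts.shape[1] != 3:
        raise ValueError("path3d must be a 3-D trajectory")
    n_frames = len(pts)
    n_h, n_v = scene.image_size
    rng = np.random.default_rng(scene.seed)

    vv, uu = np.mgrid[0:n_v, 0:n_h]
    frames: dict[str, np.ndarray] = {}
    centroids: dict[str, np.ndarray] = {}
    margin = 3.0 * scene.blob_radius
    for cam in scene.cameras:
        uv = cam.project(pts)
        for k, (u, v) in enumerate(uv):
            if not (margin <= u <= n_h - 1 - margin and margin <= v <= n_v - 1 - margin):
                raise ValueError(
                    f"frame {k}: point projects to ({u:.1f}, {v:.1f}) outside "
                    f"the usable area of {cam.camera_id}"
                )
        stack = np.empty((n_frames, n_v, n_h), dtype=np.uint8)
        truth = uv.copy()
        for k, (u, v) in enumerate(uv):
            img = np.full((n_v, n_h), scene.background_level, dtype=float)
            img += scene.background_drift * k
            if k >= scene.blob_absent_frames:
                r2 = (uu - u) ** 2 + (vv - v) ** 2
                img += scene.blob_intensity * np.exp(-0.5 * r2 / scene.blob_radius**2)
            else:
                truth[k] = np.nan
            if scene.noise_sd > 0:
                img += rng.normal(0.0, scene.noise_sd, img.shape)
            stack[k] = np.clip(img, 0, 255).astype(np.uint8)
        frames[cam.camera_id] = stack
        centroids[cam.camera_id] = truth
    return RenderedSequence(frames=frames, centroids=centroids, points3d=pts)
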