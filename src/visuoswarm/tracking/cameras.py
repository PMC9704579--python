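"""Camera models and synthetic camera rigs.

A camera is just its 3x4 projection matrix P (calibration is assumed done
elsewhere; matrices are inputs).  Pixel convention used everywhere in the
package: (u, v) = (column, row), origin at the top-left corner, 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CameraModel", "make_camera_ring"]


@dataclass
class CameraModel:
    """Finite projective camera with 3x4 matrix P."""

    P: np.ndarray
    camera_id: str = "cam0"

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        if self.P.shape != (3, 4):
            raise ValueError(f"projection matrix must be 3x4, got {self.P.shape}")
        if np.linalg.matrix_rank(self.P) != 3:
            raise ValueError("projection matrix must have rank 3")

    def project(self, points: np.ndarray) -> np.ndarray:
        """Project (n, 3) world points to (n, 2) pixel coordinates (u, v)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        hom = np.hstack([pts, np.ones((len(pts), 1))])
        img = hom @ self.P.T
        w = img[:, 2]
        if np.any(np.abs(w) < 1e-12):
            raise ValueError("point projects to infinity for this camera")
        uv = img[:, :2] / w[:, None]
        return uv if np.asarray(points).ndim == 2 else uv[0]


def _look_at(center: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rotation matrix with camera z-axis pointing from center to target."""
    z = target - center
    z = z / np.linalg.norm(z)
    up = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(up, z)) > 0.99:
        up = np.array([0.0, 1.0, 0.0])
    x = np.cross(up, z)
    x /= np.linalg.norm(x)
    y = np.cross(z, x)
    return np.stack([x, y, z])


def make_camera_ring(
    n_cameras: int = 3,
    distance: float = 2.0,
    image_size: tuple[int, int] = (64, 64),
    focal_px: float = 120.0,
    target: np.ndarray | None = None,
    angular_span_deg: float = 160.0,
    elevation: float = 0.3,
) -> list[CameraModel]:
    """Build a ring of synthetic calibrated cameras looking at a common target.

    Mimics a tripod arrangement with cameras separated by tens of degrees.
    image_size is (n_h, n_v) = (width, height) pixels.
    """
    if n_cameras < 1:
        raise ValueError("need at least one camera")
    target = np.zeros(3) if target is None else np.asarray(target, dtype=float)
    cx, cy = image_size[0] / 2.0, image_size[1] / 2.0
    K = np.array([[focal_px, 0, cx], [0, focal_px, cy], [0, 0, 1.0]])
    cams = []
    angles = np.linspace(0.0, np.deg2rad(angular_span_deg), n_cameras)
    for k, th in enumerate(angles):
        center = target + distance * np.array(
            [np.cos(th), np.sin(th), elevation / distance]
        )
        R = _look_at(center, target)
        t = -R @ center
        P = K @ np.hstack([R, t[:, None]])
        cams.append(CameraModel(P, camera_id=f"cam{k}"))
    return cams
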