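"""Linear (DLT) triangulation of multi-camera detections with reprojection
gating.

Each camera contributes two rows to a homogeneous system built from its
projection matrix P and the detection (u, v):

    [v P_3 - P_2]
    [u P_3 - P_1] O = 0,

solved for the 3-D point O by singular value decomposition (at least two
cameras required).  The point is re-projected into every contributing
camera and accepted only when the maximum reprojection error is within the
tolerance eta_psi (0.5 px by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cameras import CameraModel
from .centroids import Detection2D

__all__ = ["Point3D", "TriangulationError", "triangulate"]

DEFAULT_ETA_PSI = 0.5  # reprojection tolerance, pixels


class TriangulationError(ValueError):
    """Triangulation could not produce an acceptable point."""


@dataclass
class Point3D:
    """Reconstructed 3-D point with its reprojection diagnostics."""

    xyz: np.ndarray
    reprojection_error: float  # max over contributing cameras, pixels
    camera_ids: list[str]
    frame: int = 0


def triangulate(
    detections: list[Detection2D],
    cameras: dict[str, CameraModel] | list[CameraModel],
    eta_psi: float = DEFAULT_ETA_PSI,
) -> Point3D:
    """DLT-triangulate one frame's detections across cameras.

    Raises :class:`TriangulationError` for fewer than two views, a
    degenerate (rank-deficient) system, or a reprojection error above
    eta_psi (the error value is included in the message).
    """
    if isinstance(cameras, list):
        cameras = {c.camera_id: c for c in cameras}
    if len(detections) < 2:
        raise TriangulationError("need detections from at least two cameras")
    frames = {d.frame for d in detections}
    if len(frames) != 1:
        raise TriangulationError(f"detections span multiple frames: {sorted(frames)}")

    rows = []
    used = []
    for det in detections:
        cam = cameras[det.camera_id]
        P = cam.P
        rows.append(det.v * P[2] - P[1])
        rows.append(det.u * P[2] - P[0])
        used.append(det)
    A = np.asarray(rows)

    _, svals, vt = np.linalg.svd(A)
    # rank-deficient design (e.g. identical cameras) has >1 vanishing direction
    if svals[-2] < 1e-10 * svals[0]:
        raise TriangulationError("degenerate camera geometry: DLT system is rank deficient")
    X = vt[-1]
    if abs(X[3]) < 1e-12:
        raise TriangulationError("triangulated point at infinity")
    xyz = X[:3] / X[3]

    errs = []
    for det in used:
        uv = cameras[det.camera_id].project(xyz)
        errs.append(float(np.linalg.norm(uv - det.uv)))
    err = max(errs)
    if err > eta_psi:
        raise TriangulationError(
            f"reprojection error {err:.3f} px exceeds tolerance {eta_psi} px"
        )
    return Point3D(
        xyz=xyz,
        reprojection_error=err,
        camera_ids=[d.camera_id for d in used],
        frame=used[0].frame,
    )
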