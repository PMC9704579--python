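"""End-to-end multi-camera tracking: images in, 3-D trajectory out.

Per camera and frame: update the running-average background, segment the
foreground, extract blob centroids, and associate one detection to the
track by gating to the Kalman prediction (nearest detection within the gate
radius, ties broken by larger area).  Missing detections are bridged by the
Kalman prediction.  Per frame, the associated detections of all cameras are
DLT-triangulated with reprojection gating to produce the 3-D position.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..trajectory import Trajectory
from .background import BackgroundModel, SegmentationParams, segment_foreground, update_background
from .cameras import CameraModel
from .centroids import Detection2D, extract_centroids
from .kalman import KalmanTrack, kalman_step
from .triangulate import TriangulationError, triangulate

__all__ = ["TrackerParams", "TrackingOutput", "track_sequence"]


@dataclass
class TrackerParams:
    """Knobs of the full tracking pipeline (defaults mirror the recording
    thresholds: dt = 0.02 s, eta_mu = 0.1, eta_alpha = 10, eps = 0.5,
    eta_psi = 0.5)."""

    dt: float = 0.02
    eta_mu: float = 0.1
    n_init_frames: int = 10
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    eps_a: float = 0.5
    eps_x: float = 0.5
    eps_y: float = 0.5
    eta_psi: float = 0.5
    gate_radius: float = 15.0  # association gate around the prediction, px
    max_missed: int = 10  # drop the track after this many blind frames


@dataclass
class TrackingOutput:
    """3-D trajectory plus per-camera 2-D detections and diagnostics."""

    trajectory: Trajectory  # (n, 3); NaN rows where triangulation failed
    reprojection_error: np.ndarray  # (n,), NaN where failed
    n_cameras: np.ndarray  # (n,) contributing views
    detections: dict[str, list[Detection2D]]

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.trajectory.values).all(axis=1)


def _associate(
    detections: list[Detection2D], track: KalmanTrack | None, gate: float
) -> Detection2D | None:
    """Nearest detection within the gate; ties by larger area."""
    if not detections:
        return None
    if track is None:
        return detections[0]  # largest blob starts the track
    pred = track.position
    best, best_key = None, None
    for d in detections:
        dist = float(np.linalg.norm(d.uv - pred))
        if dist > gate:
            continue
        key = (round(dist, 6), -d.area)
        if best_key is None or key < best_key:
            best, best_key = d, key
    return best


def track_sequence(
    frames: dict[str, np.ndarray],
    cameras: list[CameraModel] | dict[str, CameraModel],
    params: TrackerParams | None = None,
) -> TrackingOutput:
    """Track a single bright target through per-camera image stacks.

    ``frames`` maps camera id -> (n_frames, height, width) array; all
    cameras must cover the same frames.
    """
    params = params or TrackerParams()
    if isinstance(cameras, list):
        cameras = {c.camera_id: c for c in cameras}
    cam_ids = sorted(frames)
    n_frames = {len(frames[c]) for c in cam_ids}
    if len(n_frames) != 1:
        raise ValueError("camera stacks have different frame counts")
    n = n_frames.pop()

    backgrounds = {
        c: BackgroundModel.from_initial_frames(
            frames[c], eta_mu=params.eta_mu, n_init=params.n_init_frames
        )
        for c in cam_ids
    }
    tracks: dict[str, KalmanTrack | None] = {c: None for c in cam_ids}
    all_detections: dict[str, list[Detection2D]] = {c: [] for c in cam_ids}

    xyz = np.full((n, 3), np.nan)
    reproj = np.full(n, np.nan)
    n_cams = np.zeros(n, dtype=int)

    for k in range(n):
        frame_dets: list[Detection2D] = []
        for c in cam_ids:
            img = frames[c][k]
            backgrounds[c] = update_background(backgrounds[c], img)
            mask = segment_foreground(
                img, backgrounds[c].estimate, params.segmentation
            )
            dets = extract_centroids(
                mask, frame=k, camera_id=c,
                min_area=params.segmentation.min_area,
                max_area=params.segmentation.max_area,
            )
            chosen = _associate(dets, tracks[c], params.gate_radius)
            if chosen is not None:
                if tracks[c] is None:
                    tracks[c] = KalmanTrack.from_detection(
                        chosen.u, chosen.v, dt=params.dt,
                        eps_a=params.eps_a, eps_x=params.eps_x, eps_y=params.eps_y,
                    )
                else:
                    tracks[c] = kalman_step(tracks[c], chosen.uv)
                det = chosen
            elif tracks[c] is not None and tracks[c].missed_frames < params.max_missed:
                tracks[c] = kalman_step(tracks[c], None)
                u, v = tracks[c].position
                det = Detection2D(
                    frame=k, camera_id=c, u=float(u), v=float(v),
                    area=0.0, source="kalman-predicted",
                )
            else:
                tracks[c] = None
                continue
            all_detections[c].append(det)
            frame_dets.append(det)

        if len(frame_dets) >= 2:
            try:
                pt = triangulate(frame_dets, cameras, eta_psi=params.eta_psi)
            except TriangulationError:
                continue
            xyz[k] = pt.xyz
            reproj[k] = pt.reprojection_error
            n_cams[k] = len(pt.camera_ids)

    return TrackingOutput(
        trajectory=Trajectory(xyz, params.dt),
        reprojection_error=reproj,
        n_cameras=n_cams,
        detections=all_detections,
    )
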