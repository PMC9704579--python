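"""Constant-velocity Kalman filtering of 2-D image-plane detections.

Kinematic model in image coordinates: state (p_x, p_y, v_x, v_y) with

    x_k = A x_{k-1} + B a_{k-1},   A = [[1,0,dt,0],[0,1,0,dt],[0,0,1,0],[0,0,0,1]],
    B = [[dt^2/2,0],[0,dt^2/2],[dt,0],[0,dt]],   y = C x, C = [[1,0,0,0],[0,1,0,0]].

The process noise covariance E_x is built from the acceleration SD eps_a
(position SD = eps_a dt^2/2, velocity SD = eps_a dt) and the measurement
noise covariance E_z from the pixel SDs (eps_x, eps_y).  Prediction runs
every frame; when a detection is missing the corrected state is simply the
prediction and the missed-frame count increments, so blob positions keep
being produced across short occlusions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["KalmanTrack", "kalman_step", "process_noise", "measurement_noise"]


def process_noise(eps_a: float, dt: float) -> np.ndarray:
    """Process noise covariance E_x from the acceleration SD and time step."""
    q = np.array(
        [
            [dt**4 / 4, 0, dt**3 / 2, 0],
            [0, dt**4 / 4, 0, dt**3 / 2],
            [dt**3 / 2, 0, dt**2, 0],
            [0, dt**3 / 2, 0, dt**2],
        ]
    )
    return q * eps_a**2


def measurement_noise(eps_x: float, eps_y: float) -> np.ndarray:
    return np.diag([eps_x**2, eps_y**2])


@dataclass
class KalmanTrack:
    """State, covariance and model matrices of one image-plane track."""

    state: np.ndarray  # (4,) = (p_x, p_y, v_x, v_y)
    covariance: np.ndarray  # (4, 4)
    dt: float = 0.02
    eps_a: float = 0.5
    eps_x: float = 0.5
    eps_y: float = 0.5
    missed_frames: int = 0
    valid: bool = True

    def __post_init__(self) -> None:
        self.state = np.asarray(self.state, dtype=float)
        self.covariance = np.asarray(self.covariance, dtype=float)
        if self.state.shape != (4,) or self.covariance.shape != (4, 4):
            raise ValueError("state must be (4,), covariance (4, 4)")

    @classmethod
    def from_detection(
        cls, u: float, v: float, dt: float = 0.02,
        eps_a: float = 0.5, eps_x: float = 0.5, eps_y: float = 0.5,
        position_var: float = 1.0, velocity_var: float = 100.0,
    ) -> "KalmanTrack":
        return cls(
            state=np.array([u, v, 0.0, 0.0]),
            covariance=np.diag([position_var, position_var,
                                velocity_var, velocity_var]),
            dt=dt, eps_a=eps_a, eps_x=eps_x, eps_y=eps_y,
        )

    @property
    def A(self) -> np.ndarray:
        dt = self.dt
        return np.array(
            [[1, 0, dt, 0], [0, 1, 0, dt], [0, 0, 1, 0], [0, 0, 0, 1]], dtype=float
        )

    @property
    def C(self) -> np.ndarray:
        return np.array([[1, 0, 0, 0], [0, 1, 0, 0]], dtype=float)

    @property
    def position(self) -> np.ndarray:
        return self.state[:2]


def kalman_step(
    track: KalmanTrack, measurement: np.ndarray | None = None
) -> KalmanTrack:
    """One predict(+correct) cycle.

    Predict: x^- = A x, P^- = A P A^T + E_x.  With a measurement, correct
    with the Kalman gain K = P^- C^T (C P^- C^T + E_z)^{-1}; without one the
    prediction is kept and the missed-frame count increments.  The updated
    covariance is re-symmetrized each step; a non-finite covariance flags
    the track invalid.
    """
    A, C = track.A, track.C
    Ex = process_noise(track.eps_a, track.dt)
    Ez = measurement_noise(track.eps_x, track.eps_y)

    x_pred = A @ track.state
    p_pred = A @ track.covariance @ A.T + Ex

    if measurement is None:
        x_new, p_new = x_pred, p_pred
        missed = track.missed_frames + 1
    else:
        z = np.asarray(measurement, dtype=float)
        S = C @ p_pred @ C.T + Ez
        K = p_pred @ C.T @ np.linalg.inv(S)
        x_new = x_pred + K @ (z - C @ x_pred)
        p_new = (np.eye(4) - K @ C) @ p_pred
        missed = 0

    p_new = 0.5 * (p_new + p_new.T)
    valid = bool(np.all(np.isfinite(p_new)) and np.all(np.isfinite(x_new)))
    return KalmanTrack(
        state=x_new, covariance=p_new, dt=track.dt,
        eps_a=track.eps_a, eps_x=track.eps_x, eps_y=track.eps_y,
        missed_frames=missed, valid=valid,
    )
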