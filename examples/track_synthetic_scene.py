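"""Track a flying target through a rendered three-camera scene.

Renders a fast 3-D orbit as a bright Gaussian blob over a drifting noisy
background in three synthetic calibrated cameras (with a blob-free lead-in
while the background model initializes), then runs the full vision
pipeline — running-average background subtraction, thresholded
segmentation, blob centroids, Kalman-gated association with gap
prediction, and DLT triangulation with reprojection gating — and compares
the reconstructed trajectory with the ground truth.
"""

import numpy as np

from visuoswarm.synthetic import SceneSpec, render_image_sequence
from visuoswarm.tracking import TrackerParams, make_camera_ring, track_sequence
from visuoswarm.trajectory import Trajectory

cams = make_camera_ring(3, distance=2.0, image_size=(128, 128), focal_px=180)
n = 100
t = np.arange(n) * 0.02
path = Trajectory(
    np.column_stack([
        0.30 * np.sin(2 * np.pi * 0.6 * t),
        0.22 * np.cos(2 * np.pi * 0.6 * t),
        0.12 * np.sin(4 * np.pi * 0.6 * t),
    ]),
    dt=0.02,
)
scene = SceneSpec(cameras=cams, image_size=(128, 128), blob_radius=1.5,
                  blob_intensity=70.0, background_drift=0.2, noise_sd=2.0,
                  seed=1, blob_absent_frames=12)
seq = render_image_sequence(path, scene)

out = track_sequence(seq.frames, cams, TrackerParams())
present = np.arange(n) >= scene.blob_absent_frames
valid = out.valid & present
err = np.linalg.norm(out.trajectory.values[valid] - path.values[valid], axis=1)
extent = np.linalg.norm(path.values.max(0) - path.values.min(0))

print(f"frames with accepted 3-D points : {valid.sum()} / {present.sum()}")
print(f"3-D RMSE                        : {np.sqrt((err**2).mean()):.4f} "
      f"({100 * np.sqrt((err**2).mean()) / extent:.2f}% of scene extent)")
print(f"mean reprojection error         : "
      f"{np.nanmean(out.reprojection_error):.3f} px (gate 0.5 px)")
# Frames can be dropped when the 0.5 px reprojection gate rejects a noisy
# triangulation; accepted points reconstruct the flight path to well under
# 1% of the traversed volume.
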