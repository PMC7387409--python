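"""Render a synthetic two-photon scene and recover the cells from it.

Builds five slowly moving cells in a 160x160 um field, renders them into a
3-channel (GFP / mCherry / SHG) z-stack with photobleaching and noise, then
runs the preprocessing chain: max projection -> debleach -> registration ->
spot detection. The printed centroid errors show sub-pixel recovery.
"""

import numpy as np

from ivmotility import (
    MotionModel, SceneGeometry, debleach, detect_spots, max_project,
    render_timelapse, rigid_register, simulate_track,
)

geom = SceneGeometry(shape=(160, 160), um_per_px=1.0, periphery_px=40)
tracks = [
    simulate_track(MotionModel("confined_brownian", 2.0, confinement_radius=4.0),
                   20, 0.5, start=(30.0 + 28 * i, 40.0 + 18 * i), seed=i, cell_id=i)
    for i in range(5)
]
stack, truth = render_timelapse(tracks, geom, cell_radius_um=5.0,
                                bleach_rate=0.02, noise=(50.0, 2.0), seed=0)
print(f"stack shape (t, z, c, y, x) = {stack.voxels.shape}")

series = rigid_register(debleach(max_project(stack), "GFP"), reference=0)[0]
detections = detect_spots(series, channel="GFP")

errors = []
for f, dets in enumerate(detections):
    for d in dets:
        true = min(((t.x[f], t.y[f]) for t in tracks),
                   key=lambda p: np.hypot(d.x_um - p[0], d.y_um - p[1]))
        errors.append(np.hypot(d.x_um - true[0], d.y_um - true[1]))

print(f"detections per frame: {[len(d) for d in detections[:6]]} ... (5 cells)")
print(f"mean centroid error: {np.mean(errors):.2f} um "
      f"(sub-pixel at 1 um/px); max: {np.max(errors):.2f} um")
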