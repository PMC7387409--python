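import numpy as np
import pytest

from ivmotility import SceneGeometry, Track


@pytest.fixture
def geometry():
    return SceneGeometry(shape=(128, 128), um_per_px=1.0, um_per_slice=5.0,
                         frame_interval=0.5, periphery_px=32)


def make_track(points, dt=0.5, cell_id=0, region="unassigned"):
    """Track from a list of (x, y) μm positions at a fixed frame interval."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    return Track(cell_id=cell_id, frames=np.arange(n), times=np.arange(n) * dt,
                 x=pts[:, 0], y=pts[:, 1], region=region)


def random_track(rng, n_points=None, scale=20.0, dt=0.5, cell_id=0):
    n = n_points or rng.integers(2, 40)
    pts = np.cumsum(rng.normal(0, scale / 10, (n, 2)), axis=0) + rng.uniform(0, scale, 2)
    return make_track(pts, dt=dt, cell_id=cell_id)


@pytest.fixture
def grid_tracks():
    """Static, well-separated cells on a grid inside a 256 px field."""
    def _make(n=20, n_frames=10, spacing=48.0, jitter_rng=None):
        tracks = []
        per_row = int(np.ceil(np.sqrt(n)))
        for i in range(n):
            x0 = 40.0 + spacing * (i % per_row)
            y0 = 40.0 + spacing * (i // per_row)
            xs = np.full(n_frames, x0)
            ys = np.full(n_frames, y0)
            if jitter_rng is not None:
                xs = xs + np.cumsum(jitter_rng.normal(0, 0.5, n_frames))
                ys = ys + np.cumsum(jitter_rng.normal(0, 0.5, n_frames))
            tracks.append(Track(cell_id=i, frames=np.arange(n_frames),
                                times=np.arange(n_frames) * 0.5, x=xs, y=ys))
        return tracks
    return _make
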