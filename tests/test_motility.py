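"""Motility metrics, elongation and the four-quadrant classifier."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ivmotility import (
    ClassifierThresholds,
    ContourMask,
    Detection,
    MotionModel,
    ProjectedSeries,
    classify_behavior,
    cohort_thresholds,
    elongation_index,
    elongation_series,
    segment_contours,
    simulate_track,
    track_metrics,
    track_plot_coordinates,
)
from ivmotility.motility import DegenerateContourError, TrackMetrics

from conftest import make_track, random_track


# ---------------------------------------------------------------------------
# track_metrics


def test_collinear_track_unit_meandering():
    t = make_track([(i, 0.0) for i in np.linspace(0, 10, 11)], dt=0.5)
    m = track_metrics(t)
    assert m.d_um == 10.0 and m.L_um == 10.0
    assert m.v_um_min == 2.0 and m.mi == 1.0


def test_closed_square_loop_zero_displacement():
    pts = [(0, 0), (10, 0), (10, 10), (0, 10), (0, 0)]
    m = track_metrics(make_track(pts, dt=1.0))
    assert m.d_um == 0.0 and m.L_um == 40.0
    assert m.v_um_min == 0.0 and m.mi == 0.0


def test_right_angle_track_arithmetic():
    m = track_metrics(make_track([(0, 0), (3, 0), (3, 4)], dt=0.5))
    assert m.d_um == pytest.approx(5.0, abs=1e-12)
    assert m.L_um == pytest.approx(7.0, abs=1e-12)
    assert m.v_um_min == pytest.approx(5.0, abs=1e-12)
    assert m.mi == pytest.approx(5.0 / 7.0, abs=1e-12)
    assert m.path_speed_um_min == pytest.approx(7.0, abs=1e-12)


def test_track_metrics_errors():
    t = make_track([(0, 0), (1, 0)])
    t.times = np.zeros(2)
    with pytest.raises(ValueError):
        track_metrics(t)


@settings(derandomize=True, max_examples=30, deadline=None)
@given(st.integers(0, 10_000))
def test_metrics_invariant_under_rigid_motion(seed):
    """v and MI are unchanged by rotation + translation; MI stays in [0, 1]."""
    rng = np.random.default_rng(seed)
    t = random_track(rng, n_points=int(rng.integers(3, 30)))
    m = track_metrics(t)
    assert m.L_um >= m.d_um >= 0 and 0 <= m.mi <= 1
    theta = rng.uniform(0, 2 * np.pi)
    R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    shifted = (t.positions @ R.T) + rng.uniform(-50, 50, 2)
    m2 = track_metrics(make_track(shifted, dt=0.5))
    assert m2.v_um_min == pytest.approx(m.v_um_min, abs=1e-9)
    assert m2.mi == pytest.approx(m.mi, abs=1e-9)


def test_mi_one_iff_collinear_monotone():
    mono = make_track([(x, 2 * x) for x in [0, 1, 3, 7, 9]])
    assert track_metrics(mono).mi == pytest.approx(1.0, abs=1e-9)
    backtrack = make_track([(0, 0), (5, 0), (3, 0)])  # collinear, not monotone
    assert track_metrics(backtrack).mi < 1.0 - 1e-9


def test_regime_separation_on_synthetic_tracks():
    ballistic = [track_metrics(simulate_track(MotionModel("ballistic", 5.0), 61, 0.5,
                                              seed=s)).mi for s in range(20)]
    confined = [track_metrics(simulate_track(
        MotionModel("confined_brownian", 5.0, confinement_radius=10.0), 61, 0.5,
        seed=s)).mi for s in range(20)]
    assert min(ballistic) > 0.99
    assert np.mean([mi < 0.3 for mi in confined]) >= 0.95


# ---------------------------------------------------------------------------
# track_plot_coordinates


def test_track_plot_origin_centred_and_shape_preserving():
    rng = np.random.default_rng(2)
    tracks = [random_track(rng, cell_id=i) for i in range(50)]
    table = track_plot_coordinates(tracks)
    for t in tracks:
        sub = table[table["cell_id"] == t.cell_id]
        assert sub.iloc[0]["x_um"] == 0.0 and sub.iloc[0]["y_um"] == 0.0
        shifted = sub[["x_um", "y_um"]].to_numpy()
        orig = t.positions
        d_orig = np.linalg.norm(orig[:, None] - orig[None, :], axis=-1)
        d_new = np.linalg.norm(shifted[:, None] - shifted[None, :], axis=-1)
        assert np.allclose(d_orig, d_new, atol=1e-9)


def test_track_plot_already_at_origin_unchanged():
    t = make_track([(0, 0), (1, 2), (3, 1)])
    table = track_plot_coordinates([t])
    assert np.allclose(table[["x_um", "y_um"]].to_numpy(), t.positions)


# ---------------------------------------------------------------------------
# elongation


def _mask(major, minor):
    return ContourMask(frame=0, cell_id=0, mask=np.ones((3, 3), bool),
                       offset=(0, 0), major_um=major, minor_um=minor)


def test_elongation_index_ratio_and_degenerate():
    assert elongation_index(_mask(10.0, 5.0)) == 2.0
    with pytest.raises(ValueError):
        _mask(10.0, 0.0)


def test_elongation_rotation_invariance():
    """A 2:1 ellipse rasterized at 0° and 30° gives the same E within 2%."""
    yy, xx = np.mgrid[0:160, 0:160]
    Es = []
    for theta in (0.0, np.pi / 6):
        c, s = np.cos(theta), np.sin(theta)
        u = c * (xx - 80) + s * (yy - 80)
        v = -s * (xx - 80) + c * (yy - 80)
        ell = (((u / 16.0) ** 2 + (v / 8.0) ** 2) <= 1).astype(float) * 100
        series = ProjectedSeries(frames=ell[None, None], channels=("GFP",))
        masks, fails = segment_contours(series, [Detection(0, 80, 80, 100, 1)],
                                        "GFP", 30.0)
        assert not fails
        Es.append(elongation_index(masks[0]))
    assert Es[0] == pytest.approx(Es[1], rel=0.02)
    assert Es[0] == pytest.approx(2.0, rel=0.05)


def test_elongation_series_excludes_degenerate_frames():
    good = [_mask(8.0, 4.0), _mask(6.0, 6.0)]
    for i, g in enumerate(good):
        g.frame = i
    series = elongation_series(good, cell_id=1)
    assert series.mean == pytest.approx(1.5)
    assert series.sd == pytest.approx(0.5)
    assert series.n_excluded == 0
    assert np.all(series.values >= 1.0)


# ---------------------------------------------------------------------------
# classification


def test_classify_control_cohort_means_to_q1():
    thr = ClassifierThresholds(2.16, 0.45)
    m = TrackMetrics(cell_id=0, d_um=0, L_um=0, T_min=1, v_um_min=4.60,
                     mi=0.41, path_speed_um_min=0)
    assert classify_behavior(m, thr) == "Q1"


def test_classify_threshold_boundary_counts_high():
    thr = ClassifierThresholds(2.16, 0.45)
    m = TrackMetrics(cell_id=0, d_um=0, L_um=0, T_min=1, v_um_min=2.16,
                     mi=0.45, path_speed_um_min=0)
    assert classify_behavior(m, thr) == "Q2"


def test_classify_grid_matches_bruteforce_oracle():
    thr = ClassifierThresholds(2.16, 0.45)
    vs = np.linspace(0.1, 4.5, 10)
    mis = np.linspace(0.05, 0.95, 10)
    for v in vs:
        for mi in mis:
            m = TrackMetrics(cell_id=0, d_um=0, L_um=0, T_min=1, v_um_min=v,
                             mi=mi, path_speed_um_min=0)
            # brute-force nested conditional oracle
            if v >= 2.16:
                expected = "Q2" if mi >= 0.45 else "Q1"
            else:
                expected = "Q4" if mi >= 0.45 else "Q3"
            assert classify_behavior(m, thr) == expected


def test_every_track_in_exactly_one_quadrant():
    rng = np.random.default_rng(3)
    thr = ClassifierThresholds(2.0, 0.5)
    quads = [classify_behavior(
        TrackMetrics(cell_id=i, d_um=0, L_um=0, T_min=1,
                     v_um_min=float(rng.uniform(0, 4)),
                     mi=float(rng.uniform(0, 1)), path_speed_um_min=0), thr)
        for i in range(200)]
    assert all(q in ("Q1", "Q2", "Q3", "Q4") for q in quads)
    assert len(quads) == 200


# ---------------------------------------------------------------------------
# cohort thresholds


def test_cohort_thresholds_mean_of_tracks():
    ms = [TrackMetrics(cell_id=0, d_um=0, L_um=0, T_min=1, v_um_min=1.0,
                       mi=0.2, path_speed_um_min=0),
          TrackMetrics(cell_id=1, d_um=0, L_um=0, T_min=1, v_um_min=3.0,
                       mi=0.6, path_speed_um_min=0)]
    thr = cohort_thresholds(ms)
    assert thr.v_star == 2.0 and thr.mi_star == pytest.approx(0.4)
    single = cohort_thresholds(ms[:1])
    assert single.v_star == 1.0 and single.mi_star == pytest.approx(0.2)
    with pytest.raises(ValueError):
        cohort_thresholds([])


def test_cohort_thresholds_match_bruteforce_table():
    rng = np.random.default_rng(4)
    tracks = [random_track(rng, cell_id=i) for i in range(60)]
    ms = [track_metrics(t) for t in tracks]
    thr = cohort_thresholds(ms)
    assert thr.v_star == pytest.approx(np.mean([m.v_um_min for m in ms]), abs=1e-12)
    assert thr.mi_star == pytest.approx(np.mean([m.mi for m in ms]), abs=1e-12)
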