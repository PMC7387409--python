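"""Synthetic-data generators: determinism, hard constraints, calibration."""

import numpy as np
import pytest

from ivmotility import (
    ArmSpec,
    CohortSpec,
    MotionModel,
    SceneGeometry,
    draw_depth_positions,
    generate_spatial_mask,
    generate_vessel_fields,
    render_timelapse,
    simulate_cohort,
    simulate_track,
    max_project,
    track_metrics,
)
from ivmotility.synthgen import PlacementError

from conftest import make_track


# ---------------------------------------------------------------------------
# simulate_track


def test_ballistic_steps_constant_and_collinear():
    t = simulate_track(MotionModel("ballistic", 5.0), 61, 0.5, seed=0)
    assert t.n_points == 61
    steps = np.diff(t.positions, axis=0)
    assert np.allclose(np.linalg.norm(steps, axis=1), 2.5, atol=1e-9)
    # collinear: all cross products with the first step vanish
    cross = steps[:, 0] * steps[0, 1] - steps[:, 1] * steps[0, 0]
    assert np.allclose(cross, 0.0, atol=1e-9)


@pytest.mark.parametrize("seed", range(10))
def test_confined_never_leaves_radius(seed):
    model = MotionModel("confined_brownian", 5.0, confinement_radius=10.0)
    t = simulate_track(model, 61, 0.5, start=(3.0, -7.0), seed=seed)
    r = np.hypot(t.x - 3.0, t.y + 7.0)
    assert r.max() <= 10.0 + 1e-9


@pytest.mark.parametrize("seed", range(5))
def test_levy_steps_respect_truncation(seed):
    model = MotionModel("levy", 5.0, levy_exponent=2.0, truncation_step=8.0)
    t = simulate_track(model, 200, 0.5, seed=seed)
    steps = np.linalg.norm(np.diff(t.positions, axis=0), axis=1)
    assert steps.max() <= 8.0 + 1e-9


def test_levy_tail_heavier_than_brownian_by_p99_median():
    """Tail-weight ordering from the simulator matches an independent
    re-sampling of the two step distributions (truncated Pareto vs folded
    normal), compared by the 99th-percentile / median statistic."""
    # independent oracle: re-sample the step-length laws directly
    rng = np.random.default_rng(123)
    u = rng.uniform(size=200_000)
    lo, hi, alpha = 0.3 * 2.5, 40.0, 2.0
    pareto = (lo ** (1 - alpha) + u * (hi ** (1 - alpha) - lo ** (1 - alpha))) ** (1 / (1 - alpha))
    gauss = np.linalg.norm(rng.normal(0, 2.5 / np.sqrt(2), (200_000, 2)), axis=1)
    oracle_levy = np.percentile(pareto, 99) / np.median(pareto)
    oracle_brown = np.percentile(gauss, 99) / np.median(gauss)
    assert oracle_levy > oracle_brown

    def pooled_steps(model, n_seeds=100):
        out = []
        for s in range(n_seeds):
            t = simulate_track(model, 200, 0.5, seed=s)
            out.append(np.linalg.norm(np.diff(t.positions, axis=0), axis=1))
        return np.concatenate(out)

    levy_steps = pooled_steps(MotionModel("levy", 5.0, levy_exponent=2.0,
                                          truncation_step=40.0))
    brown_steps = pooled_steps(MotionModel("confined_brownian", 5.0,
                                           confinement_radius=1e6))
    sim_levy = np.percentile(levy_steps, 99) / np.median(levy_steps)
    sim_brown = np.percentile(brown_steps, 99) / np.median(brown_steps)
    assert sim_levy > sim_brown


def test_stationary_probing_tiny_displacement():
    t = simulate_track(MotionModel("stationary_probing", 0.0), 61, 0.5, seed=3)
    assert track_metrics(t).d_um < 5.0
    assert np.hypot(t.x - t.x[0], t.y - t.y[0]).max() < 6.0


@pytest.mark.parametrize("kind", ["ballistic", "confined_brownian", "levy",
                                  "stationary_probing"])
def test_track_determinism(kind):
    model = MotionModel(kind, 3.0)
    a = simulate_track(model, 50, 0.5, seed=7)
    b = simulate_track(model, 50, 0.5, seed=7)
    assert np.array_equal(a.positions, b.positions)


def test_track_input_errors():
    with pytest.raises(ValueError):
        simulate_track(MotionModel("ballistic", 5.0), 1, 0.5)
    with pytest.raises(ValueError):
        simulate_track(MotionModel("ballistic", 5.0), 10, 0.0)
    with pytest.raises(ValueError):
        MotionModel("ballistic", np.nan)
    with pytest.raises(ValueError):
        MotionModel("levy", 1.0, levy_exponent=0.9)


# ---------------------------------------------------------------------------
# simulate_cohort


def _mixture():
    models = (MotionModel("ballistic", 4.6),
              MotionModel("levy", 4.6, persistence=0.6, truncation_step=8.0),
              MotionModel("confined_brownian", 4.6, confinement_radius=10.0),
              MotionModel("stationary_probing", 4.6))
    return models, (0.25, 0.35, 0.25, 0.15)


def _cohort_spec(multipliers, n_mice=4, cells=25, seed=0):
    models, weights = _mixture()
    arms = tuple(ArmSpec(label=lab, n_mice=n_mice, cells_per_mouse=cells,
                         models=models, weights=weights, speed_multiplier=m)
                 for lab, m in multipliers)
    return CohortSpec(arms=arms, geometry=SceneGeometry(), n_frames=61, seed=seed)


def test_cohort_velocity_ordering_matches_multipliers():
    """Arm-mean velocities recomputed from ground-truth coordinates follow
    the configured speed multipliers: control > combo > mono."""
    spec = _cohort_spec([("control", 1.0), ("mono", 0.4), ("combo", 0.5)])
    tracksets, gt = simulate_cohort(spec)
    means = {arm: np.mean([track_metrics(t).v_um_min for ts in lst for t in ts])
             for arm, lst in tracksets.items()}
    assert means["control"] > means["combo"] > means["mono"]
    # ground truth covers every generated track
    ids = {t.cell_id for ts in sum(tracksets.values(), []) for t in ts}
    assert set(gt.model_kinds) == ids == set(gt.region)


def test_cohort_single_cell():
    spec = _cohort_spec([("only", 1.0)], n_mice=1, cells=1)
    tracksets, gt = simulate_cohort(spec)
    assert len(tracksets["only"]) == 1 and len(tracksets["only"][0]) == 1
    assert len(gt.tracks) == 1


def test_cohort_determinism():
    spec = _cohort_spec([("a", 1.0), ("b", 0.5)], n_mice=2, cells=5, seed=42)
    (ts1, gt1), (ts2, gt2) = simulate_cohort(spec), simulate_cohort(spec)
    for arm in ts1:
        for m1, m2 in zip(ts1[arm], ts2[arm]):
            for t1, t2 in zip(m1.tracks, m2.tracks):
                assert np.array_equal(t1.positions, t2.positions)
    assert gt1.model_kinds == gt2.model_kinds


def test_cohort_empty_arms_error():
    with pytest.raises(ValueError):
        CohortSpec(arms=())


def test_cohort_tracks_stay_in_field():
    spec = _cohort_spec([("fast", 1.5)], n_mice=2, cells=10)
    tracksets, _ = simulate_cohort(spec)
    w, h = spec.geometry.size_um
    for ts in tracksets["fast"]:
        for t in ts:
            assert t.x.min() >= 0 and t.x.max() < w
            assert t.y.min() >= 0 and t.y.max() < h


# ---------------------------------------------------------------------------
# render_timelapse


def test_render_zero_cells_gfp_blank(geometry):
    stack, _ = render_timelapse([], geometry, noise=(0, 0), seed=0)
    assert np.all(stack.voxels[:, :, 0] == 0)


def test_render_static_cell_argmax_at_centroid(geometry):
    t = make_track([(60.0, 40.0)] * 5)
    stack, _ = render_timelapse([t], geometry, noise=(0, 0), seed=0)
    series = max_project(stack)
    for f in range(5):
        row, col = np.unravel_index(np.argmax(series.frames[f, 0]),
                                    series.frames[f, 0].shape)
        assert abs(col - 60) <= 1 and abs(row - 40) <= 1


def test_render_bleach_matches_closed_form(geometry):
    t = make_track([(60.0, 40.0)] * 60)
    stack, _ = render_timelapse([t], geometry, bleach_rate=0.02, noise=(0, 0), seed=0)
    means = max_project(stack).frames[:, 0].mean(axis=(1, 2))
    expected = means[0] * (1 - 0.02) ** np.arange(60)
    assert np.max(np.abs(means / expected - 1)) < 1e-6


def test_render_cell_outside_field_error(geometry):
    t = make_track([(500.0, 40.0)] * 3)
    with pytest.raises(ValueError):
        render_timelapse([t], geometry, seed=0)


def test_render_channel_geometry(geometry):
    stack, _ = render_timelapse([], geometry, noise=(0, 0), seed=0)
    proj = max_project(stack)
    mcherry, shg = proj.frames[0, 1], proj.frames[0, 2]
    assert np.all(mcherry[:, : geometry.periphery_px] == 0)
    assert np.all(mcherry[:, geometry.periphery_px:] > 0)
    assert shg[:, : geometry.periphery_px].max() > 0
    assert np.all(shg[:, geometry.periphery_px:] == 0)


# ---------------------------------------------------------------------------
# spatial masks and vessel fields


def test_spatial_mask_empty():
    mask, pos = generate_spatial_mask(0, field=(64, 64), seed=0)
    assert not mask.any() and pos.shape == (0, 2)


def test_spatial_mask_component_count():
    from skimage.measure import label

    mask, pos = generate_spatial_mask(50, field=(512, 512), seed=1)
    assert label(mask).max() == 50 and len(pos) == 50


def test_spatial_mask_placement_error():
    with pytest.raises(PlacementError):
        generate_spatial_mask(500, field=(32, 32), seed=0, max_retries=20)


def _moment_kurtosis(x):
    x = np.asarray(x, float)
    m = x.mean()
    return np.mean((x - m) ** 4) / np.mean((x - m) ** 2) ** 2


def test_beta_core_concentrated_kurtosis_exceeds_uniform():
    """A core-concentrated beta depth family yields higher Pearson kurtosis
    than uniform infiltration (moment formula applied to true positions)."""
    xu = draw_depth_positions(50_000, ("uniform",), 1000.0, seed=2)
    xb = draw_depth_positions(50_000, ("beta", 5, 1.5), 1000.0, seed=2)
    assert _moment_kurtosis(xb) > _moment_kurtosis(xu)
    assert abs(_moment_kurtosis(xu) - 1.8) < 0.1


def test_vessel_fields_monotone_rho_one():
    from ivmotility import vessel_cell_correlation

    df = generate_vessel_fields(50, 1.0, seed=0)
    rho, _ = vessel_cell_correlation(df)
    assert rho == pytest.approx(1.0, abs=1e-12)


def test_vessel_fields_null_rho_near_zero():
    from ivmotility import vessel_cell_correlation

    df = generate_vessel_fields(1000, 0.0, seed=3)
    rho, _ = vessel_cell_correlation(df)
    assert abs(rho) < 0.1


def test_vessel_fields_minimum_and_errors():
    df = generate_vessel_fields(3, 0.5, seed=0)
    assert len(df) == 3
    assert (df["vessel_count"] >= 0).all() and (df["cell_count"] >= 0).all()
    with pytest.raises(ValueError):
        generate_vessel_fields(2, 0.5)
    with pytest.raises(ValueError):
        generate_vessel_fields(10, 1.5)
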