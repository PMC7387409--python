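"""Cohort-level statistics and end-to-end pipeline orchestration.

Statistical conventions: results are reported as mean ± SEM. Two
independent groups are compared with an unpaired t-test when both pass a
D'Agostino–Pearson normality gate (p > 0.05), otherwise with the
Mann–Whitney rank test; groups smaller than 8 skip the gate (its statistic
is unreliable there) and default to the rank test. Three or more groups
use Kruskal–Wallis followed, when significant, by Dunn's tie-corrected
pairwise z-tests with Bonferroni adjustment. The Mann–Whitney path uses
the asymptotic normal approximation with mid-ranks and no continuity
correction, so exactly tied identical groups give p = 1.

Tumor volume from caliper axes uses the ellipsoid estimate
V = (π/6)·a·b·c (mm³).
"""

from __future__ import annotations

import itertools
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import synthgen
from .imgproc import debleach, detect_spots, max_project, rigid_register
from .motility import metrics_table, track_plot_coordinates
from .spatial import region_counts, spatial_histogram
from .tracking import assign_region, filter_short_tracks, link_detections

__all__ = [
    "StatResult",
    "PipelineError",
    "PipelineResult",
    "ellipsoid_volume",
    "compare_two_groups",
    "compare_k_groups",
    "dunn_test",
    "demo_config",
    "run_pipeline",
]

NORMALITY_MIN_N = 8


def ellipsoid_volume(a: float, b: float, c: float) -> float:
    """Tumor volume (mm³) from three orthogonal caliper axes: (π/6)·a·b·c."""
    for v in (a, b, c):
        if not np.isfinite(v) or v < 0:
            raise ValueError("axes must be finite and >= 0")
    lo, mid, hi = sorted((a, b, c))  # fixed multiply order: exactly symmetric
    return float(np.pi / 6 * lo * mid * hi)


@dataclass
class StatResult:
    """Outcome of a group comparison, including which test path fired."""

    test: str
    groups: tuple[int, ...]          # group sizes
    statistic: float
    p_value: float
    normality: dict[str, float | None] | None = None
    gate: str | None = None          # "t-test", "rank", "rank (small n)"
    posthoc: pd.DataFrame | None = None
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError("p-value out of [0, 1]")


def _mannwhitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method="asymptotic", use_continuity=False)
    return float(res.statistic), float(res.pvalue)


def compare_two_groups(x, y, alpha: float = 0.05) -> StatResult:
    """Compare two independent groups with a normality-gated test choice."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("each group needs at least 3 values")
    normality: dict[str, float | None] = {"x": None, "y": None}
    if min(len(x), len(y)) >= NORMALITY_MIN_N:
        normality["x"] = float(stats.normaltest(x).pvalue)
        normality["y"] = float(stats.normaltest(y).pvalue)
        both_normal = normality["x"] > alpha and normality["y"] > alpha
        if both_normal:
            t, p = stats.ttest_ind(x, y, equal_var=True)
            return StatResult(test="unpaired t-test", groups=(len(x), len(y)),
                              statistic=float(t), p_value=float(p),
                              normality=normality, gate="t-test", alpha=alpha)
        gate = "rank"
    else:
        gate = "rank (small n)"
    u, p = _mannwhitney(x, y)
    return StatResult(test="Mann-Whitney", groups=(len(x), len(y)),
                      statistic=u, p_value=p, normality=normality,
                      gate=gate, alpha=alpha)


def dunn_test(groups: list[np.ndarray], labels: list[str] | None = None,
              p_adjust: str = "bonferroni") -> pd.DataFrame:
    """Dunn's post-hoc pairwise z-tests on pooled mid-ranks, tie-corrected.

    For groups i, j: z = (R̄_i − R̄_j) / sqrt((N(N+1)/12 − T)·(1/n_i + 1/n_j))
    with tie correction T = Σ(t³ − t) / (12(N − 1)). Two-sided p-values are
    Bonferroni-adjusted over the k(k−1)/2 comparisons by default.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if labels is None:
        labels = [f"g{i}" for i in range(len(groups))]
    pooled = np.concatenate(groups)
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    sizes = [len(g) for g in groups]
    mean_ranks = []
    start = 0
    for n in sizes:
        mean_ranks.append(ranks[start:start + n].mean())
        start += n
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12 - tie_term
    m = len(groups) * (len(groups) - 1) // 2
    rows = []
    for i, j in itertools.combinations(range(len(groups)), 2):
        se = np.sqrt(var_base * (1 / sizes[i] + 1 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p = 2 * stats.norm.sf(abs(z))
        p_adj = min(1.0, p * m) if p_adjust == "bonferroni" else p
        rows.append({"group_i": labels[i], "group_j": labels[j], "z": z,
                     "p_unadjusted": p, "p_adjusted": p_adj})
    return pd.DataFrame(rows)


def compare_k_groups(groups, labels: list[str] | None = None,
                     alpha: float = 0.05) -> StatResult:
    """Kruskal–Wallis over k ≥ 3 groups; Dunn post hoc when significant."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 3:
        raise ValueError("need at least 3 groups (use compare_two_groups for 2)")
    if any(len(g) < 3 for g in groups):
        raise ValueError("each group needs at least 3 values")
    h, p = stats.kruskal(*groups)
    posthoc = dunn_test(groups, labels) if p < alpha else None
    return StatResult(test="Kruskal-Wallis", groups=tuple(len(g) for g in groups),
                      statistic=float(h), p_value=float(p),
                      posthoc=posthoc, alpha=alpha)


# ---------------------------------------------------------------------------
# end-to-end pipeline


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineResult:
    """Tables and summaries produced by one full pipeline run."""

    metrics: pd.DataFrame
    thresholds: dict
    arm_stats: dict
    spatial: dict
    manifest: dict
    out_dir: Path | None = None


def demo_config(seed: int = 0) -> dict:
    """Default three-arm synthetic study configuration.

    Emulates the design of an immune-checkpoint-inhibitor imaging cohort:
    a fast vehicle-control arm and two slower, more numerous treated arms
    (anti-PD-L1 monotherapy and combination therapy), imaged at 0.5-minute
    intervals. All sizes are desk-scale.
    """
    return {
        "seed": int(seed),
        "geometry": {"shape": [256, 256], "um_per_px": 1.0, "um_per_slice": 5.0,
                     "frame_interval": 0.5, "periphery_px": 64},
        "n_frames": 41,
        "base_speed": 4.6,
        "mixture": {"ballistic": 0.25, "levy": 0.35,
                    "confined_brownian": 0.25, "stationary_probing": 0.15},
        "arms": [
            {"label": "control", "n_mice": 3, "cells_per_mouse": 8,
             "speed_multiplier": 1.0},
            {"label": "anti-PD-L1", "n_mice": 3, "cells_per_mouse": 12,
             "speed_multiplier": 0.38},
            {"label": "combo", "n_mice": 3, "cells_per_mouse": 12,
             "speed_multiplier": 0.47},
        ],
        "render": {"cell_radius_um": 5.0, "bleach_rate": 0.01, "n_z": 3,
                   "noise": [50.0, 2.0], "drift_px_per_frame": [0.0, 0.0]},
        "detect": {"channel": "GFP", "smooth_sigma_um": 2.5,
                   "threshold": "otsu", "min_area_px": None},
        "track": {"max_step_um": 10.0, "max_gap": 1, "min_timepoints": 5},
        "thresholds": "auto",
        "spatial": {"bin_um": 25.0},
    }


def _build_cohort_spec(cfg: dict) -> synthgen.CohortSpec:
    g = cfg["geometry"]
    geom = synthgen.SceneGeometry(shape=tuple(g["shape"]), um_per_px=g["um_per_px"],
                                  um_per_slice=g["um_per_slice"],
                                  frame_interval=g["frame_interval"],
                                  periphery_px=g["periphery_px"])
    base = cfg["base_speed"]
    models, weights = [], []
    for kind, w in cfg["mixture"].items():
        models.append(synthgen.MotionModel(
            kind=kind, speed_scale=base, persistence=0.6 if kind == "levy" else 0.0,
            levy_exponent=2.0, confinement_radius=10.0, truncation_step=8.0))
        weights.append(w)
    arms = tuple(
        synthgen.ArmSpec(label=a["label"], n_mice=a["n_mice"],
                         cells_per_mouse=a["cells_per_mouse"],
                         models=tuple(models), weights=tuple(weights),
                         speed_multiplier=a["speed_multiplier"])
        for a in cfg["arms"]
    )
    return synthgen.CohortSpec(arms=arms, geometry=geom,
                               n_frames=cfg["n_frames"], seed=cfg["seed"])


def run_pipeline(config: dict | None = None, out_dir: str | Path | None = None,
                 write_figures: bool = True) -> PipelineResult:
    """Run the full synthetic study: simulate → render/preprocess → detect →
    track → metrics/classify → spatial + cohort statistics.

    Every parameter and seed is recorded in a manifest; a failure in any
    stage raises :class:`PipelineError` tagged with the stage name (and, when
    an output directory is given, leaves a partial manifest on disk).
    """
    cfg = config or demo_config()
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": cfg, "stages": [], "started": time.strftime("%Y-%m-%d %H:%M:%S")}

    def _stage(name: str):
        manifest["stages"].append(name)
        if out is not None:
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    try:
        stage = "simulate"
        spec = _build_cohort_spec(cfg)
        tracksets_by_arm, gt = synthgen.simulate_cohort(spec)
        _stage(stage)

        stage = "preprocess"
        rcfg = cfg["render"]
        render_ss = np.random.SeedSequence([cfg["seed"], 1])
        geom = spec.geometry
        drift_rate = np.asarray(rcfg["drift_px_per_frame"], dtype=float)
        drift = np.arange(cfg["n_frames"])[:, None] * drift_rate[None, :]
        processed = []  # (arm, mouse, registered ProjectedSeries)
        mouse_list = [(arm, ts) for arm, lst in tracksets_by_arm.items() for ts in lst]
        for (arm, ts), child in zip(mouse_list, render_ss.spawn(len(mouse_list))):
            stack, _ = synthgen.render_timelapse(
                ts, geom, cell_radius_um=rcfg["cell_radius_um"],
                bleach_rate=rcfg["bleach_rate"], drift=drift,
                noise=tuple(rcfg["noise"]), n_z=rcfg["n_z"],
                seed=np.random.default_rng(child))
            series = max_project(stack)
            series = debleach(series, "GFP")
            series, _shifts = rigid_register(series, reference=0)
            processed.append((arm, ts.mouse, series))
        _stage(stage)

        stage = "detect"
        dcfg = cfg["detect"]
        detections = [
            (arm, mouse, detect_spots(series, channel=dcfg["channel"],
                                      smooth_sigma_um=dcfg["smooth_sigma_um"],
                                      threshold=dcfg["threshold"],
                                      min_area_px=dcfg["min_area_px"]))
            for arm, mouse, series in processed
        ]
        _stage(stage)

        stage = "track"
        tcfg = cfg["track"]
        peri, core = geom.periphery_mask(), geom.core_mask()
        tracked = []
        for arm, mouse, dets in detections:
            ts = link_detections(dets, max_step_um=tcfg["max_step_um"],
                                 max_gap=tcfg["max_gap"],
                                 frame_interval_min=geom.frame_interval,
                                 mouse=mouse, arm=arm)
            ts = filter_short_tracks(ts, min_timepoints=tcfg["min_timepoints"])
            ts = assign_region(ts, peri, core, um_per_px=geom.um_per_px)
            tracked.append(ts)
        _stage(stage)

        stage = "metrics"
        thr_cfg = cfg["thresholds"]
        thresholds = None
        if thr_cfg != "auto":
            from .motility import ClassifierThresholds
            thresholds = ClassifierThresholds(*thr_cfg)
        metrics, thresholds = metrics_table(tracked, thresholds=thresholds)
        _stage(stage)

        stage = "spatial_stats"
        # final-frame positions of filtered tracks stand in for an IF field
        pos = np.array([[t.x[-1], t.y[-1]] for ts in tracked for t in ts.tracks])
        pos = pos.reshape(-1, 2)
        hist = spatial_histogram(pos, axis="x", bin_um=cfg["spatial"]["bin_um"],
                                 extent=(0.0, geom.size_um[0]))
        counts = region_counts(pos, peri, core, um_per_px=geom.um_per_px)
        arm_labels = [a["label"] for a in cfg["arms"]]
        groups = [metrics.loc[metrics["arm"] == a, "v_um_min"].to_numpy()
                  for a in arm_labels]
        arm_means = {a: float(np.mean(g)) if len(g) else np.nan
                     for a, g in zip(arm_labels, groups)}
        arm_sems = {a: float(stats.sem(g)) if len(g) > 1 else np.nan
                    for a, g in zip(arm_labels, groups)}
        if len(groups) >= 3 and all(len(g) >= 3 for g in groups):
            kw = compare_k_groups(groups, labels=arm_labels)
            kw_summary = {"test": kw.test, "H": kw.statistic, "p": kw.p_value,
                          "posthoc": (kw.posthoc.to_dict("records")
                                      if kw.posthoc is not None else None)}
        else:
            kw_summary = None
        quad_counts = (metrics.groupby(["arm", "quadrant"]).size()
                       .unstack(fill_value=0).to_dict("index"))
        arm_stats = {
            "velocity_mean_um_min": arm_means,
            "velocity_sem_um_min": arm_sems,
            "kruskal_wallis": kw_summary,
            "quadrant_counts": quad_counts,
            "n_tracks": {a: int(len(g)) for a, g in zip(arm_labels, groups)},
        }
        spatial_summary = {
            "kurtosis": hist.kurtosis,
            "kurtosis_excess": hist.kurtosis_excess,
            "n_cells": hist.n_cells,
            "region_counts": {"peritumoral": counts.peritumoral,
                              "intratumoral": counts.intratumoral,
                              "unassigned": counts.unassigned},
        }
        _stage(stage)
    except Exception as exc:  # noqa: BLE001 - re-tagged with the failing stage
        raise PipelineError(stage, exc) from exc

    manifest["thresholds"] = {"v_star": thresholds.v_star, "mi_star": thresholds.mi_star}
    manifest["n_tracks_total"] = int(len(metrics))
    result = PipelineResult(metrics=metrics,
                            thresholds=asdict(thresholds) if hasattr(thresholds, "__dataclass_fields__")
                            else {"v_star": thresholds.v_star, "mi_star": thresholds.mi_star},
                            arm_stats=arm_stats, spatial=spatial_summary,
                            manifest=manifest, out_dir=out)
    if out is not None:
        metrics.to_csv(out / "metrics.csv", index=False)
        hist.to_frame().to_csv(out / "spatial_histogram.csv", index=False)
        (out / "thresholds.json").write_text(json.dumps(result.thresholds, indent=2))
        (out / "arm_stats.json").write_text(json.dumps(arm_stats, indent=2, default=str))
        (out / "spatial.json").write_text(json.dumps(spatial_summary, indent=2))
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        if write_figures:
            _write_figures(out, metrics, thresholds, tracked)
    return result


def _write_figures(out: Path, metrics: pd.DataFrame, thresholds, tracked) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for arm, sub in metrics.groupby("arm"):
        ax.scatter(sub["mi"], sub["v_um_min"], s=14, label=arm, alpha=0.7)
    ax.axhline(thresholds.v_star, color="k", lw=0.8)
    ax.axvline(thresholds.mi_star, color="k", lw=0.8)
    ax.set_xlabel("meandering index")
    ax.set_ylabel("mean velocity (μm/min)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out / "quadrant_scatter.png", dpi=120)
    plt.close(fig)

    coords = track_plot_coordinates([t for ts in tracked for t in ts.tracks])
    fig, ax = plt.subplots(figsize=(4, 4))
    for _, sub in coords.groupby("cell_id"):
        ax.plot(sub["x_um"], sub["y_um"], lw=0.7, alpha=0.7)
    ax.set_xlabel("Δx (μm)")
    ax.set_ylabel("Δy (μm)")
    ax.set_aspect("equal")
    fig.tight_layout()
    fig.savefig(out / "track_plots.png", dpi=120)
    plt.close(fig)
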