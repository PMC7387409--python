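"""Per-track motility metrics, elongation, and behavioral classification.

Definitions (all in the projected xy plane, μm and minutes):

* displacement ``d`` — straight-line distance from the track origin to its
  terminus;
* path length ``L`` — sum of consecutive step lengths;
* mean velocity ``v = d / T`` with ``T`` the track duration. Note this is
  the displacement-based convention, not the mean step speed; the
  conventional path speed ``L / T`` is exported alongside as a clearly
  labelled supplementary column;
* meandering index ``MI = d / L`` in [0, 1]; 1 is a perfectly straight,
  monotone track, values near 0 indicate confined or looping motion. When
  ``L = 0`` (no movement at all) MI is defined as 0;
* elongation index ``E`` — fitted-ellipse major/minor axis ratio of a cell
  contour, ≥ 1; its temporal standard deviation summarises morpho-dynamics.

Behavioral quadrants split the (v, MI) plane at cohort-level thresholds
(v*, MI*): Q1 fast/low-MI (migrating, returning toward origin), Q2
fast/high-MI (directional, sustained), Q3 slow/low-MI (low motility),
Q4 slow/high-MI (non-sustained motility). Values exactly at a threshold
count as "high" (>=).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .imgproc import ContourMask
from .tracking import Track, TrackSet

__all__ = [
    "TrackMetrics",
    "ElongationSeries",
    "ClassifierThresholds",
    "DegenerateContourError",
    "track_metrics",
    "track_plot_coordinates",
    "elongation_index",
    "elongation_series",
    "classify_behavior",
    "cohort_thresholds",
    "metrics_table",
    "QUADRANTS",
]

QUADRANTS = ("Q1", "Q2", "Q3", "Q4")


class DegenerateContourError(ValueError):
    """Contour too degenerate (line/point) for an elongation estimate."""


@dataclass
class TrackMetrics:
    """Summary metrics of one track."""

    cell_id: int
    d_um: float
    L_um: float
    T_min: float
    v_um_min: float            # displacement-based mean velocity d / T
    mi: float                  # meandering index d / L
    path_speed_um_min: float   # supplementary conventional speed L / T
    region: str = "unassigned"
    quadrant: str | None = None


@dataclass
class ElongationSeries:
    """Per-frame elongation of one cell plus temporal summaries."""

    cell_id: int
    frames: np.ndarray
    values: np.ndarray     # E per frame with a valid contour
    mean: float
    sd: float              # temporal variability (morpho-dynamics), extension
    n_excluded: int = 0


@dataclass(frozen=True)
class ClassifierThresholds:
    """Quadrant split point: cohort-mean velocity and meandering index."""

    v_star: float
    mi_star: float

    def __post_init__(self) -> None:
        if not self.v_star > 0:
            raise ValueError("v_star must be > 0")
        if not 0 < self.mi_star < 1:
            raise ValueError("mi_star must be in (0, 1)")


def track_metrics(track: Track) -> TrackMetrics:
    """Compute d, L, T, v, MI (and supplementary path speed) for one track."""
    if track.n_points < 2:
        raise ValueError("track needs at least 2 points")
    T = float(track.times[-1] - track.times[0])
    if T <= 0:
        raise ValueError("track duration must be positive")
    pos = track.positions
    d = float(np.linalg.norm(pos[-1] - pos[0]))
    steps = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    L = float(steps.sum())
    mi = d / L if L > 0 else 0.0
    return TrackMetrics(cell_id=track.cell_id, d_um=d, L_um=L, T_min=T,
                        v_um_min=d / T, mi=mi, path_speed_um_min=L / T,
                        region=track.region)


def track_plot_coordinates(tracks: TrackSet | list[Track]) -> pd.DataFrame:
    """Origin-centred coordinates for a track ("rose") plot.

    Every track is translated so its first point is (0, 0); pairwise
    inter-point distances — the track shape — are preserved exactly.
    """
    track_list = list(tracks.tracks if isinstance(tracks, TrackSet) else tracks)
    rows = []
    for t in track_list:
        rows.append(pd.DataFrame({
            "cell_id": t.cell_id,
            "frame": t.frames,
            "x_um": t.x - t.x[0],
            "y_um": t.y - t.y[0],
        }))
    if not rows:
        return pd.DataFrame(columns=["cell_id", "frame", "x_um", "y_um"])
    return pd.concat(rows, ignore_index=True)


def elongation_index(mask: ContourMask) -> float:
    """Elongation E = fitted-ellipse major/minor axis ratio (≥ 1)."""
    if mask.minor_um <= 0:
        raise DegenerateContourError("minor axis is zero")
    return mask.major_um / mask.minor_um


def elongation_series(contours: list[ContourMask], cell_id: int = 0) -> ElongationSeries:
    """Assemble the per-frame elongation of one cell; degenerate frames excluded."""
    frames, values = [], []
    n_excluded = 0
    for c in sorted(contours, key=lambda c: c.frame):
        try:
            values.append(elongation_index(c))
            frames.append(c.frame)
        except DegenerateContourError:
            n_excluded += 1
    values = np.asarray(values)
    if values.size == 0:
        return ElongationSeries(cell_id, np.array([], int), values,
                                mean=np.nan, sd=np.nan, n_excluded=n_excluded)
    return ElongationSeries(cell_id, np.asarray(frames), values,
                            mean=float(values.mean()),
                            sd=float(values.std(ddof=0)) if values.size > 1 else 0.0,
                            n_excluded=n_excluded)


def classify_behavior(metrics: TrackMetrics, thresholds: ClassifierThresholds) -> str:
    """Assign the four-quadrant behavioral class of one track.

    Q1: v >= v* and MI < MI*; Q2: v >= v* and MI >= MI*;
    Q3: v < v* and MI < MI*;  Q4: v < v* and MI >= MI*.
    """
    if not (np.isfinite(metrics.v_um_min) and np.isfinite(metrics.mi)):
        raise ValueError("metrics must be finite")
    high_v = metrics.v_um_min >= thresholds.v_star
    high_mi = metrics.mi >= thresholds.mi_star
    if high_v:
        return "Q2" if high_mi else "Q1"
    return "Q4" if high_mi else "Q3"


def cohort_thresholds(all_metrics: list[TrackMetrics]) -> ClassifierThresholds:
    """Thresholds = unweighted means of v and MI over every track of every arm."""
    if not all_metrics:
        raise ValueError("need at least one track to derive thresholds")
    v_star = float(np.mean([m.v_um_min for m in all_metrics]))
    mi_star = float(np.mean([m.mi for m in all_metrics]))
    return ClassifierThresholds(v_star=v_star, mi_star=mi_star)


def metrics_table(
    tracksets: list[TrackSet],
    thresholds: ClassifierThresholds | None = None,
    elongation: dict[int, ElongationSeries] | None = None,
) -> tuple[pd.DataFrame, ClassifierThresholds]:
    """Long-format per-track metric table over one or more track sets.

    When ``thresholds`` is None they are derived from the pooled tracks
    (cohort-mean convention). Returns the table and the thresholds used.
    """
    all_metrics: list[TrackMetrics] = []
    meta: list[tuple[str, str]] = []
    for ts in tracksets:
        for t in ts.tracks:
            all_metrics.append(track_metrics(t))
            meta.append((ts.mouse, ts.arm))
    if thresholds is None:
        thresholds = cohort_thresholds(all_metrics)
    rows = []
    for (mouse, arm), m in zip(meta, all_metrics):
        m.quadrant = classify_behavior(m, thresholds)
        es = elongation.get(m.cell_id) if elongation else None
        rows.append({
            "mouse": mouse, "arm": arm, "cell_id": m.cell_id, "region": m.region,
            "d_um": m.d_um, "L_um": m.L_um, "T_min": m.T_min,
            "v_um_min": m.v_um_min, "mi": m.mi,
            "path_speed_um_min": m.path_speed_um_min,
            "E_mean": es.mean if es else np.nan,
            "E_sd": es.sd if es else np.nan,
            "quadrant": m.quadrant,
        })
    return pd.DataFrame(rows), thresholds
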