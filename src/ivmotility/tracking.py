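"""Track assembly: detection linking, length filtering and region labels.

Linking is deterministic greedy nearest-neighbour with a distance gate,
a pragmatic automated stand-in for interactive frame-by-frame tracking.
Cells that cannot be followed for more than ``min_timepoints`` observations
are excluded before any motility statistic is computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .imgproc import Detection

__all__ = [
    "Track",
    "TrackSet",
    "link_detections",
    "filter_short_tracks",
    "assign_region",
]

PERITUMORAL = "peritumoral"
INTRATUMORAL = "intratumoral"
UNASSIGNED = "unassigned"


@dataclass
class Track:
    """Ordered centroid sequence of one cell (μm / minutes)."""

    cell_id: int
    frames: np.ndarray   # strictly increasing frame indices
    times: np.ndarray    # minutes
    x: np.ndarray        # μm
    y: np.ndarray        # μm
    region: str = UNASSIGNED

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.times = np.asarray(self.times, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        n = len(self.frames)
        if not (len(self.times) == len(self.x) == len(self.y) == n):
            raise ValueError("frames/times/x/y must have equal length")
        if n >= 2 and not np.all(np.diff(self.frames) > 0):
            raise ValueError("frame indices must be strictly increasing")

    @property
    def n_points(self) -> int:
        return len(self.frames)

    @property
    def positions(self) -> np.ndarray:
        """(n, 2) array of (x, y) positions in μm."""
        return np.column_stack([self.x, self.y])


@dataclass
class TrackSet:
    """A collection of tracks from one imaging session."""

    tracks: list[Track]
    mouse: str = "m0"
    arm: str = "none"
    imaging_region: str = "tumor"

    def __post_init__(self) -> None:
        ids = [t.cell_id for t in self.tracks]
        if len(ids) != len(set(ids)):
            raise ValueError("cell ids must be unique within a TrackSet")

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self):
        return iter(self.tracks)


@dataclass
class _OpenTrack:
    track_id: int
    dets: list[Detection] = field(default_factory=list)

    @property
    def last(self) -> Detection:
        return self.dets[-1]


def link_detections(
    detections: list[list[Detection]],
    max_step_um: float = 10.0,
    max_gap: int = 1,
    frame_interval_min: float = 0.5,
    mouse: str = "m0",
    arm: str = "none",
) -> TrackSet:
    """Link per-frame detections into tracks by greedy nearest neighbour.

    Candidate (track, detection) pairs within ``max_step_um`` and with a frame
    gap of at most ``max_gap`` are assigned in order of increasing distance;
    equidistant candidates are broken by lower track id, then lower detection
    index, so linking is fully deterministic. Every detection ends up in
    exactly one (possibly length-1) track; unlinkable detections start new
    tracks.
    """
    if max_step_um <= 0:
        raise ValueError("max_step_um must be > 0")
    open_tracks: list[_OpenTrack] = []
    finished: list[_OpenTrack] = []
    next_id = 0
    for f, frame_dets in enumerate(detections):
        still_open = []
        for ot in open_tracks:
            (still_open if f - ot.last.frame <= max_gap + 1 else finished).append(ot)
        open_tracks = still_open

        pairs = []
        for ot in open_tracks:
            for j, det in enumerate(frame_dets):
                d = float(np.hypot(det.x_um - ot.last.x_um, det.y_um - ot.last.y_um))
                if d <= max_step_um:
                    pairs.append((d, ot.track_id, j, ot))
        pairs.sort(key=lambda p: (p[0], p[1], p[2]))
        used_tracks: set[int] = set()
        used_dets: set[int] = set()
        for d, tid, j, ot in pairs:
            if tid in used_tracks or j in used_dets:
                continue
            ot.dets.append(frame_dets[j])
            used_tracks.add(tid)
            used_dets.add(j)
        for j, det in enumerate(frame_dets):
            if j not in used_dets:
                open_tracks.append(_OpenTrack(next_id, [det]))
                next_id += 1
    finished.extend(open_tracks)
    finished.sort(key=lambda ot: ot.track_id)
    tracks = [
        Track(
            cell_id=ot.track_id,
            frames=[d.frame for d in ot.dets],
            times=[d.frame * frame_interval_min for d in ot.dets],
            x=[d.x_um for d in ot.dets],
            y=[d.y_um for d in ot.dets],
        )
        for ot in finished
    ]
    return TrackSet(tracks=tracks, mouse=mouse, arm=arm)


def filter_short_tracks(trackset: TrackSet, min_timepoints: int = 5) -> TrackSet:
    """Drop tracks observed for ``min_timepoints`` or fewer timepoints.

    The exclusion is strict: with the default of 5, a 5-point track is
    removed and a 6-point track retained. Idempotent.
    """
    if min_timepoints < 2:
        raise ValueError("min_timepoints must be >= 2")
    kept = [t for t in trackset.tracks if t.n_points > min_timepoints]
    return replace(trackset, tracks=kept)


def assign_region(
    trackset: TrackSet,
    periphery_mask: np.ndarray,
    core_mask: np.ndarray,
    um_per_px: float = 1.0,
) -> TrackSet:
    """Label each track peritumoral or intratumoral by majority vote.

    The masks must be disjoint and jointly tile the field. Each track gets
    the label of the compartment containing the majority of its positions;
    ties go to peritumoral (conservative toward the collagen interface).
    Tracks entirely outside both masks stay unassigned.
    """
    periphery_mask = np.asarray(periphery_mask, dtype=bool)
    core_mask = np.asarray(core_mask, dtype=bool)
    if periphery_mask.shape != core_mask.shape:
        raise ValueError("masks must have identical shape")
    if np.any(periphery_mask & core_mask):
        raise ValueError("periphery and core masks must be disjoint")
    h, w = periphery_mask.shape
    out = []
    for t in trackset.tracks:
        rows = np.round(t.y / um_per_px).astype(int)
        cols = np.round(t.x / um_per_px).astype(int)
        inside = (rows >= 0) & (rows < h) & (cols >= 0) & (cols < w)
        n_peri = int(np.count_nonzero(periphery_mask[rows[inside], cols[inside]]))
        n_core = int(np.count_nonzero(core_mask[rows[inside], cols[inside]]))
        if n_peri == 0 and n_core == 0:
            region = UNASSIGNED
        elif n_peri >= n_core:
            region = PERITUMORAL
        else:
            region = INTRATUMORAL
        out.append(replace(t, region=region))
    return replace(trackset, tracks=out)
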