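"""Preprocessing and detection for multi-channel time-lapse stacks.

The pipeline mirrors a standard intravital workflow: maximum-intensity
projection of each z-stack, photobleaching correction on frame means,
rigid (translation-only) drift correction by phase correlation, Gaussian
denoising with intensity thresholding for spot detection, and local
contour segmentation for per-cell morphology.

Coordinate conventions used throughout the package:

* pixel indices are 0-based with the origin at the top-left corner;
* ``x`` increases rightward (columns, toward the tumor core),
  ``y`` increases downward (rows);
* centroids are reported in micrometres via the stack calibration.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from skimage.registration import phase_cross_correlation

__all__ = [
    "Calibration",
    "TimeLapseStack",
    "ProjectedSeries",
    "Detection",
    "ContourMask",
    "max_project",
    "debleach",
    "rigid_register",
    "detect_spots",
    "segment_contours",
    "count_if_cells",
    "count_vessels",
]


@dataclass(frozen=True)
class Calibration:
    """Physical calibration of a stack: μm per pixel/slice, minutes per frame."""

    um_per_px_x: float = 1.0
    um_per_px_y: float = 1.0
    um_per_slice: float = 5.0
    min_per_frame: float = 0.5

    def __post_init__(self) -> None:
        for name in ("um_per_px_x", "um_per_px_y", "um_per_slice", "min_per_frame"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"calibration field {name} must be finite and > 0, got {v}")


@dataclass
class TimeLapseStack:
    """Calibrated multi-channel voxel series indexed (t, z, channel, y, x)."""

    voxels: np.ndarray
    calibration: Calibration = field(default_factory=Calibration)
    channels: tuple[str, ...] = ("GFP", "mCherry", "SHG")

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 5:
            raise ValueError("voxels must be 5-dimensional (t, z, channel, y, x)")
        if any(s < 1 for s in self.voxels.shape):
            raise ValueError("all stack dimensions must be >= 1")
        if len(self.channels) != self.voxels.shape[2]:
            raise ValueError("channel labels must match the channel axis length")
        if np.min(self.voxels) < 0:
            raise ValueError("stack intensities must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.voxels.shape[0]

    def channel_index(self, channel: str) -> int:
        try:
            return self.channels.index(channel)
        except ValueError:
            raise KeyError(f"unknown channel {channel!r}; have {self.channels}") from None


@dataclass
class ProjectedSeries:
    """2D+t multi-channel series, indexed (t, channel, y, x)."""

    frames: np.ndarray
    calibration: Calibration = field(default_factory=Calibration)
    channels: tuple[str, ...] = ("GFP", "mCherry", "SHG")

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 4:
            raise ValueError("frames must be 4-dimensional (t, channel, y, x)")
        if len(self.channels) != self.frames.shape[1]:
            raise ValueError("channel labels must match the channel axis length")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def channel_index(self, channel: str) -> int:
        try:
            return self.channels.index(channel)
        except ValueError:
            raise KeyError(f"unknown channel {channel!r}; have {self.channels}") from None


@dataclass(frozen=True)
class Detection:
    """A single detected cell in one frame (centroid in μm)."""

    frame: int
    x_um: float
    y_um: float
    peak: float
    area_px: int


@dataclass
class ContourMask:
    """Segmented cell region around a detection, with fitted-ellipse axes (μm)."""

    frame: int
    cell_id: int
    mask: np.ndarray          # boolean, local window
    offset: tuple[int, int]   # (row0, col0) of the window in the full frame
    major_um: float
    minor_um: float

    def __post_init__(self) -> None:
        if not (self.major_um >= self.minor_um > 0):
            raise ValueError("fitted ellipse requires major >= minor > 0")


# ---------------------------------------------------------------------------
# projection / debleach / registration


def max_project(stack: TimeLapseStack | ProjectedSeries) -> ProjectedSeries:
    """Maximum-intensity projection over z. Idempotent on projected input."""
    if isinstance(stack, ProjectedSeries):
        return dataclasses.replace(stack, frames=stack.frames.copy())
    return ProjectedSeries(
        frames=stack.voxels.max(axis=1),
        calibration=stack.calibration,
        channels=stack.channels,
    )


def debleach(series: ProjectedSeries, channel: str = "GFP") -> ProjectedSeries:
    """Correct photobleaching by flattening the frame-mean intensity.

    A single exponential ``m_t = A * exp(-k t)`` is fitted to the frame means
    of the given channel by least squares on the log-means; frame ``t`` is then
    rescaled by ``exp(k t)`` so corrected means are flat. The first frame is
    unchanged by construction. Only the named channel is rescaled.
    """
    if series.n_frames < 3:
        raise ValueError("debleach requires at least 3 frames")
    c = series.channel_index(channel)
    means = series.frames[:, c].mean(axis=(1, 2))
    if np.any(means <= 0):
        raise ValueError("debleach fit requires strictly positive frame means")
    t = np.arange(series.n_frames, dtype=float)
    slope, _ = np.polyfit(t, np.log(means), 1)
    factors = np.exp(-slope * t)  # exp(k t) with k = -slope
    out = series.frames.astype(float, copy=True)
    out[:, c] *= factors[:, None, None]
    return dataclasses.replace(series, frames=out)


def rigid_register(
    series: ProjectedSeries,
    reference: int = 0,
    channel: str | None = None,
) -> tuple[ProjectedSeries, np.ndarray]:
    """Translation-only drift correction by integer-pixel phase correlation.

    Shifts are estimated on one channel (default: the per-pixel sum over
    channels) against the reference frame and applied to all channels
    identically. Returns the registered series and the applied per-frame
    shifts as an ``(n_frames, 2)`` array in ``(dx, dy)`` pixel order; the
    reference frame shift is ``(0, 0)``. For a rig drifting by ``+d`` pixels
    the applied shift is ``-d``. Degenerate (constant) frames raise a warning
    and receive zero shift.
    """
    if not (0 <= reference < series.n_frames):
        raise ValueError("reference frame index out of range")
    if channel is None:
        imgs = series.frames.sum(axis=1)
    else:
        imgs = series.frames[:, series.channel_index(channel)]
    ref = imgs[reference]
    ref_flat = np.ptp(ref) == 0
    out = np.empty_like(series.frames, dtype=float)
    shifts = np.zeros((series.n_frames, 2))
    for t in range(series.n_frames):
        if t == reference or ref_flat or np.ptp(imgs[t]) == 0:
            if t != reference and (ref_flat or np.ptp(imgs[t]) == 0):
                warnings.warn(f"frame {t}: degenerate image, registration skipped")
            out[t] = series.frames[t]
            continue
        # classic cross-correlation: robust on smooth, low-texture frames
        (drow, dcol), _, _ = phase_cross_correlation(ref, imgs[t],
                                                     upsample_factor=1,
                                                     normalization=None)
        shifts[t] = (dcol, drow)
        for c in range(series.frames.shape[1]):
            out[t, c] = ndi.shift(series.frames[t, c].astype(float), (drow, dcol),
                                  order=0, mode="constant", cval=0.0)
    return dataclasses.replace(series, frames=out), shifts


# ---------------------------------------------------------------------------
# spot detection


def _default_min_area(cal: Calibration, radius_um: float = 3.0) -> int:
    """Area (px) of a disk of the given radius — the smallest credible cell."""
    return max(1, int(round(np.pi * radius_um**2 / (cal.um_per_px_x * cal.um_per_px_y))))


def _detect_frame(
    img: np.ndarray,
    cal: Calibration,
    frame: int,
    smooth_sigma_um: float,
    threshold: str | float,
    min_area_px: int,
    merge_area_px: int | None = None,
) -> list[Detection]:
    sigma_px = smooth_sigma_um / (0.5 * (cal.um_per_px_x + cal.um_per_px_y))
    sm = ndi.gaussian_filter(np.asarray(img, dtype=float), sigma_px) if sigma_px > 0 \
        else np.asarray(img, dtype=float)
    if np.ptp(sm) == 0:
        return []
    if threshold == "otsu":
        thr = threshold_otsu(sm)
    else:
        thr = float(threshold)
    labels = label(sm > thr)
    dets: list[Detection] = []
    for p in regionprops(labels, intensity_image=sm):
        if p.area < min_area_px:
            continue
        if merge_area_px is not None and p.area > merge_area_px:
            warnings.warn(
                f"frame {frame}: component of {p.area} px exceeds the single-cell "
                f"area bound ({merge_area_px} px); unresolved merge counted once"
            )
        row, col = p.centroid_weighted
        dets.append(Detection(
            frame=frame,
            x_um=float(col * cal.um_per_px_x),
            y_um=float(row * cal.um_per_px_y),
            peak=float(p.intensity_max),
            area_px=int(p.area),
        ))
    return dets


def detect_spots(
    series: ProjectedSeries,
    channel: str = "GFP",
    smooth_sigma_um: float = 2.5,
    threshold: str | float = "otsu",
    min_area_px: int | None = None,
) -> list[list[Detection]]:
    """Gaussian denoise, threshold, and centroid cells in every frame.

    Per frame: Gaussian smoothing (``smooth_sigma_um``, default half a 5 μm
    cell radius), Otsu or absolute thresholding, connected-component
    labelling, removal of components below ``min_area_px`` (default: the area
    of a 3 μm-radius disk), and intensity-weighted centroids converted to μm.
    A blank frame yields an empty list, not an error.
    """
    if smooth_sigma_um < 0:
        raise ValueError("smooth_sigma_um must be >= 0")
    cal = series.calibration
    if min_area_px is None:
        min_area_px = _default_min_area(cal)
    c = series.channel_index(channel)
    return [
        _detect_frame(series.frames[t, c], cal, t, smooth_sigma_um, threshold, min_area_px)
        for t in range(series.n_frames)
    ]


def count_if_cells(
    image: np.ndarray,
    calibration: Calibration | None = None,
    smooth_sigma_um: float = 2.5,
    threshold: str | float = "otsu",
    min_area_px: int | None = None,
    merge_area_px: int | None = None,
) -> tuple[int, np.ndarray]:
    """Count cells in a single 2D immunofluorescence field.

    Same detector as :func:`detect_spots` on one frame. Returns the total
    count and an ``(n, 2)`` array of ``(x, y)`` centroids in μm for spatial
    analysis. Two cells merged closer than the optical resolution are counted
    once; pass ``merge_area_px`` to log a warning for suspiciously large
    components.
    """
    cal = calibration or Calibration()
    if min_area_px is None:
        min_area_px = _default_min_area(cal)
    dets = _detect_frame(np.asarray(image), cal, 0, smooth_sigma_um, threshold,
                         min_area_px, merge_area_px)
    pos = np.array([(d.x_um, d.y_um) for d in dets]).reshape(-1, 2)
    return len(dets), pos


def count_vessels(
    image: np.ndarray,
    threshold: str | float = "otsu",
    min_area_px: int = 20,
) -> int:
    """Count vessel cross-sections (e.g. CD31+) in a 2D field.

    Threshold, label connected components and count those with area at least
    ``min_area_px``. A blank (constant) field counts zero vessels.
    """
    img = np.asarray(image, dtype=float)
    if np.ptp(img) == 0:
        return 0
    thr = threshold_otsu(img) if threshold == "otsu" else float(threshold)
    labels = label(img > thr)
    return int(sum(1 for p in regionprops(labels) if p.area >= min_area_px))


# ---------------------------------------------------------------------------
# contour segmentation


def segment_contours(
    series: ProjectedSeries,
    detections: list[Detection],
    channel: str = "GFP",
    window_um: float = 15.0,
) -> tuple[list[ContourMask], list[dict]]:
    """Segment a cell contour in a local window around each detection.

    The window is thresholded locally (Otsu) and the connected component
    containing the detection centroid is retained; fitted-ellipse axes come
    from the second-order region moments. Regions touching the window border,
    empty windows and degenerate (line/point) regions are recorded as failures
    and excluded from morphology statistics. Returns ``(masks, failures)``
    with exactly one mask or one failure record per detection.
    """
    cal = series.calibration
    c = series.channel_index(channel)
    half = max(2, int(round(window_um / cal.um_per_px_x)))
    masks: list[ContourMask] = []
    failures: list[dict] = []
    for i, det in enumerate(detections):
        img = series.frames[det.frame, c]
        row = int(round(det.y_um / cal.um_per_px_y))
        col = int(round(det.x_um / cal.um_per_px_x))
        r0, r1 = max(0, row - half), min(img.shape[0], row + half + 1)
        c0, c1 = max(0, col - half), min(img.shape[1], col + half + 1)
        sub = np.asarray(img[r0:r1, c0:c1], dtype=float)

        def _fail(reason: str) -> None:
            failures.append({"cell_id": i, "frame": det.frame, "reason": reason})

        if sub.size == 0 or np.ptp(sub) == 0:
            _fail("blank window")
            continue
        labels = label(sub > threshold_otsu(sub))
        lab = labels[min(row - r0, labels.shape[0] - 1), min(col - c0, labels.shape[1] - 1)]
        if lab == 0:
            fg = np.argwhere(labels > 0)
            if fg.size == 0:
                _fail("no foreground")
                continue
            d2 = ((fg - [row - r0, col - c0]) ** 2).sum(axis=1)
            if d2.min() > 4:  # nearest foreground farther than 2 px from the centroid
                _fail("no region at centroid")
                continue
            lab = labels[tuple(fg[int(np.argmin(d2))])]
        region = labels == lab
        rows_any, cols_any = np.any(region, axis=1), np.any(region, axis=0)
        if rows_any[0] or rows_any[-1] or cols_any[0] or cols_any[-1]:
            _fail("region touches window border")
            continue
        p = regionprops(region.astype(int))[0]
        major = p.axis_major_length * cal.um_per_px_x
        minor = p.axis_minor_length * cal.um_per_px_x
        if minor <= 0:
            _fail("degenerate region")
            continue
        masks.append(ContourMask(frame=det.frame, cell_id=i, mask=region,
                                 offset=(r0, c0), major_um=major, minor_um=minor))
    return masks, failures
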