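"""Ground-truthed synthetic data: trajectories, rendered stacks, masks, cohorts.

Every generator is a pure function of its parameters and a seed, so all
downstream stages can be validated against known ground truth. The motion
repertoire covers the regimes seen in intravital T-cell imaging:

* ``ballistic`` — straight, persistent migration along a fixed heading;
* ``confined_brownian`` — a random walk hard-confined within a radius of its
  start, mimicking cells trapped near tumor targets;
* ``levy`` — truncated power-law (Pareto) step lengths with isotropic
  headings and optional persistence blending: clusters of small steps
  interspersed with long relocations, the classic search pattern;
* ``stationary_probing`` — sub-micron centroid jitter with periodic small
  protrusion events, the rounded "probing" phenotype with displacement ≈ 0.

The scene is a two-compartment geometry: a collagen-rich periphery band at
low x and the tumor core at high x ("toward the core" is +x everywhere in
this package). A master seed fans out to per-arm / per-mouse / per-cell
sub-seeds through ``numpy.random.SeedSequence.spawn``, so any subset of a
cohort is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .imgproc import Calibration, TimeLapseStack
from .tracking import INTRATUMORAL, PERITUMORAL, Track, TrackSet

__all__ = [
    "MotionModel",
    "SceneGeometry",
    "ArmSpec",
    "CohortSpec",
    "GroundTruth",
    "PlacementError",
    "simulate_track",
    "simulate_cohort",
    "render_timelapse",
    "generate_spatial_mask",
    "draw_depth_positions",
    "generate_vessel_fields",
]

MOTION_KINDS = ("ballistic", "confined_brownian", "levy", "stationary_probing")

# stationary_probing phenomenology: centroid jitter sd and protrusion events
_PROBING_JITTER_SD_UM = 0.5
_PROBING_PERIOD_FRAMES = 10
_PROBING_AMPLITUDE_UM = 1.5
# lower cutoff of the truncated Pareto, as a fraction of speed_scale * dt
_LEVY_MIN_STEP_FRAC = 0.3


class PlacementError(RuntimeError):
    """Raised when disjoint cell placement fails after bounded retries."""


@dataclass(frozen=True)
class MotionModel:
    """Parametric single-cell motion regime.

    ``speed_scale`` (μm/min) sets the step-length scale; ``persistence`` in
    [0, 1] blends the previous heading into the next one (levy only;
    ballistic motion is fully persistent by definition). ``levy_exponent``
    (> 1) is the power-law tail exponent and ``truncation_step`` (μm) the
    hard maximum step of the truncated Pareto; ``confinement_radius`` (μm)
    bounds confined_brownian tracks around their start.
    """

    kind: str
    speed_scale: float
    persistence: float = 0.0
    levy_exponent: float = 2.0
    confinement_radius: float = 10.0
    truncation_step: float = 40.0

    def __post_init__(self) -> None:
        if self.kind not in MOTION_KINDS:
            raise ValueError(f"unknown motion kind {self.kind!r}; choose from {MOTION_KINDS}")
        vals = (self.speed_scale, self.persistence, self.levy_exponent,
                self.confinement_radius, self.truncation_step)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("motion-model parameters must be finite")
        if self.speed_scale < 0:
            raise ValueError("speed_scale must be >= 0")
        if not 0 <= self.persistence <= 1:
            raise ValueError("persistence must be in [0, 1]")
        if self.kind == "levy" and self.levy_exponent <= 1:
            raise ValueError("levy_exponent must be > 1")
        if self.kind == "confined_brownian" and self.confinement_radius <= 0:
            raise ValueError("confinement_radius must be > 0")
        if self.kind == "levy" and self.truncation_step <= 0:
            raise ValueError("truncation_step must be > 0")


@dataclass(frozen=True)
class SceneGeometry:
    """Two-compartment field: periphery band (low x) vs tumor core (high x)."""

    shape: tuple[int, int] = (320, 320)   # (H, W) pixels
    um_per_px: float = 1.0
    um_per_slice: float = 5.0
    frame_interval: float = 0.5           # minutes
    periphery_px: int = 80                # columns [0, periphery_px) are stroma

    def __post_init__(self) -> None:
        if self.frame_interval <= 0 or self.um_per_px <= 0 or self.um_per_slice <= 0:
            raise ValueError("calibration and frame interval must be > 0")
        if not 0 < self.periphery_px < self.shape[1]:
            raise ValueError("periphery band must be a proper sub-range of the field width")

    @property
    def size_um(self) -> tuple[float, float]:
        """(width, height) of the field in μm."""
        return (self.shape[1] * self.um_per_px, self.shape[0] * self.um_per_px)

    def periphery_mask(self) -> np.ndarray:
        m = np.zeros(self.shape, dtype=bool)
        m[:, : self.periphery_px] = True
        return m

    def core_mask(self) -> np.ndarray:
        return ~self.periphery_mask()

    def calibration(self) -> Calibration:
        return Calibration(self.um_per_px, self.um_per_px,
                           self.um_per_slice, self.frame_interval)


@dataclass(frozen=True)
class ArmSpec:
    """One treatment arm: mice, cells per mouse, motion mixture, speed factor."""

    label: str
    n_mice: int
    cells_per_mouse: int
    models: tuple[MotionModel, ...]
    weights: tuple[float, ...]
    speed_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.n_mice < 1 or self.cells_per_mouse < 1:
            raise ValueError("counts must be >= 1")
        if len(self.models) != len(self.weights) or not self.models:
            raise ValueError("need one weight per motion model")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if self.speed_multiplier < 0:
            raise ValueError("speed_multiplier must be >= 0")


@dataclass(frozen=True)
class CohortSpec:
    """A multi-arm synthetic study design."""

    arms: tuple[ArmSpec, ...]
    geometry: SceneGeometry = field(default_factory=SceneGeometry)
    n_frames: int = 61
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.arms:
            raise ValueError("cohort needs at least one arm")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")


@dataclass
class GroundTruth:
    """True per-cell trajectories and labels behind a synthetic dataset."""

    tracks: list[Track]
    model_kinds: dict[int, str]
    region: dict[int, str]
    bleach_rate: float | None = None
    drift: np.ndarray | None = None     # (n_frames, 2) in (dx, dy) pixels


# ---------------------------------------------------------------------------
# single-track simulation


def _as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _truncated_pareto(rng: np.random.Generator, alpha: float, lo: float,
                      hi: float, size: int) -> np.ndarray:
    """Inverse-CDF sample of a Pareto density ∝ l^-alpha truncated to [lo, hi]."""
    u = rng.uniform(size=size)
    if abs(alpha - 1.0) < 1e-12:
        return lo * (hi / lo) ** u
    a, b = lo ** (1 - alpha), hi ** (1 - alpha)
    return (a + u * (b - a)) ** (1 / (1 - alpha))


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else np.array([1.0, 0.0])


def simulate_track(
    model: MotionModel,
    n_frames: int,
    dt: float,
    start: tuple[float, float] = (0.0, 0.0),
    seed: int | np.random.Generator = 0,
    cell_id: int = 0,
) -> Track:
    """Simulate one cell trajectory of ``n_frames`` positions at interval ``dt``.

    Identical ``(model, seed)`` pairs yield identical tracks. Hard
    guarantees: confined_brownian never leaves ``confinement_radius`` of its
    start; levy steps never exceed ``truncation_step``.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    if not np.isfinite(dt) or dt <= 0:
        raise ValueError("dt must be finite and > 0")
    start = np.asarray(start, dtype=float)
    if not np.all(np.isfinite(start)):
        raise ValueError("start position must be finite")
    rng = _as_rng(seed)
    n_steps = n_frames - 1
    pos = np.empty((n_frames, 2))
    pos[0] = start

    if model.kind == "ballistic":
        theta = rng.uniform(0, 2 * np.pi)
        step = model.speed_scale * dt * np.array([np.cos(theta), np.sin(theta)])
        pos = start + np.arange(n_frames)[:, None] * step
    elif model.kind == "confined_brownian":
        sd = model.speed_scale * dt / np.sqrt(2)
        R = model.confinement_radius
        for i in range(1, n_frames):
            prop = pos[i - 1] + rng.normal(0, sd, 2)
            vec = prop - start
            r = np.linalg.norm(vec)
            if r > R:  # radial reflection at the confinement boundary
                r_new = min(abs(2 * R - r), R)
                prop = start + _unit(vec) * r_new
            pos[i] = prop
    elif model.kind == "levy":
        lo = max(1e-6, _LEVY_MIN_STEP_FRAC * model.speed_scale * dt)
        lo = min(lo, 0.5 * model.truncation_step)
        lengths = _truncated_pareto(rng, model.levy_exponent, lo,
                                    model.truncation_step, n_steps)
        heading = _unit(rng.normal(size=2))
        for i in range(n_steps):
            rand_dir = _unit(rng.normal(size=2))
            heading = _unit(model.persistence * heading
                            + (1 - model.persistence) * rand_dir)
            pos[i + 1] = pos[i] + lengths[i] * heading
    elif model.kind == "stationary_probing":
        jitter = rng.normal(0, _PROBING_JITTER_SD_UM, (n_frames, 2))
        jitter[0] = 0.0
        offsets = np.zeros((n_frames, 2))
        for t0 in range(_PROBING_PERIOD_FRAMES, n_frames, _PROBING_PERIOD_FRAMES):
            direction = _unit(rng.normal(size=2))
            for k in range(2):  # protrusion lasts two frames
                if t0 + k < n_frames:
                    offsets[t0 + k] = _PROBING_AMPLITUDE_UM * direction
        pos = start + jitter + offsets
        pos[0] = start
    else:  # pragma: no cover - guarded by MotionModel validation
        raise ValueError(model.kind)

    frames = np.arange(n_frames)
    return Track(cell_id=cell_id, frames=frames, times=frames * dt,
                 x=pos[:, 0], y=pos[:, 1])


# ---------------------------------------------------------------------------
# cohort simulation


def _reflect_into(a: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fold coordinates into [lo, hi] by triangular reflection."""
    span = hi - lo
    b = np.mod(a - lo, 2 * span)
    return lo + np.where(b <= span, b, 2 * span - b)


def _stratified_assignment(weights: tuple[float, ...], n: int,
                           rng: np.random.Generator) -> np.ndarray:
    """Model indices in exact mixture proportions, randomly permuted.

    Counts are ``floor(w_i * n)`` with the remainder going to the largest
    fractional parts (ties to the lower index). Fixing the composition
    removes mixture-sampling noise from arm-level contrasts, so configured
    between-arm effects are identifiable at desk-scale cohort sizes.
    """
    w = np.asarray(weights, dtype=float)
    counts = np.floor(w * n).astype(int)
    frac = w * n - counts
    for k in np.lexsort((np.arange(len(w)), -frac))[: n - counts.sum()]:
        counts[k] += 1
    idx = np.repeat(np.arange(len(w)), counts)
    return rng.permutation(idx)


def simulate_cohort(spec: CohortSpec) -> tuple[dict[str, list[TrackSet]], GroundTruth]:
    """Simulate every mouse of a multi-arm cohort.

    Returns ``{arm label: [TrackSet per mouse]}`` plus a :class:`GroundTruth`
    covering every generated track (true coordinates, motion kind, start-
    compartment region). Motion models are assigned per mouse in exact
    mixture proportions (permuted); tracks are folded back into the field by
    reflection so rendering stays valid; region labels use the starting
    compartment.
    """
    geom = spec.geometry
    w_um, h_um = geom.size_um
    margin = 12.0
    band_um = geom.periphery_px * geom.um_per_px
    ss = np.random.SeedSequence(spec.seed)
    arm_seeds = ss.spawn(len(spec.arms))
    tracksets: dict[str, list[TrackSet]] = {}
    all_tracks: list[Track] = []
    kinds: dict[int, str] = {}
    regions: dict[int, str] = {}
    next_id = 0
    for arm, arm_ss in zip(spec.arms, arm_seeds):
        mouse_seeds = arm_ss.spawn(arm.n_mice)
        per_mouse = []
        for m, mouse_ss in enumerate(mouse_seeds):
            children = mouse_ss.spawn(arm.cells_per_mouse + 1)
            assignment = _stratified_assignment(
                arm.weights, arm.cells_per_mouse, np.random.default_rng(children[0]))
            tracks = []
            for k, cell_ss in zip(assignment, children[1:]):
                rng = np.random.default_rng(cell_ss)
                model = replace(arm.models[k],
                                speed_scale=arm.models[k].speed_scale * arm.speed_multiplier)
                start = (rng.uniform(margin, w_um - margin),
                         rng.uniform(margin, h_um - margin))
                tr = simulate_track(model, spec.n_frames, geom.frame_interval,
                                    start=start, seed=rng, cell_id=next_id)
                tr.x = _reflect_into(tr.x, margin / 2, w_um - margin / 2)
                tr.y = _reflect_into(tr.y, margin / 2, h_um - margin / 2)
                tracks.append(tr)
                kinds[next_id] = model.kind
                regions[next_id] = PERITUMORAL if start[0] < band_um else INTRATUMORAL
                for t in (tr,):
                    t.region = regions[next_id]
                next_id += 1
            per_mouse.append(TrackSet(tracks=tracks, mouse=f"{arm.label}_m{m}", arm=arm.label))
            all_tracks.extend(tracks)
        tracksets[arm.label] = per_mouse
    return tracksets, GroundTruth(tracks=all_tracks, model_kinds=kinds, region=regions)


# ---------------------------------------------------------------------------
# rendering


def render_timelapse(
    tracks: TrackSet | list[Track],
    geometry: SceneGeometry,
    cell_radius_um: float = 5.0,
    bleach_rate: float = 0.0,
    drift: np.ndarray | None = None,
    noise: tuple[float, float] = (0.0, 0.0),
    n_z: int = 3,
    seed: int | np.random.Generator = 0,
) -> tuple[TimeLapseStack, GroundTruth]:
    """Render tracks into a calibrated (t, z, channel, y, x) stack.

    Channel 0 ("GFP") holds one Gaussian blob per cell per frame, centred at
    the drift-shifted true centroid, with amplitude decaying geometrically at
    ``bleach_rate`` per frame before noise. Channel 1 ("mCherry") fills the
    tumor core; channel 2 ("SHG") renders collagen-like fibers only in the
    periphery band. ``drift`` is an (n_frames, 2) array of absolute per-frame
    (dx, dy) pixel offsets. ``noise`` is (Poisson photon scale, Gaussian sd);
    zero disables each. The z axis carries a fixed unimodal intensity profile
    whose maximum slice equals the 2D scene, so a max projection recovers it
    exactly.
    """
    track_list = list(tracks.tracks if isinstance(tracks, TrackSet) else tracks)
    if not 0 <= bleach_rate < 1:
        raise ValueError("bleach_rate must be in [0, 1)")
    h, w = geometry.shape
    upp = geometry.um_per_px
    n_frames = 1 + max((int(t.frames[-1]) for t in track_list), default=0)
    n_frames = max(n_frames, 2)
    if drift is None:
        drift = np.zeros((n_frames, 2))
    drift = np.asarray(drift, dtype=float)
    if drift.shape != (n_frames, 2):
        raise ValueError(f"drift must have shape ({n_frames}, 2)")
    rng = _as_rng(seed)

    sigma_px = cell_radius_um / upp / 2.0
    half = int(np.ceil(4 * sigma_px))
    gfp = np.zeros((n_frames, h, w), dtype=np.float64)
    for tr in track_list:
        cols = tr.x / upp
        rows = tr.y / upp
        if np.any((cols < 0) | (cols >= w) | (rows < 0) | (rows >= h)):
            raise ValueError(f"cell {tr.cell_id} leaves the field of view")
        for fi, frame in enumerate(tr.frames):
            cx = cols[fi] + drift[frame, 0]
            cy = rows[fi] + drift[frame, 1]
            r0, r1 = int(np.floor(cy)) - half, int(np.floor(cy)) + half + 1
            c0, c1 = int(np.floor(cx)) - half, int(np.floor(cx)) + half + 1
            r0c, r1c = max(r0, 0), min(r1, h)
            c0c, c1c = max(c0, 0), min(c1, w)
            if r0c >= r1c or c0c >= c1c:
                continue
            yy, xx = np.mgrid[r0c:r1c, c0c:c1c]
            gfp[frame, r0c:r1c, c0c:c1c] += 1000.0 * np.exp(
                -((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma_px**2))

    mcherry = geometry.core_mask().astype(np.float64) * 600.0
    shg = _render_fibers(geometry, rng)

    decay = (1.0 - bleach_rate) ** np.arange(n_frames)
    zc = (n_z - 1) / 2.0
    z_sd = max(n_z / 4.0, 0.5)
    z_prof = np.exp(-((np.arange(n_z) - zc) ** 2) / (2 * z_sd**2))
    z_prof /= z_prof.max()

    from scipy import ndimage as ndi

    vox = np.zeros((n_frames, n_z, 3, h, w), dtype=np.float64)
    for t in range(n_frames):
        # stage drift moves the whole frame: shift the static channels too
        if drift[t, 0] != 0 or drift[t, 1] != 0:
            shift_vec = (drift[t, 1], drift[t, 0])  # (dy, dx) -> (rows, cols)
            mch_t = ndi.shift(mcherry, shift_vec, order=1, mode="nearest")
            shg_t = ndi.shift(shg, shift_vec, order=1, mode="constant", cval=0.0)
        else:
            mch_t, shg_t = mcherry, shg
        ch = np.stack([gfp[t] * decay[t], mch_t * decay[t], shg_t])
        vox[t] = z_prof[:, None, None, None] * ch[None, :, :, :]

    p_scale, g_sd = noise
    if p_scale > 0:
        vox = rng.poisson(vox * p_scale).astype(np.float64) / p_scale
    if g_sd > 0:
        vox = vox + rng.normal(0.0, g_sd, vox.shape)
    np.clip(vox, 0.0, None, out=vox)

    stack = TimeLapseStack(voxels=vox, calibration=geometry.calibration(),
                           channels=("GFP", "mCherry", "SHG"))
    gt = GroundTruth(tracks=track_list,
                     model_kinds={t.cell_id: "unknown" for t in track_list},
                     region={t.cell_id: t.region for t in track_list},
                     bleach_rate=bleach_rate, drift=drift)
    return stack, gt


def _render_fibers(geometry: SceneGeometry, rng: np.random.Generator,
                   n_fibers: int = 12) -> np.ndarray:
    """Wavy vertical collagen-like fibers confined to the periphery band."""
    h, w = geometry.shape
    img = np.zeros((h, w), dtype=np.float64)
    band = geometry.periphery_px
    yy = np.arange(h)
    for _ in range(n_fibers):
        x0 = rng.uniform(2, band - 3)
        amp = rng.uniform(1.0, 4.0)
        period = rng.uniform(40, 120)
        phase = rng.uniform(0, 2 * np.pi)
        xs = np.clip(np.round(x0 + amp * np.sin(2 * np.pi * yy / period + phase)),
                     0, band - 1).astype(int)
        for off in (-1, 0, 1):
            cols = np.clip(xs + off, 0, band - 1)
            img[yy, cols] = 400.0
    from scipy import ndimage as ndi

    img = ndi.gaussian_filter(img, 1.0)
    img[:, band:] = 0.0
    return img


# ---------------------------------------------------------------------------
# spatial masks and vessel fields


def draw_depth_positions(
    n: int,
    distribution: tuple = ("uniform",),
    width: float = 1000.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Draw periphery→core (x) coordinates from a stated parametric family.

    ``distribution`` is ``("uniform",)`` or ``("beta", a, b)``; beta samples
    are scaled to [0, width]. Core-concentrated infiltration corresponds to
    beta families with mass toward high x (e.g. ``("beta", 5, 1.5)``).
    """
    rng = _as_rng(seed)
    if distribution[0] == "uniform":
        return rng.uniform(0, width, n)
    if distribution[0] == "beta":
        _, a, b = distribution
        return rng.beta(a, b, n) * width
    raise ValueError(f"unknown depth distribution {distribution!r}")


def generate_spatial_mask(
    n_cells: int,
    depth_distribution: tuple = ("uniform",),
    field: tuple[int, int] = (256, 256),
    seed: int | np.random.Generator = 0,
    cell_radius_px: int = 3,
    max_retries: int = 200,
) -> tuple[np.ndarray, np.ndarray]:
    """Place ``n_cells`` disjoint disks; x positions follow the depth family.

    Returns a boolean mask with exactly ``n_cells`` foreground components and
    the true (x, y) centre positions in pixels. Raises
    :class:`PlacementError` when disjoint placement fails after bounded
    retries per cell.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    rng = _as_rng(seed)
    h, w = field
    mask = np.zeros((h, w), dtype=bool)
    centers: list[tuple[float, float]] = []
    min_d2 = (2 * cell_radius_px + 2) ** 2
    r = cell_radius_px
    for _ in range(n_cells):
        for attempt in range(max_retries):
            x = float(np.clip(draw_depth_positions(1, depth_distribution, w, rng)[0],
                              r + 1, w - r - 2))
            y = float(rng.uniform(r + 1, h - r - 2))
            if all((x - cx) ** 2 + (y - cy) ** 2 >= min_d2 for cx, cy in centers):
                centers.append((x, y))
                yy, xx = np.mgrid[0:h, 0:w]
                break
        else:
            raise PlacementError(
                f"could not place cell {len(centers)} disjointly after {max_retries} tries")
    yy, xx = np.mgrid[0:h, 0:w]
    for cx, cy in centers:
        mask |= (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2
    return mask, np.array(centers).reshape(-1, 2)


def generate_vessel_fields(
    n_fields: int,
    target_rho: float = 0.7,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Simulate per-field vessel and cell counts with a target Spearman rho.

    Counts are Poisson-marginal transforms of a Gaussian copula whose Pearson
    correlation is chosen as ``2 sin(pi * rho / 6)`` so the latent Spearman
    correlation equals the target; integer discretisation attenuates it only
    mildly. ``|target_rho| = 1`` uses a strictly monotone construction so the
    empirical rho is exactly ±1.
    """
    if n_fields < 3:
        raise ValueError("need at least 3 fields")
    if abs(target_rho) > 1:
        raise ValueError("target_rho must lie in [-1, 1]")
    rng = _as_rng(seed)
    if abs(target_rho) >= 1 - 1e-12:
        base = np.arange(n_fields)
        vessels = 3 + base
        cells = 10 + 5 * (base if target_rho > 0 else base[::-1])
    else:
        r = 2 * np.sin(np.pi * target_rho / 6)
        z = rng.multivariate_normal([0, 0], [[1, r], [r, 1]], size=n_fields)
        u = stats.norm.cdf(z)
        vessels = stats.poisson.ppf(u[:, 0], 8).astype(int)
        cells = stats.poisson.ppf(u[:, 1], 40).astype(int)
    return pd.DataFrame({
        "field": np.arange(n_fields),
        "vessel_count": np.asarray(vessels, dtype=int),
        "cell_count": np.asarray(cells, dtype=int),
    })
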