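"""Ground-truthed synthetic chemotaxis assays.

This module generates everything the analysis pipeline consumes, with known
ground truth at every level:

* **Trajectories** — biased random walks in the migration channel.  Per step
  the direction is von Mises distributed about the up-gradient axis
  (concentration ``kappa``; ``kappa = 0`` is an unbiased walk) and the step
  length is ``speed * frame_interval`` with speed drawn from a Gamma law.
  Because step speeds are independent of direction, the large-sample
  chemotactic index has the closed form ``I1(kappa)/I0(kappa)`` (the mean
  resultant length of the von Mises law), which :func:`calibrate_kappa`
  inverts so a simulated condition can be pinned to any target C.I.
* **Images** — cells drawn as filled rotated ellipses of known area and
  elongation, as label masks plus a noisy grayscale rendering, so the
  segmentation/morphometry stage can be validated in closed loop.
* **Cohorts** — synthetic COPD/control subject panels in which COPD-like
  sputum is the more potent chemoattractant and, within the COPD group, the
  target C.I. decreases linearly with FEV1/FVC up to configurable noise —
  the statistical structure the downstream group tests and regressions probe.

All randomness flows from a single root seed through
:class:`numpy.random.SeedSequence` spawning, so any stage is independently
reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import i0e, i1e

from .gradient import ChannelGeometry

__all__ = [
    "AssayConfig",
    "MotilityParams",
    "ShapeParams",
    "Attractant",
    "ConditionSpec",
    "Track",
    "CohortSubject",
    "SyntheticCohort",
    "expected_ci",
    "calibrate_kappa",
    "simulate_track",
    "simulate_tracks",
    "place_cells",
    "render_field",
    "render_frames",
    "render_shape_field",
    "generate_cohort",
]


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AssayConfig:
    """Imaging/assay geometry shared by simulation and analysis.

    ``gradient_axis`` is the in-plane unit vector pointing *up* the gradient,
    i.e. from the sink wall toward the chemoattractant source wall.  With the
    source wall at ``y = 0`` this is ``(0, -1)``.
    """

    geometry: ChannelGeometry = field(default_factory=ChannelGeometry)
    frame_interval: float = 10.0  # s
    n_frames: int = 120  # 20 min at 10 s
    pixel_size: float = 1.0  # µm / pixel
    gradient_axis: tuple[float, float] = (0.0, -1.0)
    field_length: float = 1000.0  # µm imaged along the flow axis

    def __post_init__(self) -> None:
        if not self.frame_interval > 0:
            raise ValueError("frame_interval must be > 0")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")
        if not self.field_length > 0:
            raise ValueError("field_length must be > 0")
        axis = np.asarray(self.gradient_axis, dtype=float)
        if not np.isclose(np.linalg.norm(axis), 1.0, atol=1e-9):
            raise ValueError("gradient_axis must be a unit vector")

    @property
    def duration(self) -> float:
        return (self.n_frames - 1) * self.frame_interval


@dataclass(frozen=True)
class MotilityParams:
    """Ground-truth motility law of a simulated condition.

    kappa
        von Mises directional concentration (0 = unbiased).
    mean_step_speed
        Mean of the per-step Gamma speed law, µm/s.
    speed_shape
        Gamma shape parameter; larger = narrower speed distribution.
    persistence
        Weight in [0, 1) blending the previous step direction into the von
        Mises center.  Nonzero persistence breaks the Bessel-ratio
        calibration and is excluded from it by design.
    """

    kappa: float = 0.0
    mean_step_speed: float = 0.15
    speed_shape: float = 2.0
    persistence: float = 0.0

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if not self.mean_step_speed > 0:
            raise ValueError("mean_step_speed must be > 0")
        if not self.speed_shape > 0:
            raise ValueError("speed_shape must be > 0")
        if not 0.0 <= self.persistence < 1.0:
            raise ValueError("persistence must be in [0, 1)")


@dataclass(frozen=True)
class ShapeParams:
    """Ground-truth cell shape: area (µm²), elongation, orientation rule."""

    area: float = 150.0
    aspect_ratio_true: float = 1.0
    orientation_mode: str = "random"  # gradient_aligned | random | isotropic
    boundary_noise: float = 0.0

    def __post_init__(self) -> None:
        if not self.area > 0:
            raise ValueError("area must be > 0")
        if self.aspect_ratio_true < 1.0:
            raise ValueError("aspect_ratio_true must be >= 1")
        if self.orientation_mode not in ("gradient_aligned", "random", "isotropic"):
            raise ValueError(f"unknown orientation_mode {self.orientation_mode!r}")
        if self.boundary_noise < 0:
            raise ValueError("boundary_noise must be >= 0")

    @property
    def semi_axes(self) -> tuple[float, float]:
        """Semi-major and semi-minor axis (µm) of the ground-truth ellipse."""
        a = math.sqrt(self.area * self.aspect_ratio_true / math.pi)
        return a, a / self.aspect_ratio_true


@dataclass(frozen=True)
class Attractant:
    """A chemoattractant source: name, signaling family, and potency.

    ``family`` is ``"terminal"`` (bacterial end-target peptides such as fMLP)
    or ``"intermediate"`` (host chemokines such as IL-8 and sputum).
    ``potency`` is the directional concentration kappa the attractant would
    induce in a single gradient on its own.
    """

    name: str
    family: str = "intermediate"
    potency: float = 1.0

    def __post_init__(self) -> None:
        if self.family not in ("terminal", "intermediate"):
            raise ValueError("family must be 'terminal' or 'intermediate'")
        if self.potency < 0:
            raise ValueError("potency must be >= 0")


# fraction of the losing attractant's potency subtracted from the winner's in
# competing gradients; makes dominance dose-dependent.
_COMPETITION_PENALTY = 0.5


@dataclass(frozen=True)
class ConditionSpec:
    """One assay condition: attractant layout, derived bias, cell shape.

    In competing gradients the terminal family dominates the intermediate
    one; within a family the higher potency wins.  The effective bias is the
    winner's potency reduced by half the loser's (clipped at zero), so a
    stronger competitor weakens net directionality — the dose dependence the
    competing-gradient experiments show.  ``bias_sign`` is +1 when the net
    bias points toward the top (y = 0) source and -1 toward the bottom.
    A uniform field (same attractant both sides, or none) has zero bias.
    """

    label: str
    top_attractant: Attractant | None = None
    bottom_attractant: Attractant | None = None
    shape: ShapeParams = field(default_factory=ShapeParams)

    def _rank(self, a: Attractant) -> tuple[int, float]:
        return (1 if a.family == "terminal" else 0, a.potency)

    @property
    def bias_sign(self) -> int:
        top, bot = self.top_attractant, self.bottom_attractant
        if top is None and bot is None:
            return 0
        if bot is None:
            return 1
        if top is None:
            return -1
        if self._rank(top) == self._rank(bot):
            return 0
        return 1 if self._rank(top) > self._rank(bot) else -1

    @property
    def effective_kappa(self) -> float:
        top, bot = self.top_attractant, self.bottom_attractant
        if self.bias_sign == 0:
            return 0.0
        winner, loser = (top, bot) if self.bias_sign > 0 else (bot, top)
        kappa = winner.potency
        if loser is not None:
            kappa -= _COMPETITION_PENALTY * loser.potency
        return max(kappa, 0.0)


@dataclass
class Track:
    """One cell's time-ordered positions (µm) in channel coordinates."""

    track_id: int
    t: np.ndarray  # s, strictly increasing
    xy: np.ndarray  # (n, 2) µm
    condition_label: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.xy = np.asarray(self.xy, dtype=float)
        if self.t.ndim != 1 or self.xy.shape != (self.t.size, 2):
            raise ValueError("t must be 1-D and xy must be (len(t), 2)")
        if self.t.size and np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")

    def __len__(self) -> int:
        return self.t.size


# ---------------------------------------------------------------------------
# chemotactic-index calibration
# ---------------------------------------------------------------------------

def expected_ci(kappa: float) -> float:
    """Asymptotic chemotactic index of the unbiased-speed von Mises walk.

    For i.i.d. step directions ~ vonMises(0, kappa) and step lengths
    independent of direction, the C.I. of a long track converges to the mean
    resultant length I1(kappa)/I0(kappa): strictly increasing in kappa, 0 at
    kappa = 0, and approaching 1 as kappa grows.
    """
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    if kappa == 0:
        return 0.0
    # exponentially scaled Bessels avoid overflow at large kappa
    return float(i1e(kappa) / i0e(kappa))


def calibrate_kappa(target_ci: float) -> float:
    """Invert :func:`expected_ci`: kappa whose asymptotic C.I. is the target."""
    if not 0.0 <= target_ci < 1.0:
        raise ValueError("target_ci must be in [0, 1)")
    if target_ci == 0.0:
        return 0.0
    hi = 1.0
    while expected_ci(hi) < target_ci:
        hi *= 2.0
    return float(brentq(lambda k: expected_ci(k) - target_ci, 0.0, hi, xtol=1e-12))


# ---------------------------------------------------------------------------
# trajectory simulation
# ---------------------------------------------------------------------------

def _reflect(z: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fold coordinates into [lo, hi] by specular reflection at the walls."""
    period = 2.0 * (hi - lo)
    z = np.mod(np.asarray(z, dtype=float) - lo, period)
    return np.where(z > hi - lo, period - z, z) + lo


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_track(
    motility: MotilityParams,
    config: AssayConfig,
    start: tuple[float, float],
    bias_direction: tuple[float, float] | None = None,
    seed=0,
    track_id: int = 0,
    condition_label: str = "",
) -> Track:
    """Simulate one biased random walk inside the channel.

    The walk starts at ``start`` (µm; must lie inside the imaged field),
    takes ``n_frames - 1`` steps at the frame interval, and is specularly
    reflected at the channel walls (y in [0, width]) and field ends
    (x in [0, field_length]).  ``bias_direction`` defaults to the config's
    up-gradient axis.  Fully reproducible from ``seed``.
    """
    rng = _as_rng(seed)
    geom = config.geometry
    start = np.asarray(start, dtype=float)
    if not (0 <= start[0] <= config.field_length and 0 <= start[1] <= geom.width):
        raise ValueError(f"start {start} outside channel field")

    if bias_direction is None:
        bias_direction = config.gradient_axis
    bias = np.asarray(bias_direction, dtype=float)
    norm = np.linalg.norm(bias)
    if norm == 0:
        raise ValueError("bias_direction must be nonzero")
    bias = bias / norm
    bias_angle = math.atan2(bias[1], bias[0])

    n_steps = config.n_frames - 1
    dt = config.frame_interval
    speeds = rng.gamma(
        shape=motility.speed_shape,
        scale=motility.mean_step_speed / motility.speed_shape,
        size=n_steps,
    )

    if motility.persistence == 0.0:
        dev = rng.vonmises(0.0, motility.kappa, size=n_steps)
        angles = bias_angle + dev
    else:
        angles = np.empty(n_steps)
        prev = bias.copy()
        p = motility.persistence
        for i in range(n_steps):
            center = (1.0 - p) * bias + p * prev
            cnorm = np.linalg.norm(center)
            c_angle = bias_angle if cnorm == 0 else math.atan2(center[1], center[0])
            angles[i] = c_angle + rng.vonmises(0.0, motility.kappa)
            prev = np.array([math.cos(angles[i]), math.sin(angles[i])])

    steps = (speeds * dt)[:, None] * np.column_stack([np.cos(angles), np.sin(angles)])
    xy = np.vstack([start, start + np.cumsum(steps, axis=0)])
    xy[:, 0] = _reflect(xy[:, 0], 0.0, config.field_length)
    xy[:, 1] = _reflect(xy[:, 1], 0.0, geom.width)
    t = np.arange(config.n_frames, dtype=float) * dt
    return Track(track_id=track_id, t=t, xy=xy, condition_label=condition_label)


def simulate_tracks(
    n_tracks: int,
    motility: MotilityParams,
    config: AssayConfig,
    seed=0,
    start_region: tuple[tuple[float, float], tuple[float, float]] | None = None,
    bias_direction: tuple[float, float] | None = None,
    condition_label: str = "",
) -> list[Track]:
    """Simulate a batch of tracks with independent spawned random streams.

    ``start_region`` is ((x_lo, x_hi), (y_lo, y_hi)) in µm; the default keeps
    cells away from the source wall so that up-gradient drift over the assay
    rarely produces wall reflections (which would bias the measured C.I.
    relative to the calibrated asymptote).
    """
    geom = config.geometry
    if start_region is None:
        start_region = (
            (0.1 * config.field_length, 0.9 * config.field_length),
            (0.5 * geom.width, 0.95 * geom.width),
        )
    root = np.random.SeedSequence(_seed_entropy(seed))
    children = root.spawn(n_tracks)
    (x_lo, x_hi), (y_lo, y_hi) = start_region
    tracks = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        start = (rng.uniform(x_lo, x_hi), rng.uniform(y_lo, y_hi))
        tracks.append(
            simulate_track(
                motility,
                config,
                start,
                bias_direction=bias_direction,
                seed=rng,
                track_id=i,
                condition_label=condition_label,
            )
        )
    return tracks


def _seed_entropy(seed) -> int:
    if isinstance(seed, np.random.SeedSequence):
        return seed.entropy
    return int(seed)


# ---------------------------------------------------------------------------
# image rendering
# ---------------------------------------------------------------------------

def place_cells(
    n: int,
    field_um: tuple[float, float],
    min_separation: float,
    rng,
    margin: float = 0.0,
) -> np.ndarray:
    """Place ``n`` cell centers with a guaranteed minimum separation.

    Centers are laid on a jittered grid: pitch = min_separation plus twice
    the jitter amplitude, so the separation guarantee is exact.  Raises if
    the field cannot hold ``n`` cells at that pitch.
    """
    rng = _as_rng(rng)
    lx, ly = field_um
    jitter = 0.15 * min_separation
    pitch = min_separation + 2.0 * jitter
    nx = int((lx - 2.0 * margin) // pitch)
    ny = int((ly - 2.0 * margin) // pitch)
    if nx * ny < n:
        raise ValueError(
            f"field {field_um} holds at most {nx * ny} cells at separation "
            f"{min_separation:.1f} µm; {n} requested"
        )
    nodes = [(i, j) for j in range(ny) for i in range(nx)]
    idx = rng.choice(len(nodes), size=n, replace=False)
    centers = np.empty((n, 2))
    for k, ii in enumerate(idx):
        i, j = nodes[ii]
        cx = margin + (i + 0.5) * pitch + rng.uniform(-jitter, jitter)
        cy = margin + (j + 0.5) * pitch + rng.uniform(-jitter, jitter)
        centers[k] = (cx, cy)
    return centers


def _draw_ellipse(
    label_img: np.ndarray,
    center_um: np.ndarray,
    orientation: float,
    shape: ShapeParams,
    pixel_size: float,
    label: int,
    rng,
) -> None:
    """Rasterize one filled (optionally boundary-perturbed) rotated ellipse.

    Pixels already owned by another label are left untouched so every
    nonzero pixel belongs to exactly one cell.
    """
    a, b = shape.semi_axes
    r_max = a * (1.0 + 3.0 * shape.boundary_noise)
    cx, cy = center_um / pixel_size
    rad = r_max / pixel_size
    j_lo, j_hi = int(math.floor(cx - rad)), int(math.ceil(cx + rad)) + 1
    i_lo, i_hi = int(math.floor(cy - rad)), int(math.ceil(cy + rad)) + 1
    j_lo, i_lo = max(j_lo, 0), max(i_lo, 0)
    j_hi = min(j_hi, label_img.shape[1])
    i_hi = min(i_hi, label_img.shape[0])
    jj, ii = np.meshgrid(np.arange(j_lo, j_hi), np.arange(i_lo, i_hi))
    dx = jj * pixel_size - center_um[0]
    dy = ii * pixel_size - center_um[1]
    u = (dx * math.cos(orientation) + dy * math.sin(orientation)) / a
    v = (-dx * math.sin(orientation) + dy * math.cos(orientation)) / b
    q = u * u + v * v
    if shape.boundary_noise > 0:
        theta = np.arctan2(v, u)
        coeffs = rng.normal(0.0, shape.boundary_noise / math.sqrt(6.0), size=6)
        eta = np.zeros_like(theta)
        for m, (am, bm) in enumerate(zip(coeffs[:3], coeffs[3:]), start=2):
            eta += am * np.cos(m * theta) + bm * np.sin(m * theta)
        inside = q <= (1.0 + eta) ** 2
    else:
        inside = q <= 1.0
    patch = label_img[i_lo:i_hi, j_lo:j_hi]
    patch[inside & (patch == 0)] = label


def render_field(
    centers_um: np.ndarray,
    orientations: np.ndarray,
    shapes: list[ShapeParams],
    field_um: tuple[float, float],
    pixel_size: float,
    rng,
    noise_sd: float = 0.02,
    cell_intensity: float = 0.6,
    background: float = 0.1,
) -> tuple[np.ndarray, np.ndarray]:
    """Render one frame: (uint16 label image, uint16 noisy grayscale image).

    Label ``k + 1`` marks cell ``k``.  The grayscale image is background plus
    a constant cell intensity plus Gaussian read noise, quantized to 16 bit.
    """
    rng = _as_rng(rng)
    lx, ly = field_um
    nxp = int(round(lx / pixel_size)) + 1
    nyp = int(round(ly / pixel_size)) + 1
    for s in shapes:
        if 2 * s.semi_axes[0] >= min(lx, ly):
            raise ValueError("cell too large for field")
    labels = np.zeros((nyp, nxp), dtype=np.uint16)
    for k, (c, phi, s) in enumerate(zip(centers_um, orientations, shapes)):
        _draw_ellipse(labels, np.asarray(c, float), float(phi), s, pixel_size, k + 1, rng)
    gray = background + cell_intensity * (labels > 0)
    gray = gray + rng.normal(0.0, noise_sd, size=gray.shape)
    gray16 = (np.clip(gray, 0.0, 1.0) * 65535).astype(np.uint16)
    return labels, gray16


def _orientations_for(
    tracks: list[Track], shapes: list[ShapeParams], frame: int, fixed: np.ndarray
) -> np.ndarray:
    out = np.empty(len(tracks))
    for k, (tr, s) in enumerate(zip(tracks, shapes)):
        if s.orientation_mode == "gradient_aligned":
            i = min(frame, len(tr) - 2)
            step = tr.xy[i + 1] - tr.xy[i]
            out[k] = math.atan2(step[1], step[0]) if np.any(step != 0) else fixed[k]
        elif s.orientation_mode == "random":
            out[k] = fixed[k]
        else:  # isotropic: round cells, orientation irrelevant
            out[k] = 0.0
    return out


def render_frames(
    tracks: list[Track],
    shapes: list[ShapeParams] | ShapeParams,
    config: AssayConfig,
    seed=0,
    noise_sd: float = 0.02,
) -> tuple[np.ndarray, np.ndarray]:
    """Render a time-lapse: (label stack, grayscale stack), shape (T, H, W).

    Each track becomes a filled rotated ellipse per frame; label value is
    ``track index + 1``.  Orientation follows the track's instantaneous
    movement direction (``gradient_aligned``), a per-cell fixed random angle
    (``random``), or is irrelevant (``isotropic``).
    """
    if isinstance(shapes, ShapeParams):
        shapes = [shapes] * len(tracks)
    if len(shapes) != len(tracks):
        raise ValueError("one ShapeParams per track required")
    rng = _as_rng(seed)
    fixed = rng.uniform(-math.pi, math.pi, size=len(tracks))
    field_um = (config.field_length, config.geometry.width)
    lab_stack, gray_stack = [], []
    for f in range(config.n_frames):
        centers = np.array([tr.xy[f] for tr in tracks]) if tracks else np.empty((0, 2))
        phis = _orientations_for(tracks, shapes, f, fixed)
        lab, gray = render_field(
            centers, phis, shapes, field_um, config.pixel_size, rng, noise_sd=noise_sd
        )
        lab_stack.append(lab)
        gray_stack.append(gray)
    return np.stack(lab_stack), np.stack(gray_stack)


def render_shape_field(
    n_cells: int,
    shape: ShapeParams,
    pixel_size: float,
    seed=0,
    noise_sd: float = 0.02,
) -> tuple[np.ndarray, np.ndarray]:
    """Render a single static field of ``n_cells`` identical-statistics cells.

    Centers are at least two major axes apart (so segmentation can never
    merge neighbours); orientations are uniform random unless the shape is
    isotropic.  Returns (label image, grayscale image).
    """
    rng = _as_rng(seed)
    a, _ = shape.semi_axes
    min_sep = 4.0 * a  # two major axes
    pitch = min_sep * 1.3  # matches place_cells' jittered pitch
    ncols = math.ceil(math.sqrt(n_cells))
    margin = 2.0 * a * (1.0 + 3.0 * shape.boundary_noise) + 2.0 * pixel_size
    side = (ncols + 0.5) * pitch + 2.0 * margin
    centers = place_cells(n_cells, (side, side), min_sep, rng, margin=margin)
    if shape.orientation_mode == "isotropic":
        phis = np.zeros(n_cells)
    else:
        phis = rng.uniform(-math.pi, math.pi, size=n_cells)
    return render_field(
        centers, phis, [shape] * n_cells, (side, side), pixel_size, rng, noise_sd=noise_sd
    )


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

@dataclass
class CohortSubject:
    """Ground truth plus generated assay for one synthetic subject."""

    subject_id: str
    group: str  # COPD | control
    age: int
    sex: str
    fvc_l: float | None
    fev1_l: float | None
    fev1_fvc_pct: float | None
    potency: float
    target_ci: float
    kappa_true: float
    mean_speed_true: float
    tracks: list[Track] = field(default_factory=list)


@dataclass
class SyntheticCohort:
    subjects: list[CohortSubject]
    config: AssayConfig
    seed: int

    @property
    def copd(self) -> list[CohortSubject]:
        return [s for s in self.subjects if s.group == "COPD"]

    @property
    def control(self) -> list[CohortSubject]:
        return [s for s in self.subjects if s.group == "control"]


def generate_cohort(
    n_copd: int = 5,
    n_control: int = 5,
    ci_copd_mean: float = 0.39,
    ci_copd_sd: float = 0.10,
    ci_control_mean: float = 0.22,
    ci_control_sd: float = 0.06,
    fev1fvc_range: tuple[float, float] = (35.0, 75.0),
    correlation_noise_sd: float = 0.03,
    tracks_per_subject: int = 50,
    config: AssayConfig | None = None,
    seed: int = 0,
) -> SyntheticCohort:
    """Generate a synthetic COPD/control cohort with full ground truth.

    Per COPD subject, FEV1/FVC is drawn uniformly in ``fev1fvc_range`` and
    the target C.I. decreases linearly with it (scaled so the group C.I.
    mean and sd hit the requested values) plus Gaussian noise of sd
    ``correlation_noise_sd``.  Controls draw their target C.I. from a normal
    law with the control mean/sd and carry no spirometry.  Each subject's
    directional concentration kappa comes from :func:`calibrate_kappa`, its
    mean speed from an independent normal law (so C.I. and speed are
    uncorrelated by construction), and sputum potency is a fixed increasing
    map of the target C.I. — making COPD-like samples the more potent
    attractant on average, mirroring their higher chemokine load.
    """
    for name, m in (("ci_copd_mean", ci_copd_mean), ("ci_control_mean", ci_control_mean)):
        if not 0.0 <= m < 1.0:
            raise ValueError(f"{name} must be in [0, 1)")
    if n_copd < 2 or n_control < 2:
        raise ValueError("need at least 2 subjects per group")
    if config is None:
        config = AssayConfig()

    root = np.random.SeedSequence(seed)
    demo_rng = np.random.default_rng(root.spawn(1)[0])
    subject_seeds = root.spawn(n_copd + n_control)

    lo, hi = fev1fvc_range
    mid, half = (lo + hi) / 2.0, (hi - lo) / 2.0
    subjects: list[CohortSubject] = []
    for i in range(n_copd + n_control):
        is_copd = i < n_copd
        rng = np.random.default_rng(subject_seeds[i])
        if is_copd:
            fev1fvc = rng.uniform(lo, hi)
            # uniform u on [-1, 1] has sd 1/sqrt(3); scale to the target sd
            u = (fev1fvc - mid) / half
            target = ci_copd_mean - math.sqrt(3.0) * ci_copd_sd * u
            target += rng.normal(0.0, correlation_noise_sd)
            fvc = float(rng.uniform(1.0, 2.6))
            fev1 = fvc * fev1fvc / 100.0
            age = int(rng.integers(55, 80))
        else:
            fev1fvc = None
            target = rng.normal(ci_control_mean, ci_control_sd)
            fvc = fev1 = None
            age = int(rng.integers(25, 65))
        target = float(np.clip(target, 0.02, 0.95))
        kappa = calibrate_kappa(target)
        speed = float(np.clip(rng.normal(0.17, 0.05), 0.05, None))
        subj = CohortSubject(
            subject_id=f"{'COPD' if is_copd else 'CTRL'}{(i if is_copd else i - n_copd) + 1}",
            group="COPD" if is_copd else "control",
            age=age,
            sex="F" if demo_rng.random() < 0.5 else "M",
            fvc_l=fvc,
            fev1_l=fev1,
            fev1_fvc_pct=fev1fvc,
            potency=2.0 * target,  # relative sputum potency, increasing in bias
            target_ci=target,
            kappa_true=kappa,
            mean_speed_true=speed,
        )
        motility = MotilityParams(kappa=kappa, mean_step_speed=speed)
        subj.tracks = simulate_tracks(
            tracks_per_subject,
            motility,
            config,
            seed=np.random.SeedSequence(rng.integers(0, 2**31 - 1)),
            condition_label=subj.subject_id,
        )
        subjects.append(subj)
    return SyntheticCohort(subjects=subjects, config=config, seed=seed)
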