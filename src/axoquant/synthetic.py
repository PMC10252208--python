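"""Ground-truthed synthetic microscopy scenes.

Three generators emulate the raw data of the compartmentalized motoneuron
assays so that every downstream stage can be verified without real movies:

* dual-channel style organelle movies (Mitotracker / Lysotracker) inside
  parallel microchannel corridors, with stationary, jittering and processively
  moving organelles of controlled speed laws, moving fractions, directionality
  and shape;
* bright-field-like growth-cone movies (dark deformable cone with a trailing
  axon shaft on a light background) with a controlled drift-speed law;
* immunofluorescence stills with Hoechst nuclei and marker channels at
  configured positive-cell fractions.

All randomness comes from one ``numpy.random.default_rng(seed)`` per scene and
all draws happen in a documented fixed order, so identical configs + seed give
bit-identical stacks and ground truth.

Appearance model: organelles are rendered as Gaussian-blurred shapes
(lysosomes isotropic, mitochondria elongated along the corridor axis); noise
is Poisson shot noise plus additive Gaussian read noise (the standard EMCCD
model), with SNR defined as peak amplitude over the noise SD of the
background.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import draw as skdraw

from .core import Calibration, GroundTruth, ImageStack, GROWTH_CONE_CALIBRATION

__all__ = [
    "OrganelleSceneConfig",
    "GrowthConeSceneConfig",
    "IFSceneConfig",
    "generate_organelle_movie",
    "generate_growth_cone_movie",
    "generate_if_image",
]


def _validate_fraction(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {value}")


# ---------------------------------------------------------------------------
# organelle movies
# ---------------------------------------------------------------------------

@dataclass
class OrganelleSceneConfig:
    """Configuration of a synthetic organelle-trafficking movie.

    Organelle counts may be given either explicitly per motility class
    (``n_stationary`` / ``n_jitter`` / ``n_processive``) or as a total
    ``n_organelles`` with a ``moving_fraction``; in the latter mode each
    organelle is drawn processive with probability ``moving_fraction`` and the
    remainder are split stationary/jitter by a fair Bernoulli draw.

    Speeds are in µm/s; per-object processive speeds are drawn from
    ``N(speed_mean_um_s, speed_sd_um_s)`` truncated at 0 and kept constant
    over the track. ``snr`` is peak spot amplitude over background noise SD.
    """

    organelle_kind: str = "lysosome"  # "lysosome" | "mitochondrion"
    n_stationary: int = 0
    n_jitter: int = 0
    n_processive: int = 0
    n_organelles: int | None = None
    moving_fraction: float | None = None
    speed_mean_um_s: float = 0.8
    speed_sd_um_s: float = 0.2
    jitter_step_um: float = 0.05
    anterograde_fraction: float = 0.5
    diameter_um: float = 0.8          # lysosome FWHM diameter
    major_axis_um: float = 1.6        # mitochondrion axes
    minor_axis_um: float = 0.4
    snr: float = 10.0
    background_level: float = 100.0
    read_noise_sd: float = 2.0
    n_frames: int = 400
    width: int = 512
    height: int = 512
    n_corridors: int = 2
    corridor_width_px: int = 24
    seed: int = 0

    def __post_init__(self) -> None:
        if self.organelle_kind not in ("lysosome", "mitochondrion"):
            raise ValueError("organelle_kind must be 'lysosome' or 'mitochondrion'")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        for name in ("speed_mean_um_s", "speed_sd_um_s", "jitter_step_um"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        _validate_fraction("anterograde_fraction", self.anterograde_fraction)
        if self.moving_fraction is not None:
            _validate_fraction("moving_fraction", self.moving_fraction)
        if (self.n_organelles is None) != (self.moving_fraction is None):
            raise ValueError("n_organelles and moving_fraction must be given together")
        if self.n_corridors < 1:
            raise ValueError("need at least one corridor")

    def corridor_centers(self) -> np.ndarray:
        """Row (y) centers of the parallel microchannel corridors."""
        return (np.arange(self.n_corridors) + 0.5) * self.height / self.n_corridors


def _assign_classes(cfg: OrganelleSceneConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-object motility class labels, in the documented draw order."""
    if cfg.n_organelles is not None:
        moving = rng.random(cfg.n_organelles) < cfg.moving_fraction
        classes = np.where(moving, "processive", "stationary").astype(object)
        rest = ~moving
        jitter = rng.random(cfg.n_organelles) < 0.5
        classes[rest & jitter] = "jitter"
        return classes.astype(str)
    return np.array(
        ["stationary"] * cfg.n_stationary
        + ["jitter"] * cfg.n_jitter
        + ["processive"] * cfg.n_processive
    )


def _spot_patch(amp: float, sigma_x: float, sigma_y: float, cx: float, cy: float,
                shape: tuple[int, int], out: np.ndarray) -> None:
    """Accumulate an anisotropic Gaussian spot into ``out`` (in place)."""
    h, w = shape
    rx = int(np.ceil(4 * sigma_x))
    ry = int(np.ceil(4 * sigma_y))
    x0, x1 = int(np.floor(cx)) - rx, int(np.floor(cx)) + rx + 1
    y0, y1 = int(np.floor(cy)) - ry, int(np.floor(cy)) + ry + 1
    x0c, x1c = max(x0, 0), min(x1, w)
    y0c, y1c = max(y0, 0), min(y1, h)
    if x0c >= x1c or y0c >= y1c:
        return
    xs = np.arange(x0c, x1c) - cx
    ys = np.arange(y0c, y1c) - cy
    g = np.exp(-(ys[:, None] ** 2) / (2 * sigma_y**2)) * np.exp(-(xs[None, :] ** 2) / (2 * sigma_x**2))
    out[y0c:y1c, x0c:x1c] += amp * g


def generate_organelle_movie(
    config: OrganelleSceneConfig, calib: Calibration
) -> tuple[ImageStack, GroundTruth]:
    """Render a single-channel organelle-trafficking movie with ground truth.

    Draw order (fixed for reproducibility): 1) class assignment (fraction
    mode only), 2) per-object corridor index and initial position, 3)
    per-processive-object speed and direction, 4) per-frame jitter steps,
    5) per-frame Poisson + read noise.

    Raises ``ValueError`` when the organelle count exceeds the corridor
    capacity (one organelle per ~2 spot-diameters of corridor length).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    classes = _assign_classes(cfg, rng)
    n = len(classes)

    px_um = calib.pixel_size_um
    if cfg.organelle_kind == "lysosome":
        footprint_px = cfg.diameter_um / px_um
    else:
        footprint_px = cfg.major_axis_um / px_um
    capacity = int(cfg.n_corridors * cfg.width / max(footprint_px, 2.0))
    if n > capacity:
        raise ValueError(
            f"{n} organelles exceed the capacity of {cfg.n_corridors} corridors "
            f"of width {cfg.width} px (~{capacity} organelles); reduce counts or "
            "enlarge the field"
        )

    centers = cfg.corridor_centers()
    corridor = rng.integers(0, cfg.n_corridors, size=n)
    x0 = rng.uniform(0, cfg.width, size=n)
    y0 = centers[corridor] + rng.uniform(-0.5, 0.5, size=n) * (cfg.corridor_width_px * 0.6)

    is_proc = classes == "processive"
    speeds = np.zeros(n)
    speeds[is_proc] = np.clip(
        rng.normal(cfg.speed_mean_um_s, cfg.speed_sd_um_s, size=int(is_proc.sum())), 0.0, None
    )
    antero = np.zeros(n, dtype=bool)
    antero[is_proc] = rng.random(int(is_proc.sum())) < cfg.anterograde_fraction
    direction = np.where(is_proc, np.where(antero, "anterograde", "retrograde"), "none")

    # trajectories (T, n)
    t = np.arange(cfg.n_frames)
    step_px = speeds * calib.frame_interval_s / px_um  # px/frame
    sign = np.where(antero, 1.0, -1.0)
    xs = x0[None, :] + np.where(is_proc, sign * step_px, 0.0)[None, :] * t[:, None]
    ys = np.tile(y0, (cfg.n_frames, 1))
    is_jit = classes == "jitter"
    if is_jit.any():
        jit_px = cfg.jitter_step_um / px_um
        steps = rng.normal(0.0, jit_px, size=(cfg.n_frames - 1, int(is_jit.sum()), 2))
        walk = np.concatenate([np.zeros((1, int(is_jit.sum()), 2)), np.cumsum(steps, axis=0)])
        xs[:, is_jit] += walk[:, :, 0]
        ys[:, is_jit] += walk[:, :, 1]
        # confinement: jitter stays inside its corridor band
        half = cfg.corridor_width_px / 2.0 - 1.0
        ys[:, is_jit] = np.clip(
            ys[:, is_jit], (centers[corridor][is_jit] - half)[None, :], (centers[corridor][is_jit] + half)[None, :]
        )

    noise_sd = float(np.sqrt(cfg.background_level + cfg.read_noise_sd**2))
    amp = cfg.snr * noise_sd
    if cfg.organelle_kind == "lysosome":
        sigma = cfg.diameter_um / px_um / 2.355  # FWHM = diameter
        sigma_x = sigma_y = sigma
    else:
        sigma_x = cfg.major_axis_um / px_um / 2.355
        sigma_y = cfg.minor_axis_um / px_um / 2.355

    stack = np.empty((cfg.n_frames, cfg.height, cfg.width), dtype=np.float32)
    shape = (cfg.height, cfg.width)
    for fr in range(cfg.n_frames):
        clean = np.full(shape, cfg.background_level, dtype=float)
        for i in range(n):
            cx, cy = xs[fr, i], ys[fr, i]
            if -4 * sigma_x <= cx <= cfg.width + 4 * sigma_x and -4 * sigma_y <= cy <= cfg.height + 4 * sigma_y:
                _spot_patch(amp, sigma_x, sigma_y, cx, cy, shape, clean)
        img = rng.poisson(clean).astype(np.float64)
        img += rng.normal(0.0, cfg.read_noise_sd, size=shape)
        stack[fr] = img

    if n:
        objects = pd.DataFrame(
            {
                "object_id": np.arange(n),
                "class": classes,
                "direction": direction,
                "true_speed_um_s": speeds,
                "corridor": corridor,
                "kind": cfg.organelle_kind,
                "true_diameter_um": cfg.diameter_um if cfg.organelle_kind == "lysosome" else np.nan,
                "true_aspect_ratio": (
                    cfg.major_axis_um / cfg.minor_axis_um if cfg.organelle_kind == "mitochondrion" else np.nan
                ),
            }
        )
        positions = pd.DataFrame(
            {
                "object_id": np.repeat(np.arange(n), cfg.n_frames),
                "frame": np.tile(t, n),
                "x_px": xs.T.ravel(),
                "y_px": ys.T.ravel(),
            }
        )
        positions["in_field"] = (
            (positions.x_px >= 0) & (positions.x_px < cfg.width)
            & (positions.y_px >= 0) & (positions.y_px < cfg.height)
        )
    else:
        objects = pd.DataFrame(
            columns=["object_id", "class", "direction", "true_speed_um_s", "corridor", "kind",
                     "true_diameter_um", "true_aspect_ratio"]
        )
        positions = pd.DataFrame(columns=["object_id", "frame", "x_px", "y_px", "in_field"])

    kind_name = "mito" if cfg.organelle_kind == "mitochondrion" else "lyso"
    return ImageStack(stack, calib, (kind_name,)), GroundTruth(objects, positions)


# ---------------------------------------------------------------------------
# growth-cone movies
# ---------------------------------------------------------------------------

@dataclass
class GrowthConeSceneConfig:
    """Configuration of a bright-field-like growth-cone movie.

    One dark, deformable cone (an ellipse whose axes fluctuate by
    ``shape_fluctuation_amplitude`` px per frame, symmetric about its center)
    trails a thin axon shaft and advances with a constant per-frame step
    length drawn once from ``N(drift_speed_mean_um_s, drift_speed_sd_um_s)``
    truncated at 0. The heading performs a slow random walk and reflects off
    a field margin, so the path meanders while the per-frame travel distance
    — the measured quantity — stays at the drawn speed.
    """

    drift_speed_mean_um_s: float = 0.0666
    drift_speed_sd_um_s: float = 0.0
    shape_fluctuation_amplitude: float = 1.0
    background_polarity: str = "light"  # "light" | "dark"
    n_frames: int = 360
    width: int = 128
    height: int = 128
    cone_radius_px: float = 8.0
    cone_depth: float = 120.0
    shaft_depth: float = 45.0
    background_level: float = 200.0
    noise_sd: float = 3.0
    heading_sd_rad: float = 0.25
    margin_px: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.drift_speed_mean_um_s < 0:
            raise ValueError("drift_speed_mean_um_s must be >= 0")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.background_polarity not in ("light", "dark"):
            raise ValueError("background_polarity must be 'light' or 'dark'")


def generate_growth_cone_movie(
    config: GrowthConeSceneConfig, calib: Calibration = GROWTH_CONE_CALIBRATION
) -> tuple[ImageStack, GroundTruth]:
    """Render a growth-cone movie; ground truth records the per-frame true center.

    Draw order: 1) per-cone speed, 2) initial position + heading, 3) per-frame
    heading increments and shape fluctuations, 4) per-frame noise. If the
    field cannot contain the per-frame step (step longer than the usable
    span), the trajectory is truncated at the last in-field frame and a
    warning is emitted.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    speed = max(0.0, float(rng.normal(cfg.drift_speed_mean_um_s, cfg.drift_speed_sd_um_s)))
    step_px = speed * calib.frame_interval_s / calib.pixel_size_um

    lo_x, hi_x = cfg.margin_px, cfg.width - cfg.margin_px
    lo_y, hi_y = cfg.margin_px, cfg.height - cfg.margin_px
    cx = float(rng.uniform(lo_x, hi_x))
    cy = float(rng.uniform(lo_y, hi_y))
    heading = float(rng.uniform(0, 2 * np.pi))

    n_frames = cfg.n_frames
    truncated_at = None
    centers = np.empty((cfg.n_frames, 2))
    centers[0] = (cx, cy)
    for fr in range(1, cfg.n_frames):
        heading += rng.normal(0.0, cfg.heading_sd_rad)
        nx = cx + step_px * np.cos(heading)
        ny = cy + step_px * np.sin(heading)
        tries = 0
        while not (lo_x <= nx <= hi_x and lo_y <= ny <= hi_y):
            # steer back toward the field center, keeping the step length
            heading = float(np.arctan2(cfg.height / 2 - cy, cfg.width / 2 - cx)) + float(
                rng.normal(0.0, cfg.heading_sd_rad)
            )
            nx = cx + step_px * np.cos(heading)
            ny = cy + step_px * np.sin(heading)
            tries += 1
            if tries > 20:
                break
        if not (0 <= nx < cfg.width and 0 <= ny < cfg.height):
            truncated_at = fr
            break
        cx, cy = nx, ny
        centers[fr] = (cx, cy)
    if truncated_at is not None:
        warnings.warn(
            f"drift carried the cone out of the field at frame {truncated_at}; "
            f"movie truncated to {truncated_at} frames",
            stacklevel=2,
        )
        centers = centers[:truncated_at]
        n_frames = truncated_at

    fluct = rng.normal(0.0, cfg.shape_fluctuation_amplitude, size=(n_frames, 2))
    orientations = rng.uniform(0, np.pi, size=n_frames)

    stack = np.empty((n_frames, cfg.height, cfg.width), dtype=np.float32)
    shaft = np.zeros((cfg.height, cfg.width))
    yy, xx = np.mgrid[0:cfg.height, 0:cfg.width]
    for fr in range(n_frames):
        cxf, cyf = centers[fr]
        if fr > 0:
            r0, c0 = int(round(centers[fr - 1][1])), int(round(centers[fr - 1][0]))
            r1, c1 = int(round(cyf)), int(round(cxf))
            rr, cc = skdraw.line(r0, c0, r1, c1)
            ok = (rr >= 0) & (rr < cfg.height) & (cc >= 0) & (cc < cfg.width)
            shaft[rr[ok], cc[ok]] = 1.0
        a = max(2.0, cfg.cone_radius_px + fluct[fr, 0])
        b = max(2.0, 0.75 * cfg.cone_radius_px + fluct[fr, 1])
        th = orientations[fr]
        dx, dy = xx - cxf, yy - cyf
        u = dx * np.cos(th) + dy * np.sin(th)
        v = -dx * np.sin(th) + dy * np.cos(th)
        cone = ((u / a) ** 2 + (v / b) ** 2) <= 1.0
        depth = cfg.cone_depth * ndi.gaussian_filter(cone.astype(float), 1.0)
        depth += cfg.shaft_depth * ndi.gaussian_filter(shaft, 0.8)
        if cfg.background_polarity == "light":
            clean = cfg.background_level - depth
        else:
            clean = (cfg.background_level - cfg.cone_depth) + depth
        stack[fr] = clean + rng.normal(0.0, cfg.noise_sd, size=clean.shape)

    objects = pd.DataFrame(
        {"object_id": [0], "class": ["growth_cone"], "true_speed_um_s": [speed]}
    )
    positions = pd.DataFrame(
        {
            "object_id": 0,
            "frame": np.arange(n_frames),
            "x_px": centers[:, 0],
            "y_px": centers[:, 1],
        }
    )
    return ImageStack(stack, calib, ("dic",)), GroundTruth(objects, positions)


def true_mean_step_speed(gt: GroundTruth, calib: Calibration) -> float:
    """Mean per-step travel speed (µm/s) recomputed from a ground-truth table."""
    pos = gt.positions.sort_values("frame")
    d = np.hypot(np.diff(pos.x_px.to_numpy()), np.diff(pos.y_px.to_numpy()))
    dt = np.diff(pos.frame.to_numpy()) * calib.frame_interval_s
    return float(np.mean(d * calib.pixel_size_um / dt))


# ---------------------------------------------------------------------------
# immunofluorescence stills
# ---------------------------------------------------------------------------

@dataclass
class IFSceneConfig:
    """Configuration of a synthetic multi-channel immunofluorescence still.

    ``positive_fraction`` maps marker name -> fraction of cells positive for
    that marker; a marker listed in ``conditional_on`` is drawn positive with
    its fraction *within* the parent-positive population only (e.g. SMI32
    conditioned on MAP2). ``marker_intensity_pos`` may be one value for all
    markers or a per-marker mapping.
    """

    n_cells: int = 200
    width: int = 1024
    height: int = 1024
    markers: tuple[str, ...] = ("MAP2", "SMI32")
    positive_fraction: Mapping[str, float] = field(default_factory=lambda: {"MAP2": 0.7, "SMI32": 0.55})
    conditional_on: Mapping[str, str] = field(default_factory=dict)
    marker_intensity_pos: float | Mapping[str, float] = 120.0
    marker_intensity_neg: float = 5.0
    background_level: float = 20.0
    noise_sd: float = 3.0
    nucleus_radius_px: float = 5.0
    nucleus_amplitude: float = 150.0
    soma_radius_px: float = 9.0
    neurite_density: float = 0.0   # mean neurites per positive cell
    min_separation_px: float = 26.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        for m, f in self.positive_fraction.items():
            _validate_fraction(f"positive_fraction[{m}]", f)
        for m in self.markers:
            if m not in self.positive_fraction:
                raise ValueError(f"no positive_fraction for marker {m!r}")
        for child, parent in self.conditional_on.items():
            if child not in self.markers or parent not in self.markers:
                raise ValueError("conditional_on refers to unknown markers")

    def intensity_pos(self, marker: str) -> float:
        if isinstance(self.marker_intensity_pos, Mapping):
            return float(self.marker_intensity_pos[marker])
        return float(self.marker_intensity_pos)


def _place_cells(cfg: IFSceneConfig, rng: np.random.Generator) -> np.ndarray:
    margin = cfg.min_separation_px / 2.0
    capacity = int(0.5 * (cfg.width * cfg.height) / (cfg.min_separation_px**2))
    if cfg.n_cells > capacity:
        raise ValueError(
            f"{cfg.n_cells} cells do not fit a {cfg.width}x{cfg.height} canvas at "
            f"min separation {cfg.min_separation_px} px (~{capacity} cells)"
        )
    pts: list[tuple[float, float]] = []
    attempts = 0
    while len(pts) < cfg.n_cells:
        x = rng.uniform(margin, cfg.width - margin)
        y = rng.uniform(margin, cfg.height - margin)
        if all((x - px) ** 2 + (y - py) ** 2 >= cfg.min_separation_px**2 for px, py in pts):
            pts.append((x, y))
        attempts += 1
        if attempts > 200 * max(cfg.n_cells, 1):
            raise ValueError("could not place all cells; canvas too crowded")
    return np.asarray(pts) if pts else np.empty((0, 2))


def generate_if_image(config: IFSceneConfig) -> tuple[ImageStack, GroundTruth]:
    """Render a multi-channel IF still (Hoechst + marker channels) + ground truth.

    Channel 0 is the nuclei (Hoechst) channel; markers follow in the order of
    ``config.markers``. Draw order: 1) cell positions, 2) per-marker
    positivity (in marker order; conditional markers after their parent),
    3) neurite geometry, 4) per-channel noise.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    pts = _place_cells(cfg, rng)
    n = len(pts)

    positive: dict[str, np.ndarray] = {}
    for m in cfg.markers:
        draws = rng.random(n) < cfg.positive_fraction[m]
        parent = cfg.conditional_on.get(m)
        if parent is not None:
            draws = draws & positive[parent]
        positive[m] = draws

    shape = (cfg.height, cfg.width)
    channels = []
    nuc = np.full(shape, cfg.background_level / 2.0)
    sig_n = cfg.nucleus_radius_px / 1.5
    for x, y in pts:
        _spot_patch(cfg.nucleus_amplitude, sig_n, sig_n, x, y, shape, nuc)
    nuc += rng.normal(0.0, cfg.noise_sd, size=shape)
    channels.append(nuc)

    # one shared neurite geometry per cell, reused across marker channels
    neurites: list[np.ndarray] = []
    for x, y in pts:
        canvas = np.zeros(shape)
        k = rng.poisson(cfg.neurite_density) if cfg.neurite_density > 0 else 0
        for _ in range(k):
            ang = rng.uniform(0, 2 * np.pi)
            length = rng.uniform(40, 140)
            x1 = int(np.clip(x + length * np.cos(ang), 0, cfg.width - 1))
            y1 = int(np.clip(y + length * np.sin(ang), 0, cfg.height - 1))
            rr, cc = skdraw.line(int(y), int(x), y1, x1)
            canvas[rr, cc] = 1.0
        neurites.append(canvas)

    sig_s = cfg.soma_radius_px / 1.5
    for m in cfg.markers:
        ch = np.full(shape, cfg.background_level, dtype=float)
        amp_pos = cfg.intensity_pos(m)
        for i, (x, y) in enumerate(pts):
            amp = amp_pos if positive[m][i] else cfg.marker_intensity_neg
            _spot_patch(amp, sig_s, sig_s, x, y, shape, ch)
            if positive[m][i] and cfg.neurite_density > 0 and neurites[i].any():
                ch += 0.6 * amp * ndi.gaussian_filter(neurites[i], 1.0)
        ch += rng.normal(0.0, cfg.noise_sd, size=shape)
        channels.append(ch)

    data = np.stack(channels)[None].astype(np.float32)  # (1, C, H, W)
    names = ("hoechst",) + tuple(cfg.markers)
    objects = pd.DataFrame(
        {
            "object_id": np.arange(n),
            "x_px": pts[:, 0] if n else [],
            "y_px": pts[:, 1] if n else [],
            **{f"{m}_positive": positive[m] if n else [] for m in cfg.markers},
        }
    )
    calib = Calibration(pixel_size_nm=160.0, frame_interval_s=1.0, exposure_ms=None)
    return ImageStack(data, calib, names), GroundTruth(objects)
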