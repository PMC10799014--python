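"""Seeded synthetic fluorescence images with full ground truth.

Every image class the quantification pipeline consumes is emulated here:
crossbow-micropatterned cells bearing linear actin fibres (Gaussian
cross-section), elliptical focal-adhesion puncta, round nuclei, periodic
NMIIA puncta along fibres, isolated PLA-like foci fields, and two-front
wound-healing time-lapses with a known edge velocity.  Each generator
returns the rendered image(s) together with a :class:`GroundTruth` record
holding per-object masks and the true summary quantities against which the
detectors are scored.

All randomness flows from a single integer seed per call; the same spec and
seed reproduce bit-identical pixel arrays.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import tifffile

__all__ = [
    "PlacementError",
    "FibreSpec",
    "AdhesionSpec",
    "CellSpec",
    "WoundSpec",
    "CrossbowGeometry",
    "GroundTruth",
    "crossbow_geometry",
    "crossbow_mask",
    "generate_micropattern_cell",
    "generate_foci_image",
    "generate_wound_series",
    "write_image_set",
]

# Gaussian FWHM = 2*sqrt(2*ln 2) * sigma
FWHM_FACTOR = 2.0 * math.sqrt(2.0 * math.log(2.0))

MAX_INTENSITY = 65535.0  # 16-bit ceiling used for clipping


class PlacementError(ValueError):
    """An object does not fit inside the image bounds."""


@dataclass(frozen=True)
class FibreSpec:
    """One linear fibre: centre/length/orientation define the centreline,
    ``width`` is the FWHM of the Gaussian cross-section.

    Orientation follows the image convention used throughout the package:
    x rightward, y downward, angle in degrees within [-90, 90) measured
    from the x-axis with positive angles pointing up on screen.
    """

    centre: tuple[float, float]
    length: float
    width: float
    orientation: float = 0.0
    peak_intensity: float = 200.0
    nmiia_period: Optional[float] = None

    def __post_init__(self) -> None:
        if not (self.length > self.width > 0):
            raise ValueError("require length > width > 0")
        if self.nmiia_period is not None and self.nmiia_period <= 0:
            raise ValueError("nmiia_period must be positive")

    @property
    def endpoints(self) -> tuple[np.ndarray, np.ndarray]:
        theta = math.radians(self.orientation)
        # y grows downward, so a positive angle points up on screen
        d = np.array([math.cos(theta), -math.sin(theta)])
        c = np.asarray(self.centre, dtype=float)
        h = 0.5 * self.length
        return c - h * d, c + h * d


@dataclass(frozen=True)
class AdhesionSpec:
    """One elliptical focal-adhesion plaque (axes are full extents)."""

    centre: tuple[float, float]
    major_axis: float
    minor_axis: float
    orientation: float = 0.0
    peak_intensity: float = 200.0

    def __post_init__(self) -> None:
        if not (self.major_axis >= self.minor_axis > 0):
            raise ValueError("require major_axis >= minor_axis > 0")


@dataclass(frozen=True)
class CellSpec:
    """Parameters of one synthetic micropatterned cell image."""

    pattern_shape: str = "crossbow"
    image_size: int = 256
    pixel_size: float = 0.2
    fibres: tuple[FibreSpec, ...] = ()
    adhesions: tuple[AdhesionSpec, ...] = ()
    n_nuclei: int = 1
    noise_sd: float = 0.0
    background: float = 10.0
    seed: int = 0
    nucleus_radius: float = 14.0
    nucleus_intensity: float = 220.0
    pattern_intensity: float = 40.0

    def __post_init__(self) -> None:
        if self.pattern_shape not in ("crossbow", "disc", "none"):
            raise ValueError(f"unknown pattern_shape {self.pattern_shape!r}")
        if self.image_size < 64:
            raise ValueError("image_size must be >= 64")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be >= 0")
        for f in self.fibres:
            if f.peak_intensity <= self.background:
                raise ValueError("fibre peak_intensity must exceed background")
        object.__setattr__(self, "fibres", tuple(self.fibres))
        object.__setattr__(self, "adhesions", tuple(self.adhesions))


@dataclass(frozen=True)
class WoundSpec:
    """Two-front wound time-lapse: a vertical cell-free band that narrows
    symmetrically at ``edge_velocity`` (um/h) per front.

    True width at frame k is max(0, initial_width - 2*edge_velocity*k*dt).
    """

    frame_size: int = 512
    pixel_size: float = 2.0
    initial_width: float = 500.0
    edge_velocity: float = 10.0
    dt: float = 1.0
    n_frames: int = 12
    texture_sd: float = 12.0
    seed: int = 0
    cell_intensity: float = 120.0
    background: float = 10.0

    def __post_init__(self) -> None:
        if self.initial_width <= 0:
            raise ValueError("initial_width must be positive")
        if self.edge_velocity < 0:
            raise ValueError("edge_velocity must be >= 0")
        if self.n_frames < 1 or self.dt <= 0 or self.pixel_size <= 0:
            raise ValueError("invalid frame geometry")

    def true_width(self, k: int) -> float:
        return max(0.0, self.initial_width - 2.0 * self.edge_velocity * k * self.dt)


@dataclass(frozen=True)
class CrossbowGeometry:
    """Parametric crossbow: a circular arc (the curved leading edge) plus a
    straight stem from the arc's centre of curvature to the trailing edge."""

    centre: tuple[float, float]
    radius: float
    arc_start_deg: float = -15.0
    arc_end_deg: float = 195.0
    bar_width: float = 6.0

    def arc_points(self, n: int = 720) -> np.ndarray:
        """Densely sampled (x, y) points on the arc, y downward."""
        t = np.radians(np.linspace(self.arc_start_deg, self.arc_end_deg, n))
        cx, cy = self.centre
        return np.column_stack([cx + self.radius * np.cos(t), cy - self.radius * np.sin(t)])

    def distance_to_arc(self, point: Sequence[float]) -> float:
        """Exact Euclidean distance from a point to the arc (px)."""
        cx, cy = self.centre
        dx = point[0] - cx
        dy = cy - point[1]  # flip to y-up for the angle
        ang = math.degrees(math.atan2(dy, dx))
        lo, hi = self.arc_start_deg, self.arc_end_deg
        # bring the angle into [lo, lo+360)
        ang = lo + (ang - lo) % 360.0
        r = math.hypot(dx, dy)
        if ang <= hi:
            return abs(r - self.radius)
        ends = [math.radians(a) for a in (lo, hi)]
        return min(
            math.hypot(
                point[0] - (cx + self.radius * math.cos(a)),
                point[1] - (cy - self.radius * math.sin(a)),
            )
            for a in ends
        )


def crossbow_geometry(image_size: int, radius_frac: float = 0.38, bar_width: float = 6.0) -> CrossbowGeometry:
    c = (image_size / 2.0, image_size / 2.0)
    return CrossbowGeometry(centre=c, radius=radius_frac * image_size, bar_width=bar_width)


def _grid(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return xx.astype(float), yy.astype(float)


def crossbow_mask(image_size: int, geometry: Optional[CrossbowGeometry] = None) -> np.ndarray:
    """Binary crossbow pattern: arc band + stem bar."""
    g = geometry or crossbow_geometry(image_size)
    xx, yy = _grid((image_size, image_size))
    cx, cy = g.centre
    dx, dy = xx - cx, cy - yy
    r = np.hypot(dx, dy)
    ang = np.degrees(np.arctan2(dy, dx))
    ang = g.arc_start_deg + (ang - g.arc_start_deg) % 360.0
    on_arc = (np.abs(r - g.radius) <= g.bar_width / 2.0) & (ang <= g.arc_end_deg)
    stem = (np.abs(xx - cx) <= g.bar_width / 2.0) & (yy >= cy) & (yy <= cy + g.radius)
    return on_arc | stem


def _point_segment_distance(xx: np.ndarray, yy: np.ndarray, p0: np.ndarray, p1: np.ndarray) -> np.ndarray:
    v = p1 - p0
    vv = float(v @ v)
    if vv == 0.0:
        return np.hypot(xx - p0[0], yy - p0[1])
    t = ((xx - p0[0]) * v[0] + (yy - p0[1]) * v[1]) / vv
    t = np.clip(t, 0.0, 1.0)
    return np.hypot(xx - (p0[0] + t * v[0]), yy - (p0[1] + t * v[1]))


def _render_fibre(shape: tuple[int, int], f: FibreSpec) -> np.ndarray:
    xx, yy = _grid(shape)
    p0, p1 = f.endpoints
    d = _point_segment_distance(xx, yy, p0, p1)
    sigma = f.width / FWHM_FACTOR
    return f.peak_intensity * np.exp(-0.5 * (d / sigma) ** 2)


def _render_nmiia_puncta(shape: tuple[int, int], f: FibreSpec) -> np.ndarray:
    """Gaussian puncta spaced ``nmiia_period`` px along the fibre axis."""
    assert f.nmiia_period is not None
    p0, p1 = f.endpoints
    axis = (p1 - p0) / f.length
    sigma = f.width / FWHM_FACTOR
    xx, yy = _grid(shape)
    out = np.zeros(shape, dtype=float)
    for s in np.arange(0.5 * f.nmiia_period, f.length, f.nmiia_period):
        c = p0 + axis * s
        d = np.hypot(xx - c[0], yy - c[1])
        out += f.peak_intensity * np.exp(-0.5 * (d / sigma) ** 2)
    return out


def _render_ellipse(shape: tuple[int, int], a: AdhesionSpec) -> tuple[np.ndarray, np.ndarray]:
    xx, yy = _grid(shape)
    theta = math.radians(a.orientation)
    dx, dy = xx - a.centre[0], a.centre[1] - yy  # y-up for the rotation
    u = dx * math.cos(theta) + dy * math.sin(theta)
    v = -dx * math.sin(theta) + dy * math.cos(theta)
    # Gaussian profile whose half-max contour is the declared ellipse
    sa = (a.major_axis / 2.0) / math.sqrt(2.0 * math.log(2.0))
    sb = (a.minor_axis / 2.0) / math.sqrt(2.0 * math.log(2.0))
    q = (u / sa) ** 2 + (v / sb) ** 2
    img = a.peak_intensity * np.exp(-0.5 * q)
    mask = q <= 2.0 * math.log(2.0)  # inside the half-max contour
    return img, mask


@dataclass
class GroundTruth:
    """Generator-side truth: the spec echo, per-object pixel masks, and the
    derived true summaries every detector is scored against."""

    kind: str
    spec: object
    masks: dict[str, np.ndarray] = field(default_factory=dict)
    objects: list[dict] = field(default_factory=list)
    summaries: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        def scrub(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return {k: scrub(v) for k, v in dataclasses.asdict(o).items()}
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, dict):
                return {k: scrub(v) for k, v in o.items()}
            if isinstance(o, (list, tuple)):
                return [scrub(v) for v in o]
            return o

        return {
            "kind": self.kind,
            "spec": scrub(self.spec),
            "objects": scrub(self.objects),
            "summaries": scrub(self.summaries),
        }


def _check_inside(name: str, xmin: float, xmax: float, ymin: float, ymax: float, size: int) -> None:
    if xmin < 0 or ymin < 0 or xmax > size - 1 or ymax > size - 1:
        raise PlacementError(f"{name} extends outside the {size}x{size} image")


def generate_micropattern_cell(spec: CellSpec) -> tuple[dict[str, np.ndarray], GroundTruth]:
    """Render one multi-channel micropatterned cell.

    Channels: ``actin`` (fibres), ``vinculin`` (adhesions), ``dapi``
    (nuclei) and, when any fibre declares an ``nmiia_period``, ``nmiia``
    (periodic puncta along those fibres).  Channels are additive object
    profiles + background + i.i.d. Gaussian noise, clipped to the 16-bit
    range.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.image_size
    shape = (n, n)

    truth = GroundTruth(kind="cell", spec=spec)
    geometry = crossbow_geometry(n) if spec.pattern_shape == "crossbow" else None
    if geometry is not None:
        truth.masks["pattern"] = crossbow_mask(n, geometry)
        truth.summaries["geometry"] = geometry

    actin = np.zeros(shape, dtype=float)
    if geometry is not None and spec.pattern_intensity > 0:
        # phalloidin outlines the adhesive pattern the cell spreads on
        actin += spec.pattern_intensity * truth.masks["pattern"]
    nmiia = np.zeros(shape, dtype=float)
    has_nmiia = any(f.nmiia_period is not None for f in spec.fibres)
    for i, f in enumerate(spec.fibres):
        p0, p1 = f.endpoints
        pad = f.width
        _check_inside(
            f"fibre {i}",
            min(p0[0], p1[0]) - pad,
            max(p0[0], p1[0]) + pad,
            min(p0[1], p1[1]) - pad,
            max(p0[1], p1[1]) + pad,
            n,
        )
        prof = _render_fibre(shape, f)
        actin += prof
        mask = prof >= 0.5 * f.peak_intensity  # half-max support
        truth.masks[f"fibre_{i}"] = mask
        truth.objects.append({"type": "fibre", "index": i, "params": f})
        if f.nmiia_period is not None:
            nmiia += _render_nmiia_puncta(shape, f)

    vinculin = np.zeros(shape, dtype=float)
    for i, a in enumerate(spec.adhesions):
        half = a.major_axis / 2.0 + 1
        _check_inside(
            f"adhesion {i}",
            a.centre[0] - half,
            a.centre[0] + half,
            a.centre[1] - half,
            a.centre[1] + half,
            n,
        )
        prof, mask = _render_ellipse(shape, a)
        vinculin += prof
        truth.masks[f"adhesion_{i}"] = mask
        truth.objects.append({"type": "adhesion", "index": i, "params": a})

    dapi = np.zeros(shape, dtype=float)
    xx, yy = _grid(shape)
    centres = _place_nuclei(spec, rng, geometry)
    for i, c in enumerate(centres):
        d = np.hypot(xx - c[0], yy - c[1])
        dapi += spec.nucleus_intensity * np.exp(-0.5 * (d / (spec.nucleus_radius / 2.0)) ** 2)
        truth.masks[f"nucleus_{i}"] = d <= spec.nucleus_radius
        truth.objects.append({"type": "nucleus", "index": i, "centre": tuple(c)})

    channels = {"actin": actin, "vinculin": vinculin, "dapi": dapi}
    if has_nmiia:
        channels["nmiia"] = nmiia
    out: dict[str, np.ndarray] = {}
    for name, img in channels.items():
        img = img + spec.background
        if spec.noise_sd > 0:
            img = img + rng.normal(0.0, spec.noise_sd, size=shape)
        out[name] = np.clip(img, 0.0, MAX_INTENSITY)

    truth.summaries.update(
        {
            "n_fibres": len(spec.fibres),
            "n_adhesions": len(spec.adhesions),
            "n_nuclei": spec.n_nuclei,
            "nucleus_centres": [tuple(c) for c in centres],
        }
    )
    return out, truth


def _place_nuclei(spec: CellSpec, rng: np.random.Generator, geometry: Optional[CrossbowGeometry]) -> list[np.ndarray]:
    """Disjoint nucleus discs near the pattern centre."""
    if spec.n_nuclei == 0:
        return []
    c0 = np.array([spec.image_size / 2.0, spec.image_size / 2.0])
    r = spec.nucleus_radius
    centres: list[np.ndarray] = []
    for _ in range(2000):
        if len(centres) == spec.n_nuclei:
            break
        cand = c0 + rng.uniform(-3.0 * r, 3.0 * r, size=2)
        if cand[0] - r < 1 or cand[1] - r < 1 or cand[0] + r > spec.image_size - 2 or cand[1] + r > spec.image_size - 2:
            continue
        if all(np.hypot(*(cand - c)) >= 2.0 * r + 2.0 for c in centres):
            centres.append(cand)
    if len(centres) < spec.n_nuclei:
        raise PlacementError("could not place the requested number of nuclei")
    return centres


def generate_foci_image(
    n_foci: int,
    min_separation: float = 12.0,
    spot_sigma: float = 1.5,
    noise_sd: float = 0.0,
    seed: int = 0,
    image_size: int = 256,
    background: float = 10.0,
    peak_intensity: float = 150.0,
) -> tuple[np.ndarray, GroundTruth]:
    """Field of resolvable Gaussian foci emulating a PLA image.

    ``min_separation`` must exceed 4*spot_sigma so that every spot is an
    isolated connected component above background.
    """
    if n_foci < 0:
        raise ValueError("n_foci must be >= 0")
    if n_foci > 0 and min_separation <= 4.0 * spot_sigma:
        raise ValueError("min_separation must exceed 4*spot_sigma")
    rng = np.random.default_rng(seed)
    margin = max(4.0 * spot_sigma, 4.0)
    centres: list[np.ndarray] = []
    tries = 0
    while len(centres) < n_foci:
        tries += 1
        if tries > 20000:
            raise PlacementError("could not place foci at the requested separation")
        cand = rng.uniform(margin, image_size - 1 - margin, size=2)
        if all(np.hypot(*(cand - c)) >= min_separation for c in centres):
            centres.append(cand)

    xx, yy = _grid((image_size, image_size))
    img = np.full((image_size, image_size), background, dtype=float)
    truth = GroundTruth(kind="foci", spec={"n_foci": n_foci, "min_separation": min_separation, "spot_sigma": spot_sigma, "noise_sd": noise_sd, "seed": seed})
    for i, c in enumerate(centres):
        d = np.hypot(xx - c[0], yy - c[1])
        img += peak_intensity * np.exp(-0.5 * (d / spot_sigma) ** 2)
        truth.masks[f"focus_{i}"] = d <= 2.0 * spot_sigma
        truth.objects.append({"type": "focus", "index": i, "centre": tuple(c)})
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    img = np.clip(img, 0.0, MAX_INTENSITY)
    truth.summaries = {"n_foci": n_foci, "centres": [tuple(c) for c in centres]}
    return img, truth


def generate_wound_series(spec: WoundSpec) -> tuple[np.ndarray, GroundTruth]:
    """Time-lapse stack of a vertical wound closing from both fronts.

    Cell regions carry Gaussian texture of sd ``texture_sd``; the wound band
    is near-background.  Frame k's true width (um) follows the two-front
    linear law and clamps at zero once closed.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.frame_size
    xx, _ = _grid((n, n))
    cx = n / 2.0
    frames = np.empty((spec.n_frames, n, n), dtype=float)
    widths, areas = [], []
    field_height_um = n * spec.pixel_size
    for k in range(spec.n_frames):
        w_um = spec.true_width(k)
        w_px = w_um / spec.pixel_size
        wound = np.abs(xx - cx) < w_px / 2.0
        frame = np.where(wound, spec.background, spec.cell_intensity)
        noise_sd = np.where(wound, 0.1 * spec.texture_sd, spec.texture_sd)
        frame = frame + rng.normal(0.0, 1.0, size=frame.shape) * noise_sd
        frames[k] = np.clip(frame, 0.0, MAX_INTENSITY)
        widths.append(w_um)
        areas.append(w_um * field_height_um)
    truth = GroundTruth(
        kind="wound",
        spec=spec,
        summaries={
            "times_h": [k * spec.dt for k in range(spec.n_frames)],
            "widths_um": widths,
            "areas_um2": areas,
        },
    )
    return frames, truth


def write_image_set(path: str, images: dict[str, np.ndarray] | np.ndarray, truth: GroundTruth) -> None:
    """Write a multi-page TIFF (one page per channel / time point) plus a
    JSON sidecar naming every generated object and its parameters."""
    if isinstance(images, dict):
        pages = np.stack([images[k] for k in sorted(images)])
        names = sorted(images)
    else:
        pages = np.asarray(images)
        names = [f"t{k}" for k in range(pages.shape[0])]
    tifffile.imwrite(path, np.clip(pages, 0, MAX_INTENSITY).astype(np.uint16), photometric="minisblack")
    side = dict(truth.to_json_dict())
    side["pages"] = names
    with open(str(path) + ".json", "w") as fh:
        json.dump(side, fh, indent=1)
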