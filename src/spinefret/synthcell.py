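"""Synthetic imaging scenes with exact ground truth.

Every downstream stage of the package — FRET ratio time courses, F/G-actin
fraction maps, spine morphometry, cell-shape statistics — is validated
against scenes rendered here, because the original acquisitions are not
publicly deposited.  Four scene kinds are provided:

``fret_timelapse``
    Two-channel (donor mTurquoise, acceptor YPet) time-lapse with spine-like
    ROIs.  A programmed subset of ROIs ("responders") steps its
    acceptor/donor ratio by a chosen fraction from the treatment frame
    onward.  Degradations are applied in the physical order an instrument
    would produce them: per-channel multiplicative linear photobleaching,
    lateral stage drift (subpixel, linear interpolation), then shot
    (Poisson) plus read (Gaussian) noise.

``actin_dualstain``
    Dual-channel F-actin / G-actin stain of a round cell with the F-channel
    enriched in a band inside the contour, so the true F-actin fraction is
    0.5 in the interior and 0.5 + enrichment/2 at the membrane.

``dendrite_spines``
    A dendritic shaft bearing spines of parameterised length, neck width
    and head width, one label per spine.

``cell_silhouette``
    Binary cell silhouettes of known compactness from parametric polygon
    families (convex, cross, star, lobed).

Rendering is float64 throughout; quantisation happens only on write.
Ground truth stays in the frame-0 coordinate system — drift is something
registration must undo, not something the truth follows.  A single integer
seed drives a hierarchical RNG (scene → object → frame), so identical
``SceneSpec`` + seed gives bit-identical output.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy import ndimage
from shapely.geometry import Polygon
from skimage.draw import polygon as draw_polygon

from spinefret.imgcore import CalibratedStack, LabelMask
from spinefret.spinemorph import SpineGeometry, classify_spine

__all__ = [
    "SceneSpec",
    "GroundTruth",
    "make_fret_scene",
    "make_actin_scene",
    "make_dendrite_scene",
    "make_cell_silhouette",
]

SCENE_KINDS = (
    "fret_timelapse",
    "actin_dualstain",
    "dendrite_spines",
    "cell_silhouette",
)


@dataclass
class SceneSpec:
    """Parameters shared by all synthetic scenes.

    Calibration defaults match a confocal single-spine acquisition:
    0.07 µm lateral pixels, 0.35 µm z-steps, one frame every 2.5 min
    with three baseline frames before treatment.  ``bleach_rate`` is the
    fractional intensity loss per frame, either one scalar for all
    channels or one value per channel; ``drift_per_frame`` is the lateral
    stage drift in pixels per frame (row, col).  ``poisson_scale`` is the
    photon count per intensity unit (0 disables shot noise) and
    ``gaussian_sd`` the read-noise standard deviation in intensity units.
    """

    scene_kind: str
    shape: tuple[int, int] = (200, 200)  # (Y, X) px
    n_frames: int = 12
    n_z: int = 1
    pixel_size_xy: float = 0.07
    z_step: float = 0.35
    frame_interval: float = 2.5
    baseline_frames: int = 3
    background_level: float = 20.0
    poisson_scale: float = 0.0
    gaussian_sd: float = 0.0
    bleach_rate: float | tuple[float, ...] = 0.0
    drift_per_frame: tuple[float, float] = (0.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scene_kind not in SCENE_KINDS:
            raise ValueError(f"unknown scene_kind {self.scene_kind!r}")
        for name in ("pixel_size_xy", "z_step", "frame_interval"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.n_frames < 1 or self.n_z < 1:
            raise ValueError("n_frames and n_z must be >= 1")
        if self.baseline_frames < 2:
            raise ValueError("baseline_frames must be >= 2 (a line needs 2 points)")
        if self.background_level < 0 or self.gaussian_sd < 0:
            raise ValueError("background_level and gaussian_sd must be >= 0")
        if self.poisson_scale < 0:
            raise ValueError("poisson_scale must be >= 0")
        rates = np.atleast_1d(np.asarray(self.bleach_rate, dtype=float))
        if np.any(rates < 0) or np.any(rates >= 1):
            raise ValueError("bleach_rate must be in [0, 1) per frame")

    def bleach_rates(self, n_channels: int) -> np.ndarray:
        rates = np.atleast_1d(np.asarray(self.bleach_rate, dtype=float))
        if rates.size == 1:
            return np.full(n_channels, rates[0])
        if rates.size != n_channels:
            raise ValueError(
                f"{rates.size} bleach rates for {n_channels} channels"
            )
        return rates

    @classmethod
    def from_yaml(cls, path) -> "SceneSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "shape" in raw:
            raw["shape"] = tuple(raw["shape"])
        if "drift_per_frame" in raw:
            raw["drift_per_frame"] = tuple(raw["drift_per_frame"])
        if isinstance(raw.get("bleach_rate"), list):
            raw["bleach_rate"] = tuple(raw["bleach_rate"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["shape"] = list(self.shape)
        d["drift_per_frame"] = list(self.drift_per_frame)
        if isinstance(d["bleach_rate"], tuple):
            d["bleach_rate"] = list(d["bleach_rate"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)


@dataclass
class GroundTruth:
    """The true values a scene was rendered from.

    Only the fields relevant to the scene kind are populated.
    """

    label_masks: np.ndarray | None = None
    responder_ids: tuple[int, ...] | None = None
    step_amplitude: float | None = None
    true_ratio: np.ndarray | None = None  # (n_rois, T)
    roi_ids: tuple[int, ...] | None = None
    spine_geometries: list[SpineGeometry] | None = None
    spine_classes: tuple[str, ...] | None = None
    shaft_mask: np.ndarray | None = None
    fr_map: np.ndarray | None = None  # true F-actin fraction, NaN outside
    cell_mask: np.ndarray | None = None
    contour_um: np.ndarray | None = None  # (n, 2) row/col in µm
    membrane_enrichment: float | None = None
    ring_width_um: float | None = None
    true_compactness: float | None = None
    polygon_um: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.responder_ids is not None and self.label_masks is not None:
            present = set(np.unique(self.label_masks).tolist())
            missing = set(self.responder_ids) - present
            if missing:
                raise ValueError(f"responder ids {missing} absent from masks")
        if self.true_ratio is not None and np.any(self.true_ratio <= 0):
            raise ValueError("true_ratio must be strictly positive")

    def to_json(self, path) -> None:
        def enc(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            if isinstance(v, (np.bool_, np.integer)):
                return int(v)
            if isinstance(v, np.floating):
                return float(v)
            if isinstance(v, SpineGeometry):
                return {
                    "length": v.length,
                    "neck_width": v.neck_width,
                    "head_width": v.head_width,
                }
            if isinstance(v, (list, tuple)):
                return [enc(x) for x in v]
            if isinstance(v, dict):
                return {str(k): enc(x) for k, x in v.items()}
            return v

        # skip asdict: it would recurse into arrays and geometries itself
        d = {
            f.name: enc(getattr(self, f.name))
            for f in dataclasses.fields(self)
            if getattr(self, f.name) is not None
        }
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)


# ---------------------------------------------------------------------------
# Shared rendering helpers
# ---------------------------------------------------------------------------

def _rng_tree(seed: int, n_children: int) -> list[np.random.Generator]:
    """Hierarchical RNG: one child generator per object/frame."""
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(c) for c in ss.spawn(n_children)]


def _apply_drift(frame: np.ndarray, shift: tuple[float, float], fill: float) -> np.ndarray:
    """Translate a 2D frame by a subpixel shift (linear interpolation)."""
    if shift[0] == 0 and shift[1] == 0:
        return frame
    return ndimage.shift(frame, shift, order=1, mode="constant", cval=fill)


def _apply_noise(img: np.ndarray, spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    """Shot noise (Poisson at `poisson_scale` photons/a.u.) plus read noise."""
    out = img
    if spec.poisson_scale > 0:
        out = rng.poisson(np.clip(out, 0, None) * spec.poisson_scale) / spec.poisson_scale
    if spec.gaussian_sd > 0:
        out = out + rng.normal(0.0, spec.gaussian_sd, size=img.shape)
    return np.asarray(out, dtype=np.float64)


# ---------------------------------------------------------------------------
# FRET time-lapse
# ---------------------------------------------------------------------------

def make_fret_scene(
    spec: SceneSpec,
    n_rois: int = 20,
    responder_fraction: float = 0.5,
    step_amplitude: float = 0.3,
    *,
    roi_radius_px: float = 5.0,
    signal_amplitude: float = 100.0,
    baseline_ratio_range: tuple[float, float] = (0.9, 1.1),
) -> tuple[CalibratedStack, LabelMask, GroundTruth]:
    """Render a two-channel FRET time-lapse with programmed responders.

    A responder ROI multiplies its acceptor/donor ratio by
    ``1 + step_amplitude`` from the treatment frame onward (negative
    steps model inhibition).  The acceptor channel is the donor times the
    true ratio pixel-for-pixel, so with all degradations off the scene
    round-trips exactly through the ratio formula.
    """
    if spec.scene_kind != "fret_timelapse":
        raise ValueError("spec.scene_kind must be 'fret_timelapse'")
    if n_rois < 1:
        raise ValueError("n_rois must be >= 1")
    if not 0.0 <= responder_fraction <= 1.0:
        raise ValueError("responder_fraction must be in [0, 1]")
    if step_amplitude <= -1.0:
        raise ValueError("step_amplitude must be > -1 (ratio stays positive)")

    Y, X = spec.shape
    T = spec.n_frames
    if spec.baseline_frames >= T:
        raise ValueError("baseline_frames must be < n_frames")
    tf = spec.baseline_frames  # first post-treatment frame

    rng_scene, rng_noise = _rng_tree(spec.seed, 2)

    # ROI layout: jittered grid of discs, kept clear of the border so
    # drift does not carry objects out of frame.
    margin = int(np.ceil(roi_radius_px + 4 + T * (abs(spec.drift_per_frame[0]) + abs(spec.drift_per_frame[1]))))
    margin = min(margin, min(Y, X) // 4)
    grid = int(np.ceil(np.sqrt(n_rois)))
    ys = np.linspace(margin, Y - margin, grid)
    xs = np.linspace(margin, X - margin, grid)
    centers = [(y, x) for y in ys for x in xs][:n_rois]

    labels = np.zeros((Y, X), dtype=np.uint16)
    yy, xx = np.mgrid[0:Y, 0:X]
    for i, (cy, cx) in enumerate(centers, start=1):
        disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= roi_radius_px**2
        labels[disc] = i
    roi_ids = tuple(range(1, n_rois + 1))

    n_resp = int(round(responder_fraction * n_rois))
    responder_ids = tuple(
        int(i) for i in sorted(rng_scene.permutation(n_rois)[:n_resp] + 1)
    ) if n_resp else ()

    # Per-ROI donor brightness and baseline ratio.
    amps = signal_amplitude * rng_scene.uniform(0.8, 1.2, size=n_rois)
    lo, hi = baseline_ratio_range
    base_ratio = rng_scene.uniform(lo, hi, size=n_rois)

    true_ratio = np.tile(base_ratio[:, None], (1, T))
    for rid in responder_ids:
        true_ratio[rid - 1, tf:] *= 1.0 + step_amplitude

    rates = spec.bleach_rates(2)  # (donor, acceptor)
    frame_rngs = _rng_tree(int(rng_noise.integers(2**31)), T)

    voxels = np.empty((T, spec.n_z, 2, Y, X))
    for t in range(T):
        donor = np.full((Y, X), float(spec.background_level))
        acceptor = np.full((Y, X), float(spec.background_level))
        for i in range(n_rois):
            disc = labels == (i + 1)
            donor[disc] += amps[i]
            acceptor[disc] += amps[i] * true_ratio[i, t]
        # per-channel linear multiplicative bleach
        donor *= max(1.0 - rates[0] * t, 1e-3)
        acceptor *= max(1.0 - rates[1] * t, 1e-3)
        shift = (spec.drift_per_frame[0] * t, spec.drift_per_frame[1] * t)
        donor = _apply_drift(donor, shift, spec.background_level)
        acceptor = _apply_drift(acceptor, shift, spec.background_level)
        donor = _apply_noise(donor, spec, frame_rngs[t])
        acceptor = _apply_noise(acceptor, spec, frame_rngs[t])
        for z in range(spec.n_z):
            voxels[t, z, 0] = donor
            voxels[t, z, 1] = acceptor

    stack = CalibratedStack(
        voxels=voxels,
        pixel_size_xy=spec.pixel_size_xy,
        z_step=spec.z_step,
        frame_interval=spec.frame_interval,
        channel_names=("mTurquoise", "YPet"),
        treatment_frame=tf,
    )
    truth = GroundTruth(
        label_masks=labels,
        roi_ids=roi_ids,
        responder_ids=responder_ids,
        step_amplitude=step_amplitude,
        true_ratio=true_ratio,
    )
    return stack, LabelMask(labels, roles={i: "spine" for i in roi_ids}), truth


# ---------------------------------------------------------------------------
# Actin dual stain
# ---------------------------------------------------------------------------

def make_actin_scene(
    spec: SceneSpec,
    enrichment: float = 0.4,
    ring_width_um: float = 1.0,
    *,
    cell_radius_fraction: float = 0.35,
    total_actin: float = 200.0,
) -> tuple[CalibratedStack, GroundTruth]:
    """Render a dual-channel F/G-actin stain with membrane enrichment.

    Total actin (F + G) is uniform inside the cell; the F channel takes
    fraction ``0.5 + enrichment/2`` of it within ``ring_width_um`` of the
    contour and 0.5 elsewhere, mirroring cortical F-actin enrichment at
    the plasma membrane.
    """
    if spec.scene_kind != "actin_dualstain":
        raise ValueError("spec.scene_kind must be 'actin_dualstain'")
    if not 0.0 <= enrichment <= 1.0:
        raise ValueError("enrichment must be in [0, 1]")
    Y, X = spec.shape
    radius_px = cell_radius_fraction * min(Y, X)
    radius_um = radius_px * spec.pixel_size_xy
    if ring_width_um <= 0:
        raise ValueError("ring_width_um must be positive")
    if ring_width_um >= radius_um:
        raise ValueError(
            f"ring width {ring_width_um} µm exceeds the cell radius "
            f"{radius_um:.2f} µm"
        )

    cy, cx = (Y - 1) / 2.0, (X - 1) / 2.0
    yy, xx = np.mgrid[0:Y, 0:X]
    r = np.hypot(yy - cy, xx - cx)
    cell = r <= radius_px
    depth_um = (radius_px - r) * spec.pixel_size_xy  # distance inside contour

    fr_true = np.full((Y, X), np.nan)
    fr_true[cell] = 0.5
    band = cell & (depth_um <= ring_width_um)
    fr_true[band] = 0.5 + enrichment / 2.0

    f_img = np.full((Y, X), float(spec.background_level))
    g_img = np.full((Y, X), float(spec.background_level))
    f_img[cell] += total_actin * fr_true[cell]
    g_img[cell] += total_actin * (1.0 - fr_true[cell])

    (rng,) = _rng_tree(spec.seed, 1)
    f_img = _apply_noise(f_img, spec, rng)
    g_img = _apply_noise(g_img, spec, rng)

    theta = np.linspace(0, 2 * np.pi, 360, endpoint=False)
    contour_um = np.column_stack(
        [cy + radius_px * np.sin(theta), cx + radius_px * np.cos(theta)]
    ) * spec.pixel_size_xy

    voxels = np.stack([f_img, g_img])[None, None]  # (1,1,2,Y,X)
    stack = CalibratedStack(
        voxels=voxels,
        pixel_size_xy=spec.pixel_size_xy,
        z_step=spec.z_step,
        frame_interval=spec.frame_interval,
        channel_names=("F-actin", "G-actin"),
    )
    truth = GroundTruth(
        fr_map=fr_true,
        cell_mask=cell,
        contour_um=contour_um,
        membrane_enrichment=enrichment,
        ring_width_um=ring_width_um,
    )
    return stack, truth


# ---------------------------------------------------------------------------
# Dendrite with spines
# ---------------------------------------------------------------------------

def make_dendrite_scene(
    spec: SceneSpec,
    spines: list[SpineGeometry],
    *,
    shaft_width_um: float = 1.0,
    signal_amplitude: float = 100.0,
) -> tuple[CalibratedStack, LabelMask, GroundTruth]:
    """Render a horizontal dendritic shaft with labelled spines on top.

    Each spine is a neck rectangle (``neck_width`` wide) topped by a head
    disc (``head_width`` diameter) whose centre sits ``head_width/2``
    below the tip, so the base-to-tip extent equals ``length``.  Spines
    are placed at integer pixel columns with spacing wide enough that
    masks never overlap.
    """
    if spec.scene_kind != "dendrite_spines":
        raise ValueError("spec.scene_kind must be 'dendrite_spines'")
    if not spines:
        raise ValueError("spine list must be non-empty")

    Y, X = spec.shape
    px = spec.pixel_size_xy
    shaft_half = shaft_width_um / 2.0 / px
    base_row = int(round(Y * 0.7))  # shaft top edge; spines grow upward
    shaft = np.zeros((Y, X), dtype=bool)
    shaft[base_row : int(round(base_row + 2 * shaft_half)), :] = True

    n = len(spines)
    max_w = max(max(g.head_width, g.neck_width) for g in spines) / px
    margin = int(np.ceil(max_w / 2)) + 3
    if X - 2 * margin < (n - 1) * (max_w + 4):
        raise ValueError("spines would overlap along the shaft; fewer or wider image")
    # subpixel column jitter: real spines sit at arbitrary positions, and
    # pinning them to pixel centres would systematically round rasterised
    # widths up by half a pixel
    rng_pos, rng_noise = _rng_tree(spec.seed, 2)
    cols = np.round(np.linspace(margin, X - 1 - margin, n)).astype(
        float
    ) + rng_pos.uniform(-0.5, 0.5, size=n)

    labels = np.zeros((Y, X), dtype=np.uint16)
    yy, xx = np.mgrid[0:Y, 0:X]
    for i, (g, c0) in enumerate(zip(spines, cols), start=1):
        L = g.length / px
        neck_half = g.neck_width / 2.0 / px
        head_r = g.head_width / 2.0 / px
        if base_row - L < 1:
            raise ValueError(
                f"spine {i} (length {g.length} µm) does not fit in the image"
            )
        # depth of a pixel above the shaft edge, in px (0 at edge)
        depth = base_row - 0.5 - yy
        head_cy = base_row - 0.5 - (L - head_r)
        neck = (
            (np.abs(xx - c0) <= neck_half)
            & (depth > 0)
            & (yy >= head_cy)
        )
        head = (
            ((yy - head_cy) ** 2 + (xx - c0) ** 2 <= head_r**2)
            & (depth > 0)
        )
        region = neck | head
        if (labels[region] != 0).any():
            raise ValueError(f"spine {i} overlaps a previously placed spine")
        labels[region] = i

    img = np.full((Y, X), float(spec.background_level))
    img[shaft | (labels > 0)] += signal_amplitude
    img = _apply_noise(img, spec, rng_noise)

    stack = CalibratedStack(
        voxels=img[None, None, None],
        pixel_size_xy=px,
        z_step=spec.z_step,
        frame_interval=spec.frame_interval,
        channel_names=("Cerulean",),
    )
    truth = GroundTruth(
        label_masks=labels,
        shaft_mask=shaft,
        spine_geometries=list(spines),
        spine_classes=tuple(classify_spine(g).label for g in spines),
    )
    roles = {i + 1: "spine" for i in range(n)}
    return stack, LabelMask(labels, roles=roles), truth


# ---------------------------------------------------------------------------
# Cell silhouettes
# ---------------------------------------------------------------------------

def _silhouette_polygon(
    shape_family: str, params: dict, rng: np.random.Generator
) -> np.ndarray:
    """Vertex polygon (row, col in px) for one silhouette family."""
    p = dict(params or {})
    radius = p.pop("radius_px", 60.0)
    if shape_family == "convex":
        n = int(p.pop("n_vertices", 6))
        theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
        pts = np.column_stack([radius * np.sin(theta), radius * np.cos(theta)])
    elif shape_family == "cross":
        w = p.pop("arm_width_px", radius / 2.5)
        a, h = radius, w / 2.0
        pts = np.array(
            [
                (-h, -a), (-h, -h), (-a, -h), (-a, h), (-h, h), (-h, a),
                (h, a), (h, h), (a, h), (a, -h), (h, -h), (h, -a),
            ],
            dtype=float,
        )
    elif shape_family == "star":
        n = int(p.pop("n_points", 5))
        inner = float(p.pop("inner_fraction", 0.4)) * radius
        theta = np.linspace(0, 2 * np.pi, 2 * n, endpoint=False)
        rr = np.where(np.arange(2 * n) % 2 == 0, radius, inner)
        pts = np.column_stack([rr * np.sin(theta), rr * np.cos(theta)])
    elif shape_family == "lobed":
        k = int(p.pop("n_lobes", 4))
        amp = float(p.pop("lobe_depth", 0.2))
        theta = np.linspace(0, 2 * np.pi, 720, endpoint=False)
        rr = radius * (1.0 + amp * np.cos(k * theta))
        pts = np.column_stack([rr * np.sin(theta), rr * np.cos(theta)])
    else:
        raise ValueError(f"unknown shape_family {shape_family!r}")
    if p:
        raise ValueError(f"unused silhouette parameters: {sorted(p)}")
    return pts


def make_cell_silhouette(
    spec: SceneSpec,
    shape_family: str = "convex",
    params: dict | None = None,
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Render a binary silhouette with exactly known compactness.

    Returns ``(mask, polygon_um, truth)`` where the polygon is the exact
    vertex list (row, col in µm) and ``truth.true_compactness`` is the
    shoelace area over convex-hull area of that polygon — the solidity a
    perfect measurement should recover.
    """
    if spec.scene_kind != "cell_silhouette":
        raise ValueError("spec.scene_kind must be 'cell_silhouette'")
    (rng,) = _rng_tree(spec.seed, 1)
    pts = _silhouette_polygon(shape_family, params or {}, rng)

    Y, X = spec.shape
    pts = pts + np.array([(Y - 1) / 2.0, (X - 1) / 2.0])
    poly = Polygon(pts)
    if (not poly.is_valid) or (not poly.is_simple) or poly.area <= 0:
        raise ValueError("silhouette polygon is degenerate or self-intersecting")

    rr, cc = draw_polygon(pts[:, 0], pts[:, 1], shape=(Y, X))
    mask = np.zeros((Y, X), dtype=bool)
    mask[rr, cc] = True

    compact = poly.area / poly.convex_hull.area
    polygon_um = pts * spec.pixel_size_xy
    truth = GroundTruth(
        true_compactness=float(compact),
        polygon_um=polygon_um,
        cell_mask=mask,
    )
    return mask, polygon_um, truth
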