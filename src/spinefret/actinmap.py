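"""F/G-actin fraction mapping and membrane-proximal profiling.

Dual-stain images (phalloidin for filamentous F-actin, DNase I for
monomeric G-actin) are converted to two voxel-wise readouts of the local
polymerisation state:

* the F-actin fraction ``FR = I_F / (I_F + I_G)``, bounded in [0, 1];
* the F/G ratio ``R = I_F / I_G``, non-negative and linked to the
  fraction through ``FR = R / (1 + R)`` at every defined voxel.

Foreground is selected per channel by unimodal (background-symmetry,
a.k.a. Rosin) thresholding: the threshold sits at the histogram bin with
maximum perpendicular distance to the chord joining the histogram peak to
the last occupied bin — the natural corner criterion when one dominant
background mode decays into a sparse foreground tail.  A voxel is
foreground when it passes the threshold in *either* channel (union rule),
so purely-F or purely-G regions are retained; intersection mode is
available.

Cortical enrichment at the plasma membrane is quantified by sampling the
image along lines perpendicular to the cell contour, oriented outside →
inside, and averaging the per-line profiles.

``gamma_adjust`` (γ = 0.8 by default in figures) is display-only and is
never used in quantification.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import Point, Polygon
from skimage import measure

__all__ = [
    "FractionMap",
    "MembraneProfile",
    "unimodal_threshold",
    "rosin_threshold_index",
    "fraction_map",
    "whole_cell_summary",
    "extract_contour",
    "membrane_profiles",
    "gamma_adjust",
]


# ---------------------------------------------------------------------------
# Unimodal (background-symmetry / Rosin) threshold
# ---------------------------------------------------------------------------

def rosin_threshold_index(counts: np.ndarray) -> int:
    """Index of the histogram bin with maximum distance to the peak–tail chord.

    The chord runs from the histogram maximum (the background mode) to the
    last non-empty bin.  Vectorised point-to-line distance; ties resolve
    to the first (lowest) bin, matching an exhaustive scan.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 1 or counts.size < 2:
        raise ValueError("histogram must be 1D with >= 2 bins")
    peak = int(np.argmax(counts))
    nonzero = np.nonzero(counts)[0]
    last = int(nonzero[-1])
    if last <= peak:
        raise ValueError(
            "histogram has no tail beyond its peak; not a unimodal "
            "background-plus-tail shape"
        )
    x = np.arange(peak, last + 1, dtype=float)
    y = counts[peak : last + 1]
    # distance from (x, y) to the line through (peak, y_peak), (last, y_last)
    dx, dy = last - peak, counts[last] - counts[peak]
    norm = np.hypot(dx, dy)
    d = np.abs(dy * (x - peak) - dx * (y - counts[peak])) / norm
    return peak + int(np.argmax(d))


def unimodal_threshold(
    image: np.ndarray,
    bins: int = 256,
) -> float:
    """Background-symmetry threshold of an intensity image.

    Histogram: ``bins`` equal-width bins between the image minimum and
    maximum (the bin count changes the threshold; 256 is the package
    default and is stated in the output metadata of the CLI).  Returns
    the intensity at the centre of the selected bin.

    Raises ``ValueError`` for a constant image.
    """
    image = np.asarray(image)
    vals = image[np.isfinite(image)]
    if vals.size == 0 or vals.min() == vals.max():
        raise ValueError("unimodal threshold undefined for a constant image")
    counts, edges = np.histogram(vals, bins=bins)
    i = rosin_threshold_index(counts)
    return float(0.5 * (edges[i] + edges[i + 1]))


# ---------------------------------------------------------------------------
# Fraction map
# ---------------------------------------------------------------------------

@dataclass
class FractionMap:
    """Masked voxel-wise F-actin fraction and ratio.

    ``fr`` ∈ [0, 1] and ``r`` ≥ 0 are NaN outside ``foreground``; ``r``
    is additionally NaN where the G channel is zero (the ratio is
    infinite there while the fraction is exactly 1).
    """

    fr: np.ndarray
    r: np.ndarray
    foreground: np.ndarray
    thresholds: dict[str, float]

    def __post_init__(self) -> None:
        defined = np.isfinite(self.fr)
        if np.any(self.fr[defined] < 0) or np.any(self.fr[defined] > 1):
            raise ValueError("FR must lie in [0, 1] where defined")
        both = np.isfinite(self.fr) & np.isfinite(self.r)
        if both.any():
            link = self.r[both] / (1.0 + self.r[both])
            if not np.allclose(self.fr[both], link, atol=1e-9):
                raise ValueError("FR and R violate FR = R/(1+R)")


def fraction_map(
    f_image: np.ndarray,
    g_image: np.ndarray,
    *,
    foreground: np.ndarray | None = None,
    mask_mode: str = "union",
    bins: int = 256,
) -> FractionMap:
    """Voxel-wise F-actin fraction FR = I_F/(I_F+I_G) and ratio R = I_F/I_G.

    Foreground defaults to the per-channel unimodal threshold combined by
    ``mask_mode`` ("union" keeps voxels bright in either stain;
    "intersection" requires both).  Pass ``foreground`` to override.
    """
    f_image = np.asarray(f_image, dtype=float)
    g_image = np.asarray(g_image, dtype=float)
    if f_image.shape != g_image.shape:
        raise ValueError(
            f"channel shapes differ: {f_image.shape} vs {g_image.shape}"
        )
    thresholds: dict[str, float] = {}
    if foreground is None:
        tf = unimodal_threshold(f_image, bins=bins)
        tg = unimodal_threshold(g_image, bins=bins)
        thresholds = {"F": tf, "G": tg}
        if mask_mode == "union":
            foreground = (f_image > tf) | (g_image > tg)
        elif mask_mode == "intersection":
            foreground = (f_image > tf) & (g_image > tg)
        else:
            raise ValueError(f"unknown mask_mode {mask_mode!r}")
    else:
        foreground = np.asarray(foreground, dtype=bool)
        if foreground.shape != f_image.shape:
            raise ValueError("foreground shape mismatch")

    total = f_image + g_image
    fr = np.full(f_image.shape, np.nan)
    valid_fr = foreground & (total > 0)
    np.divide(f_image, total, out=fr, where=valid_fr)
    r = np.full(f_image.shape, np.nan)
    np.divide(f_image, g_image, out=r, where=foreground & (g_image > 0))
    return FractionMap(fr=fr, r=r, foreground=foreground, thresholds=thresholds)


def whole_cell_summary(fmap: FractionMap, cell_mask: np.ndarray) -> dict:
    """Mean FR and mean R over the defined voxels of one cell."""
    cell = np.asarray(cell_mask, dtype=bool)
    sel = cell & np.isfinite(fmap.fr)
    if not sel.any():
        raise ValueError("cell mask does not overlap the defined foreground")
    sel_r = cell & np.isfinite(fmap.r)
    return {
        "mean_fr": float(fmap.fr[sel].mean()),
        "mean_r": float(fmap.r[sel_r].mean()) if sel_r.any() else float("nan"),
        "n_voxels": int(sel.sum()),
    }


# ---------------------------------------------------------------------------
# Contour and membrane profiles
# ---------------------------------------------------------------------------

def extract_contour(
    cell_mask: np.ndarray, pixel_size: float = 1.0, *, smooth_px: float = 1.0
) -> np.ndarray:
    """Subpixel closed contour of a cell mask, counterclockwise, in µm.

    The largest connected component is taken (with a warning if the mask
    has several); the contour is the 0.5-level of the slightly smoothed
    mask (``smooth_px`` Gaussian), which suppresses the pixel staircase
    that otherwise inflates perimeters by several percent.  Returned as
    an (n, 2) array of (row, col) coordinates scaled by ``pixel_size``;
    the last vertex equals the first.
    """
    mask = np.asarray(cell_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty cell mask")
    lab, n = ndimage.label(mask)
    if n > 1:
        warnings.warn(
            f"mask has {n} components; using the largest", stacklevel=2
        )
        sizes = ndimage.sum_labels(mask, lab, index=np.arange(1, n + 1))
        mask = lab == (1 + int(np.argmax(sizes)))
    field = mask.astype(float)
    if smooth_px > 0:
        field = ndimage.gaussian_filter(field, smooth_px)
    contours = measure.find_contours(field, 0.5)
    if not contours:
        contours = measure.find_contours(mask.astype(float), 0.5)
    contour = max(contours, key=len)
    # enforce counterclockwise orientation in (row, col): positive shoelace
    if _signed_area(contour) < 0:
        contour = contour[::-1]
    if not np.array_equal(contour[0], contour[-1]):
        contour = np.vstack([contour, contour[0]])
    return contour * pixel_size


def _signed_area(poly: np.ndarray) -> float:
    y, x = poly[:, 0], poly[:, 1]
    return 0.5 * float(
        np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    )


@dataclass
class MembraneProfile:
    """Intensity sampled along membrane-perpendicular lines.

    ``offsets_um`` runs from negative (outside the cell) through 0 (the
    contour) to positive (inside); ``lines`` is (n_lines, n_offsets) and
    ``mean`` its per-offset average.
    """

    offsets_um: np.ndarray
    lines: np.ndarray
    line_spacing_um: float

    def __post_init__(self) -> None:
        if np.any(np.diff(self.offsets_um) <= 0):
            raise ValueError("offsets must be strictly increasing")
        if self.lines.ndim != 2 or self.lines.shape[0] < 1:
            raise ValueError("need at least one profile line")

    @property
    def mean(self) -> np.ndarray:
        # an offset can be NaN on every line (e.g. outside the image)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.lines, axis=0)

    def to_frame(self) -> pd.DataFrame:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            sd = (
                np.nanstd(self.lines, axis=0, ddof=1)
                if self.lines.shape[0] > 1
                else np.zeros_like(self.offsets_um)
            )
        return pd.DataFrame(
            {
                "offset_um": self.offsets_um,
                "mean": self.mean,
                "sd": sd,
                "n_lines": self.lines.shape[0],
            }
        )


def _resample_contour(contour: np.ndarray, spacing: float) -> tuple[np.ndarray, np.ndarray]:
    """Equally spaced points along a closed polyline, plus unit tangents."""
    seg = np.diff(contour, axis=0)
    seglen = np.linalg.norm(seg, axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seglen)])
    total = arc[-1]
    n = max(int(np.floor(total / spacing)), 1)
    s = np.arange(n) * spacing
    pts = np.empty((n, 2))
    for d in range(2):
        pts[:, d] = np.interp(s, arc, contour[:, d])
    # tangent by central difference on the resampled closed loop
    tang = np.roll(pts, -1, axis=0) - np.roll(pts, 1, axis=0)
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    return pts, tang


def membrane_profiles(
    image: np.ndarray,
    contour_um: np.ndarray,
    pixel_size: float,
    *,
    line_spacing_um: float = 0.5,
    half_length_um: float = 3.0,
    step_um: float | None = None,
) -> MembraneProfile:
    """Sample an image along inward normals of the cell contour.

    At points spaced ``line_spacing_um`` along the contour, the image is
    sampled by bilinear interpolation from ``-half_length_um`` (outside)
    to ``+half_length_um`` (inside) in steps of ``step_um`` (default: one
    pixel).  The inward direction is resolved against the polygon itself,
    so the caller does not need to worry about contour orientation.
    """
    contour_um = np.asarray(contour_um, dtype=float)
    if len(np.unique(contour_um.round(9), axis=0)) < 3:
        raise ValueError("contour must have at least 3 distinct vertices")
    if step_um is None:
        step_um = pixel_size
    if not (half_length_um > step_um > 0):
        raise ValueError("need half_length_um > step_um > 0")

    pts, tang = _resample_contour(contour_um, line_spacing_um)
    # left-hand normal of the travel direction
    normals = np.column_stack([-tang[:, 1], tang[:, 0]])
    # orient normals inward using the polygon (majority vote for robustness)
    poly = Polygon(contour_um)
    probe = pts + normals * (2.0 * pixel_size)
    inside = np.fromiter(
        (poly.contains(Point(p)) for p in probe), dtype=bool, count=len(probe)
    )
    if inside.mean() < 0.5:
        normals = -normals

    offsets = np.arange(-half_length_um, half_length_um + step_um / 2, step_um)
    # sample coordinates: (2, n_lines, n_offsets), in px
    coords = (
        pts[:, :, None] + normals[:, :, None] * offsets[None, None, :]
    ) / pixel_size
    lines = ndimage.map_coordinates(
        np.asarray(image, dtype=float),
        coords.transpose(1, 0, 2),
        order=1,
        mode="nearest",
    )
    return MembraneProfile(
        offsets_um=offsets, lines=lines, line_spacing_um=line_spacing_um
    )


# ---------------------------------------------------------------------------
# Display gamma
# ---------------------------------------------------------------------------

def gamma_adjust(image: np.ndarray, gamma: float = 0.8) -> np.ndarray:
    """out = in**gamma on a [0, 1]-normalised image.  Display only.

    Gamma < 1 lifts dim structures; the transform is monotone so it never
    reorders intensities, and it must never feed quantification.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    image = np.asarray(image, dtype=float)
    finite = image[np.isfinite(image)]
    if finite.size and (finite.min() < -1e-9 or finite.max() > 1 + 1e-9):
        raise ValueError("image must be normalised to [0, 1] before gamma")
    return np.power(np.clip(image, 0.0, 1.0), gamma)
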