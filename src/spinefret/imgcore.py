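"""Calibrated image stacks and the shared preprocessing primitives.

The in-memory container is :class:`CalibratedStack`: a ``T×Z×C×Y×X`` float
array carrying physical calibration (µm per pixel laterally, µm per z-step,
minutes per frame) plus an optional treatment-frame marker separating
baseline from post-treatment frames.

Preprocessing follows the conventional confocal time-lapse chain: drift
(shift) registration, background subtraction, slight Gaussian blurring
(σ = 0.5 px by default), percentile scaling against a control condition,
and z-maximum projection.  The default order used by the pipelines is
register → background → blur; each step is also available on its own.

Coordinates are 0-based and row-major with pixel centers at integer
coordinates; a physical position is ``index × pixel_size``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from skimage.registration import phase_cross_correlation

__all__ = [
    "CalibratedStack",
    "LabelMask",
    "ShiftTrack",
    "read_stack",
    "write_stack",
    "estimate_background",
    "subtract_background",
    "register_translation",
    "gaussian_blur",
    "scale_to_percentile",
    "zmax_project",
]

_AXES = "TZCYX"


@dataclass
class CalibratedStack:
    """A T×Z×C×Y×X intensity stack with physical calibration.

    Parameters
    ----------
    voxels:
        Five-dimensional float array ordered ``(T, Z, C, Y, X)``.
    pixel_size_xy:
        Lateral pixel size in µm/px (must be positive).
    z_step:
        Axial step in µm.
    frame_interval:
        Acquisition interval in minutes.
    channel_names:
        One unique name per channel, e.g. ``("mTurquoise", "YPet")``.
    treatment_frame:
        Index of the first post-treatment frame, or ``None`` for a
        single-condition acquisition.  Must leave at least one baseline
        frame before it.
    """

    voxels: np.ndarray
    pixel_size_xy: float
    channel_names: tuple[str, ...]
    z_step: float = 0.35
    frame_interval: float = 2.5
    treatment_frame: int | None = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 5:
            raise ValueError(
                f"voxels must be 5D (T,Z,C,Y,X); got {self.voxels.ndim}D"
            )
        if min(self.voxels.shape) < 1:
            raise ValueError("every stack dimension must be >= 1")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxels must be finite")
        if self.pixel_size_xy <= 0:
            raise ValueError("pixel_size_xy must be positive")
        if self.z_step <= 0 or self.frame_interval <= 0:
            raise ValueError("z_step and frame_interval must be positive")
        self.channel_names = tuple(self.channel_names)
        if len(self.channel_names) != self.n_channels:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.n_channels} channels"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        if self.treatment_frame is not None and not (
            1 <= self.treatment_frame <= self.n_frames - 1
        ):
            raise ValueError(
                f"treatment_frame {self.treatment_frame} outside "
                f"[1, {self.n_frames - 1}]"
            )

    # -- shape helpers -------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.voxels.shape[0]

    @property
    def n_z(self) -> int:
        return self.voxels.shape[1]

    @property
    def n_channels(self) -> int:
        return self.voxels.shape[2]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.voxels.shape[3], self.voxels.shape[4]

    def channel_index(self, channel: int | str) -> int:
        if isinstance(channel, str):
            try:
                return self.channel_names.index(channel)
            except ValueError:
                raise KeyError(
                    f"unknown channel {channel!r}; have {self.channel_names}"
                ) from None
        if not 0 <= channel < self.n_channels:
            raise KeyError(f"channel index {channel} out of range")
        return int(channel)

    def channel(self, channel: int | str) -> np.ndarray:
        """Return the (T, Z, Y, X) view of one channel."""
        return self.voxels[:, :, self.channel_index(channel)]

    def with_voxels(self, voxels: np.ndarray) -> "CalibratedStack":
        """A copy of this stack with new voxel data, calibration preserved."""
        return replace(self, voxels=voxels)

    def times_min(self) -> np.ndarray:
        """Frame times in minutes relative to treatment.

        The first post-treatment frame sits at ``+frame_interval`` and
        the last baseline frame at ``-frame_interval``; the treatment
        instant (t = 0) falls between them.  Without a treatment frame,
        times simply count up from zero.
        """
        idx = np.arange(self.n_frames, dtype=float)
        if self.treatment_frame is None:
            return idx * self.frame_interval
        t = (idx - self.treatment_frame) * self.frame_interval
        t[idx >= self.treatment_frame] += self.frame_interval
        return t


@dataclass
class LabelMask:
    """Integer label image aligned to the Y×X frame of a stack.

    ``0`` is background; every positive label is one object (spine, cell,
    dendrite segment, or a user background ROI, per ``roles``).
    """

    labels: np.ndarray
    roles: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("label mask must be 2D (Y, X)")
        if np.issubdtype(self.labels.dtype, np.floating):
            raise ValueError("label mask must be integer-typed")
        if self.labels.min() < 0:
            raise ValueError("label ids must be non-negative")

    @property
    def label_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    def mask_of(self, label_id: int) -> np.ndarray:
        if label_id not in self.label_ids:
            raise KeyError(f"label {label_id} not present in mask")
        return self.labels == label_id


@dataclass
class ShiftTrack:
    """Per-frame translation estimates in pixels (row, col).

    ``shifts[t]`` is the displacement that was *applied* to frame ``t``
    to register it onto the reference frame; the reference frame itself
    has shift (0, 0).  Frames flagged in ``featureless`` had no usable
    structure and default to zero shift.
    """

    shifts: np.ndarray
    reference_frame: int
    featureless: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.shifts = np.asarray(self.shifts, dtype=float)
        if self.shifts.ndim != 2 or self.shifts.shape[1] != 2:
            raise ValueError("shifts must be (T, 2)")
        if not np.allclose(self.shifts[self.reference_frame], 0.0):
            raise ValueError("shift at the reference frame must be (0, 0)")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": np.arange(len(self.shifts)),
                "shift_row_px": self.shifts[:, 0],
                "shift_col_px": self.shifts[:, 1],
                "featureless": [
                    i in self.featureless for i in range(len(self.shifts))
                ],
            }
        )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _normalize_axes(data: np.ndarray, axes: str) -> np.ndarray:
    """Reorder/expand a tifffile series to the canonical TZCYX order."""
    axes = axes.upper().replace("S", "C").replace("Q", "T").replace("I", "T")
    if any(a not in _AXES for a in axes):
        raise ValueError(f"cannot interpret axis order {axes!r}")
    if len(set(axes)) != len(axes):
        raise ValueError(f"duplicate axes in {axes!r}")
    for ax in _AXES:
        if ax not in axes:
            data = np.expand_dims(data, 0)
            axes = ax + axes
    order = [axes.index(ax) for ax in _AXES]
    return np.transpose(data, order)


def read_stack(
    path,
    *,
    pixel_size_xy: float | None = None,
    z_step: float | None = None,
    frame_interval: float | None = None,
    channel_names: tuple[str, ...] | None = None,
    treatment_frame: int | None = None,
) -> CalibratedStack:
    """Read a TIFF/OME-TIFF into a :class:`CalibratedStack`.

    Axes are normalised to TZCYX with missing axes promoted to singletons.
    Calibration is taken from OME metadata when present; keyword overrides
    win.  A file without a pixel size and without an override is refused —
    every downstream measurement is in µm.
    """
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        data = _normalize_axes(series.asarray(), series.axes)
        meta_px = meta_z = meta_dt = None
        meta_channels = None
        ome = tif.ome_metadata
    if ome:
        meta_px, meta_z, meta_dt, meta_channels = _parse_ome(ome)

    px = pixel_size_xy if pixel_size_xy is not None else meta_px
    if px is None:
        raise ValueError(
            f"{path}: no pixel size in metadata and no pixel_size_xy override"
        )
    names = channel_names or meta_channels or tuple(
        f"ch{i}" for i in range(data.shape[2])
    )
    return CalibratedStack(
        voxels=data.astype(np.float64),
        pixel_size_xy=float(px),
        z_step=float(z_step if z_step is not None else (meta_z or 0.35)),
        frame_interval=float(
            frame_interval if frame_interval is not None else (meta_dt or 2.5)
        ),
        channel_names=tuple(names),
        treatment_frame=treatment_frame,
    )


def _parse_ome(ome_xml: str):
    """Pull pixel size, z-step, frame interval and channel names from OME XML."""
    import xml.etree.ElementTree as ET

    root = ET.fromstring(ome_xml)
    ns = {"ome": root.tag.split("}")[0].strip("{")}
    px = z = dt = None
    channels = None
    pixels = root.find(".//ome:Pixels", ns)
    if pixels is not None:
        if pixels.get("PhysicalSizeX"):
            px = float(pixels.get("PhysicalSizeX"))
        if pixels.get("PhysicalSizeZ"):
            z = float(pixels.get("PhysicalSizeZ"))
        if pixels.get("TimeIncrement"):
            dt = float(pixels.get("TimeIncrement"))
        chans = pixels.findall("ome:Channel", ns)
        names = [c.get("Name") for c in chans]
        if names and all(names):
            channels = tuple(names)
    return px, z, dt, channels


def write_stack(stack: CalibratedStack, path, *, dtype=None) -> None:
    """Write a stack as OME-TIFF (TZCYX) with calibration metadata.

    Rendering and analysis happen in float64; quantisation to an integer
    dtype is an explicit choice made only at write time.
    """
    data = stack.voxels
    if dtype is not None:
        info = np.iinfo(dtype)
        data = np.clip(np.rint(data), info.min, info.max).astype(dtype)
    tifffile.imwrite(
        path,
        data,
        ome=True,
        metadata={
            "axes": _AXES,
            "PhysicalSizeX": stack.pixel_size_xy,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": stack.pixel_size_xy,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZ": stack.z_step,
            "PhysicalSizeZUnit": "µm",
            "TimeIncrement": stack.frame_interval,
            "TimeIncrementUnit": "min",
            "Channel": {"Name": list(stack.channel_names)},
        },
    )


def write_label_mask(mask: LabelMask, path) -> None:
    """Write a label mask as a single-channel uint16 TIFF."""
    if mask.labels.max(initial=0) > np.iinfo(np.uint16).max:
        raise ValueError("label ids exceed uint16 range")
    tifffile.imwrite(path, mask.labels.astype(np.uint16))


def read_label_mask(path, roles: dict[int, str] | None = None) -> LabelMask:
    return LabelMask(tifffile.imread(path), roles=roles or {})


# ---------------------------------------------------------------------------
# Background
# ---------------------------------------------------------------------------

def _plane_mode(plane: np.ndarray, bins: int = 256) -> float:
    """Histogram mode of a plane — robust to sparse bright foreground.

    The returned level is the median of the values inside the modal bin,
    so a background of one repeated value (e.g. exactly zero) is
    recovered exactly rather than as the bin centre.
    """
    lo, hi = float(plane.min()), float(plane.max())
    if lo == hi:
        return lo
    counts, edges = np.histogram(plane, bins=bins, range=(lo, hi))
    i = int(np.argmax(counts))
    sel = (plane >= edges[i]) & (
        plane <= edges[i + 1] if i == bins - 1 else plane < edges[i + 1]
    )
    return float(np.median(plane[sel]))


def estimate_background(
    stack: CalibratedStack,
    channel: int | str,
    method: str = "mode",
    *,
    roi: np.ndarray | None = None,
    percentile: float = 5.0,
) -> np.ndarray:
    """Estimate one background level per (frame, z) plane of a channel.

    Methods
    -------
    ``"mode"`` (default)
        Mode of a 256-bin plane histogram.  With a mostly-empty field the
        background dominates the histogram, so the mode tracks it even in
        the presence of bright objects.
    ``"roi"``
        Mean over a user-supplied boolean background ROI.
    ``"percentile"``
        The given low percentile of the plane.
    """
    c = stack.channel_index(channel)
    planes = stack.voxels[:, :, c]  # (T, Z, Y, X)
    out = np.empty(planes.shape[:2], dtype=float)
    for t in range(planes.shape[0]):
        for z in range(planes.shape[1]):
            plane = planes[t, z]
            if method == "mode":
                out[t, z] = _plane_mode(plane)
            elif method == "roi":
                if roi is None:
                    raise ValueError("method='roi' requires a background roi")
                out[t, z] = float(plane[roi].mean())
            elif method == "percentile":
                out[t, z] = float(np.percentile(plane, percentile))
            else:
                raise ValueError(f"unknown background method {method!r}")
    return out


def subtract_background(
    stack: CalibratedStack, levels: np.ndarray | float
) -> CalibratedStack:
    """Subtract per-(frame, z, channel) background, clipping at zero.

    ``levels`` may be a scalar, a (T, Z) array applied to every channel,
    or a full (T, Z, C) array.
    """
    levels = np.asarray(levels, dtype=float)
    if np.any(levels < 0):
        raise ValueError("background levels must be non-negative")
    T, Z, C = stack.voxels.shape[:3]
    if levels.ndim == 0:
        lv = np.broadcast_to(levels, (T, Z, C))
    elif levels.shape == (T, Z):
        lv = np.broadcast_to(levels[:, :, None], (T, Z, C))
    elif levels.shape == (T, Z, C):
        lv = levels
    else:
        raise ValueError(
            f"levels shape {levels.shape} not broadcastable to (T,Z,C)"
        )
    out = np.clip(stack.voxels - lv[:, :, :, None, None], 0.0, None)
    return stack.with_voxels(out)


# ---------------------------------------------------------------------------
# Registration
# ---------------------------------------------------------------------------

def register_translation(
    stack: CalibratedStack,
    reference_channel: int | str = 0,
    reference_frame: int = 0,
    *,
    upsample_factor: int = 50,
) -> tuple[CalibratedStack, ShiftTrack]:
    """Estimate and undo per-frame lateral drift.

    Translation (no rotation/scale) is estimated by subpixel phase
    correlation on the z-maximum projection of the reference channel,
    frame against reference frame, and the same correcting shift is
    applied to every z-plane of every channel of that frame.  Subpixel
    shifts are applied by linear interpolation; pixels exposed at the
    border are filled with the frame's modal background.
    """
    c = stack.channel_index(reference_channel)
    if not 0 <= reference_frame < stack.n_frames:
        raise ValueError("reference_frame out of range")
    ref_proj = stack.voxels[reference_frame, :, c].max(axis=0)

    shifts = np.zeros((stack.n_frames, 2))
    featureless: list[int] = []
    out = stack.voxels.copy()
    for t in range(stack.n_frames):
        if t == reference_frame:
            continue
        mov_proj = stack.voxels[t, :, c].max(axis=0)
        if np.ptp(mov_proj) == 0 or np.ptp(ref_proj) == 0:
            featureless.append(t)
            warnings.warn(
                f"frame {t}: featureless reference plane, shift set to 0",
                stacklevel=2,
            )
            continue
        shift, _, _ = phase_cross_correlation(
            ref_proj, mov_proj, upsample_factor=upsample_factor
        )
        shifts[t] = shift
        if np.any(shift != 0):
            for z in range(stack.n_z):
                for ch in range(stack.n_channels):
                    plane = stack.voxels[t, z, ch]
                    out[t, z, ch] = ndimage.shift(
                        plane,
                        shift,
                        order=1,
                        mode="constant",
                        cval=_plane_mode(plane),
                    )
    track = ShiftTrack(
        shifts=shifts,
        reference_frame=reference_frame,
        featureless=tuple(featureless),
    )
    return stack.with_voxels(out), track


# ---------------------------------------------------------------------------
# Blur / scaling / projection
# ---------------------------------------------------------------------------

def gaussian_blur(stack: CalibratedStack, sigma_px: float = 0.5) -> CalibratedStack:
    """Slight per-plane Gaussian smoothing (σ in pixels, default 0.5).

    Smoothing is 2D per (frame, z, channel) plane with reflective
    boundaries, so total intensity is conserved away from borders.
    """
    if sigma_px < 0:
        raise ValueError("sigma_px must be non-negative")
    if sigma_px == 0:
        return stack.with_voxels(stack.voxels.copy())
    out = ndimage.gaussian_filter(
        stack.voxels, sigma=(0, 0, 0, sigma_px, sigma_px), mode="reflect"
    )
    return stack.with_voxels(out)


def scale_to_percentile(
    stack: CalibratedStack,
    control_stack: CalibratedStack,
    percentile: float = 99.9,
) -> CalibratedStack:
    """Divide each channel by the control condition's percentile intensity.

    Scaling each experiment to the 99.9th-percentile intensity of its
    control condition puts conditions on a common intensity scale before
    thresholding and ratio statistics.  The scaled control's percentile
    equals 1 by construction, and the result is invariant to a common
    rescaling of input intensities.
    """
    if stack.n_channels != control_stack.n_channels:
        raise ValueError("stack and control must have the same channels")
    out = stack.voxels.copy()
    for c in range(stack.n_channels):
        ref = float(np.percentile(control_stack.voxels[:, :, c], percentile))
        if ref <= 0:
            raise ValueError(
                f"control percentile for channel {c} is {ref}; cannot scale"
            )
        out[:, :, c] /= ref
    return stack.with_voxels(out)


def zmax_project(stack: CalibratedStack) -> CalibratedStack:
    """Maximum-intensity projection along z (returns a Z=1 stack)."""
    out = stack.voxels.max(axis=1, keepdims=True)
    return stack.with_voxels(out)
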