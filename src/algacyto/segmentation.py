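"""Unsupervised cell detection from the chlorophyll trigger channel.

The detection chain is deliberately simple: the intrinsic chlorophyll
autofluorescence of the chloroplast marks every live algal cell, so the
chlorophyll channel alone drives detection (the lipid channel is never
consulted).  A percentile contrast stretch lifts the dim light scattered
inside the non-fluorescent cell body above the detection threshold, so the
segmented object covers the whole cell and not just the chloroplast.  The
stretched image is reduced to binary with a single global threshold chosen by
maximizing the between-class variance of the gray-level histogram, very small
objects are discarded, and connected components become cells.

Touching cells are not split; the method targets dilute suspensions where
clumping is rare.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from skimage.measure import label as _cc_label

from .errors import ConversionError, DegenerateHistogramError
from .image_io import FluorescenceField

__all__ = [
    "SegmentationParams",
    "LabelMask",
    "to_grayscale",
    "enhance_contrast",
    "optimal_threshold",
    "binarize_and_clean",
    "assign_cells",
    "segment_field",
]

#: ITU-R BT.601 luma weights used for RGB -> grayscale conversion.
LUMINOSITY_WEIGHTS = (0.2989, 0.5870, 0.1140)

GRAYSCALE_MODES = ("single-channel", "luminosity", "max-channel")


@dataclasses.dataclass
class SegmentationParams:
    """Tunable knobs of the detection chain.

    min_object_pixels:
        Components smaller than this are treated as debris and removed.
    low_pct / high_pct:
        Percentiles mapped to 0 and the dynamic-range maximum by the
        contrast stretch.
    grayscale_mode:
        How RGB frames collapse to one intensity plane.
    connectivity:
        4 or 8; pixel neighbourhood used for components.
    min_trigger_snr:
        Minimum contrast, in background-noise standard deviations, between
        the mean raw trigger intensity of detected objects and the
        background.  A field whose "objects" fail this floor is reported as
        empty: a global-threshold optimizer always splits even a pure-noise
        histogram, so a contrast floor is what distinguishes a blank field
        from a populated one.
    """

    min_object_pixels: int = 10
    low_pct: float = 1.0
    high_pct: float = 99.0
    grayscale_mode: str = "luminosity"
    connectivity: int = 8
    min_trigger_snr: float = 4.0

    def __post_init__(self) -> None:
        if self.min_object_pixels < 1:
            raise ValueError("min_object_pixels must be >= 1")
        if not (0 <= self.low_pct < self.high_pct <= 100):
            raise ValueError("need 0 <= low_pct < high_pct <= 100")
        if self.grayscale_mode not in GRAYSCALE_MODES:
            raise ValueError(f"grayscale_mode must be one of {GRAYSCALE_MODES}")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


@dataclasses.dataclass
class LabelMask:
    """Pixel-to-cell assignment: 0 = background, k in 1..n_cells = cell k."""

    labels: np.ndarray
    n_cells: int

    @classmethod
    def empty(cls, shape: tuple[int, int]) -> "LabelMask":
        return cls(labels=np.zeros(shape, dtype=np.int32), n_cells=0)

    def pixel_counts(self) -> np.ndarray:
        """Pixels per cell, index 0 = cell 1."""
        return np.bincount(self.labels.ravel(), minlength=self.n_cells + 1)[1:]


def _skimage_connectivity(connectivity: int) -> int:
    return 1 if connectivity == 4 else 2


def to_grayscale(raster: np.ndarray, mode: str = "luminosity") -> np.ndarray:
    """Collapse an RGB raster to one intensity plane.

    2-D input is returned unchanged for every mode (there is nothing to
    convert); ``single-channel`` additionally *requires* 2-D input.
    ``luminosity`` applies the fixed BT.601 weights, ``max-channel`` takes
    the per-pixel channel maximum.
    """
    arr = np.asarray(raster)
    if mode not in GRAYSCALE_MODES:
        raise ConversionError(f"unknown grayscale mode {mode!r}")
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3 and arr.shape[-1] == 3:
        if mode == "single-channel":
            raise ConversionError("single-channel mode requires a 2-D raster")
        if mode == "luminosity":
            return arr.astype(np.float64) @ np.asarray(LUMINOSITY_WEIGHTS)
        return arr.max(axis=-1)
    raise ConversionError(f"raster must be 2-D or (H, W, 3), got shape {arr.shape}")


def enhance_contrast(
    gray: np.ndarray,
    low_pct: float = 1.0,
    high_pct: float = 99.0,
    out_max: float = 255.0,
) -> np.ndarray:
    """Percentile-based linear contrast stretch.

    Maps the ``low_pct`` percentile to 0 and the ``high_pct`` percentile to
    ``out_max``, clipping outside; output is float and not rounded.  Constant
    images (degenerate percentiles) are returned unchanged.
    """
    if not (0 <= low_pct < high_pct <= 100):
        raise ValueError("need 0 <= low_pct < high_pct <= 100")
    g = np.asarray(gray, dtype=np.float64)
    lo, hi = np.percentile(g, [low_pct, high_pct])
    if hi <= lo:
        return g.copy()
    return np.clip((g - lo) / (hi - lo), 0.0, 1.0) * float(out_max)


def optimal_threshold(gray: np.ndarray, nbins: int = 256) -> float:
    """Global threshold maximizing between-class variance of the histogram.

    The image histogram (``nbins`` equal bins spanning the observed range) is
    scanned over every split *k*: background = bins ``<= k``, foreground =
    bins ``> k``.  The returned value is the center of the lowest bin
    achieving the maximal between-class variance
    ``w0 * w1 * (mu0 - mu1)**2`` — i.e. ties break toward the lowest
    threshold.  Deterministic for a fixed histogram.

    Raises
    ------
    DegenerateHistogramError
        If the image has a single gray level (callers typically treat the
        whole image as background).
    """
    g = np.asarray(gray, dtype=np.float64).ravel()
    if g.size == 0:
        raise DegenerateHistogramError("empty image")
    mn, mx = float(g.min()), float(g.max())
    if mn == mx:
        raise DegenerateHistogramError("constant image has no threshold")
    hist, edges = np.histogram(g, bins=nbins, range=(mn, mx))
    centers = (edges[:-1] + edges[1:]) / 2.0
    hist = hist.astype(np.float64)

    w0 = np.cumsum(hist)
    w1 = w0[-1] - w0
    s0 = np.cumsum(hist * centers)
    s_total = s0[-1]
    valid = (w0 > 0) & (w1 > 0)
    mu0 = np.divide(s0, w0, out=np.zeros_like(s0), where=valid)
    mu1 = np.divide(s_total - s0, w1, out=np.zeros_like(s0), where=valid)
    bcv = np.where(valid, w0 * w1 * (mu0 - mu1) ** 2, -np.inf)
    k = int(np.argmax(bcv))  # first occurrence = lowest maximizer
    return float(centers[k])


def binarize_and_clean(
    gray: np.ndarray,
    threshold: float,
    min_object_pixels: int = 10,
    connectivity: int = 8,
) -> np.ndarray:
    """Foreground = pixels strictly above threshold, minus tiny components.

    Pixels exactly at the threshold are background.  Connected components
    with fewer than ``min_object_pixels`` pixels are removed (a component of
    exactly ``min_object_pixels`` is kept).
    """
    binary = np.asarray(gray) > threshold
    if min_object_pixels > 1 and binary.any():
        lab = _cc_label(binary, connectivity=_skimage_connectivity(connectivity))
        sizes = np.bincount(lab.ravel())
        keep = sizes >= min_object_pixels
        keep[0] = False
        binary = keep[lab]
    return binary


def assign_cells(binary: np.ndarray, connectivity: int = 8) -> LabelMask:
    """Connected-component labeling with labels 1..n in raster-scan order.

    Labels are renumbered so that cell *k* is the k-th component whose first
    pixel is encountered scanning rows top to bottom, left to right.
    """
    raw = _cc_label(np.asarray(binary, dtype=bool),
                    connectivity=_skimage_connectivity(connectivity))
    n = int(raw.max())
    if n == 0:
        return LabelMask.empty(raw.shape)
    flat = raw.ravel()
    values, first_idx = np.unique(flat, return_index=True)
    nonzero = values > 0
    order = np.argsort(first_idx[nonzero])  # components by first appearance
    remap = np.zeros(n + 1, dtype=np.int32)
    remap[values[nonzero][order]] = np.arange(1, n + 1, dtype=np.int32)
    return LabelMask(labels=remap[raw], n_cells=n)


def _trigger_contrast_ok(raw_gray: np.ndarray, labels: np.ndarray, min_snr: float) -> bool:
    """Contrast floor: detected objects must stand out of the raw background."""
    fg = labels > 0
    bg_vals = np.asarray(raw_gray, dtype=np.float64)[~fg]
    fg_vals = np.asarray(raw_gray, dtype=np.float64)[fg]
    if bg_vals.size == 0 or fg_vals.size == 0:
        return True
    bg_sd = bg_vals.std()
    contrast = fg_vals.mean() - bg_vals.mean()
    if bg_sd == 0:
        return contrast > 0
    return contrast >= min_snr * bg_sd


def segment_field(field: FluorescenceField, params: SegmentationParams | None = None) -> LabelMask:
    """Detect cells in one field from the chlorophyll channel only.

    Composition: grayscale -> contrast stretch -> between-class-variance
    threshold -> binarize + small-object removal -> component labeling.
    The lipid channel never participates, so segmentation is invariant to
    arbitrary changes of it.  Degenerate (constant or contrast-free) trigger
    channels yield an empty mask with a warning rather than an error.
    """
    params = params or SegmentationParams()
    gray = to_grayscale(field.chl_raw, params.grayscale_mode)
    enhanced = enhance_contrast(
        gray, params.low_pct, params.high_pct, out_max=float(field.dynamic_range_max)
    )
    try:
        threshold = optimal_threshold(enhanced)
    except DegenerateHistogramError:
        warnings.warn(
            f"field {field.field_id!r}: constant trigger channel, no cells detected",
            stacklevel=2,
        )
        return LabelMask.empty(field.shape)
    binary = binarize_and_clean(
        enhanced, threshold, params.min_object_pixels, params.connectivity
    )
    mask = assign_cells(binary, params.connectivity)
    if mask.n_cells and not _trigger_contrast_ok(gray, mask.labels, params.min_trigger_snr):
        warnings.warn(
            f"field {field.field_id!r}: trigger contrast below "
            f"{params.min_trigger_snr} background SDs, treating field as empty",
            stacklevel=2,
        )
        return LabelMask.empty(field.shape)
    return mask
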