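"""Spot-pattern extraction from coat photographs.

Converts a colour photograph plus a manually defined analysis rectangle into a
filtered, labelled spot map measured in *giraffe units* (GU), the
scale-invariant unit in which 1 GU equals the pixel height of the analysis
rectangle.  The chain mirrors the classic ImageJ workflow: crop, 8-bit
greyscale, linear contrast stretch, isodata (iterated intermeans) threshold,
binarise with spots as the dark phase, label 8-connected particles, then drop
edge-cut components and sub-speckle components (< 1e-5 GU²).

Coordinates are 0-based and half-open; y increases downward (raster
convention).  Angles reported elsewhere fold y back up to the mathematical
orientation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

#: default total saturated fraction for the contrast stretch (0.35% per tail)
DEFAULT_SATURATED_FRACTION = 0.007

#: default minimum spot area in GU²; smaller components are speckles
DEFAULT_MIN_AREA_GU2 = 1e-5

EIGHT_CONN = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class AnalysisRectangle:
    """Axis-aligned torso region within which spots are measured.

    Pixel coordinates, 0-based, half-open: the rectangle spans columns
    ``x0 .. x1-1`` and rows ``y0 .. y1-1``.  Its pixel height defines the GU
    scale for every downstream measurement.
    """

    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self) -> None:
        if not (self.x1 > self.x0 and self.y1 > self.y0):
            raise ValueError("analysis rectangle must have positive width and height")

    @property
    def width_px(self) -> int:
        return self.x1 - self.x0

    @property
    def height_px(self) -> int:
        return self.y1 - self.y0

    @property
    def gu_per_px(self) -> float:
        """GU length of one pixel edge: 1 / rectangle height."""
        return 1.0 / self.height_px


@dataclass
class BinaryPatternMask:
    """Bicolour (spot / ground) mask of the analysis rectangle."""

    foreground: np.ndarray  # bool, shape (H, W); True = spot phase
    gu_per_px: float

    @property
    def shape(self) -> tuple[int, int]:
        return self.foreground.shape


@dataclass
class LabeledSpotMap:
    """Connected spot components, 0 = background, 1..K = spots."""

    labels: np.ndarray  # int32, shape (H, W)
    gu_per_px: float
    n_spots_retained: int
    filter_log: list[dict] = field(default_factory=list)

    @property
    def spot_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]


def crop_to_rectangle(image: np.ndarray, rect: AnalysisRectangle) -> np.ndarray:
    """Crop ``image`` to the analysis rectangle (rows y0:y1, cols x0:x1)."""
    h, w = image.shape[:2]
    if rect.x0 < 0:
        raise ValueError(f"rectangle x0={rect.x0} outside image (left edge)")
    if rect.y0 < 0:
        raise ValueError(f"rectangle y0={rect.y0} outside image (top edge)")
    if rect.x1 > w:
        raise ValueError(f"rectangle x1={rect.x1} exceeds image width {w} (right edge)")
    if rect.y1 > h:
        raise ValueError(f"rectangle y1={rect.y1} exceeds image height {h} (bottom edge)")
    return image[rect.y0 : rect.y1, rect.x0 : rect.x1]


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """8-bit luminance conversion, round(0.299 R + 0.587 G + 0.114 B)."""
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected a 3-channel colour image")
    if image.dtype != np.uint8:
        raise ValueError("expected 8-bit (uint8) input")
    rgb = image.astype(np.float64)
    lum = 0.299 * rgb[..., 0] + 0.587 * rgb[..., 1] + 0.114 * rgb[..., 2]
    return np.round(lum).astype(np.uint8)


def enhance_contrast(
    gray: np.ndarray, saturated_fraction: float = DEFAULT_SATURATED_FRACTION
) -> np.ndarray:
    """Linear stretch mapping the tail quantiles to the full 0–255 range.

    The ``saturated_fraction/2`` and ``1 - saturated_fraction/2`` intensity
    quantiles map to 0 and 255; values outside are clipped.  A constant image
    is returned unchanged with a warning (no stretch is possible).
    """
    if not (0.0 <= saturated_fraction < 0.5):
        raise ValueError("saturated_fraction must be in [0, 0.5)")
    vals = gray.astype(np.float64)
    lo = float(np.quantile(vals, saturated_fraction / 2.0))
    hi = float(np.quantile(vals, 1.0 - saturated_fraction / 2.0))
    if hi <= lo:
        warnings.warn("constant image: contrast stretch skipped", stacklevel=2)
        return gray.copy()
    out = (vals - lo) * (255.0 / (hi - lo))
    return np.round(np.clip(out, 0.0, 255.0)).astype(np.uint8)


def isodata_threshold(gray: np.ndarray) -> int:
    """Iterated-intermeans (isodata) threshold of an 8-bit image.

    Returns the fixed point ``t = round((mean(levels <= t) + mean(levels > t)) / 2)``
    reached by iterating from the mid-range of the observed intensities.
    """
    vals = np.asarray(gray, dtype=np.float64).ravel()
    vmin, vmax = vals.min(), vals.max()
    if vmin == vmax:
        raise ValueError("constant image: no threshold exists")
    t = int(round((vmin + vmax) / 2.0))
    for _ in range(256):
        below = vals[vals <= t]
        above = vals[vals > t]
        if below.size == 0:
            t_new = int(round(above.mean())) - 1
        elif above.size == 0:
            t_new = int(round(below.mean()))
        else:
            t_new = int(round((below.mean() + above.mean()) / 2.0))
        if t_new == t:
            return t
        t = t_new
    return t


def binarize(gray: np.ndarray, threshold: int, gu_per_px: float = 1.0) -> BinaryPatternMask:
    """Foreground = pixels with intensity <= threshold (spots are dark)."""
    if not (0 <= threshold <= 255):
        raise ValueError("threshold must lie in [0, 255]")
    return BinaryPatternMask(foreground=np.asarray(gray) <= threshold, gu_per_px=gu_per_px)


def label_spots(mask: BinaryPatternMask) -> LabeledSpotMap:
    """Label 8-connected foreground components in raster-scan order."""
    labels, n = ndimage.label(mask.foreground, structure=EIGHT_CONN)
    labels = _relabel_raster_order(labels, n)
    return LabeledSpotMap(labels=labels.astype(np.int32), gu_per_px=mask.gu_per_px,
                          n_spots_retained=n)


def _relabel_raster_order(labels: np.ndarray, n: int) -> np.ndarray:
    """Renumber components 1..n by the raster position of their first pixel."""
    if n == 0:
        return labels
    flat = labels.ravel()
    first = np.full(n + 1, flat.size, dtype=np.int64)
    idx = np.flatnonzero(flat)
    # reversed so earlier raster positions overwrite later ones
    first[flat[idx[::-1]]] = idx[::-1]
    order = np.argsort(first[1:], kind="stable")  # old label-1 sorted by first pixel
    remap = np.zeros(n + 1, dtype=labels.dtype)
    remap[order + 1] = np.arange(1, n + 1)
    return remap[labels]


def apply_spot_filters(
    labeled: LabeledSpotMap,
    min_area_gu2: float = DEFAULT_MIN_AREA_GU2,
) -> LabeledSpotMap:
    """Drop edge-cut components and components smaller than ``min_area_gu2``.

    A component is edge-cut if any of its pixels lies on the border row/column
    of the rectangle; incomplete spots would bias the shape traits.  The area
    filter removes speckles below 1e-5 GU² by default.  The result is
    relabelled 1..K in raster order and the removals are recorded in
    ``filter_log``.  Applying the filters twice is a no-op.
    """
    labels = labeled.labels
    h, w = labels.shape
    ids = labeled.spot_ids
    log: list[dict] = []
    keep_mask = np.zeros(labels.shape, dtype=bool)
    border = np.zeros(labels.shape, dtype=bool)
    border[0, :] = border[-1, :] = True
    border[:, 0] = border[:, -1] = True
    edge_ids = set(np.unique(labels[border & (labels > 0)]).tolist())
    px_area_gu2 = labeled.gu_per_px ** 2
    counts = np.bincount(labels.ravel(), minlength=int(labels.max()) + 1)
    for sid in ids:
        sid = int(sid)
        area = counts[sid] * px_area_gu2
        if sid in edge_ids:
            log.append({"label": sid, "retained": False, "reason": "edge_cut"})
        elif area < min_area_gu2:
            log.append({"label": sid, "retained": False, "reason": "speckle",
                        "area_gu2": area})
        else:
            log.append({"label": sid, "retained": True, "area_gu2": area})
            keep_mask |= labels == sid
    new_labels, n = ndimage.label(keep_mask, structure=EIGHT_CONN)
    new_labels = _relabel_raster_order(new_labels, n)
    return LabeledSpotMap(labels=new_labels.astype(np.int32),
                          gu_per_px=labeled.gu_per_px,
                          n_spots_retained=int(n), filter_log=log)


def write_labeled_map(labeled: LabeledSpotMap, png_path, log_path=None) -> None:
    """Persist a labelled spot map as 16-bit PNG plus a JSON filter log."""
    import json

    import imageio.v3 as iio

    if labeled.labels.max() > 65535:
        raise ValueError("more than 65535 components cannot fit in 16-bit PNG")
    iio.imwrite(png_path, labeled.labels.astype(np.uint16))
    if log_path is not None:
        payload = {"gu_per_px": labeled.gu_per_px,
                   "n_spots_retained": labeled.n_spots_retained,
                   "filter_log": labeled.filter_log}
        with open(log_path, "w") as fh:
            json.dump(payload, fh, indent=2)


def extract_spot_map(
    image: np.ndarray,
    rect: AnalysisRectangle,
    saturated_fraction: float = DEFAULT_SATURATED_FRACTION,
    min_area_gu2: float = DEFAULT_MIN_AREA_GU2,
) -> tuple[LabeledSpotMap, np.ndarray]:
    """Full extraction chain: crop → grey → stretch → threshold → label → filter.

    Returns the filtered labelled map and the cropped colour rectangle (the
    latter feeds the mode-shade trait).
    """
    color_rect = crop_to_rectangle(image, rect)
    gray = to_grayscale(color_rect)
    stretched = enhance_contrast(gray, saturated_fraction)
    t = isodata_threshold(stretched)
    mask = binarize(stretched, t, gu_per_px=rect.gu_per_px)
    labeled = label_spots(mask)
    return apply_spot_filters(labeled, min_area_gu2), color_rect
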