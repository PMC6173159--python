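"""Per-spot and per-animal coat-pattern trait measurement.

Eleven traits per animal: number of spots plus the arithmetic means of nine
per-spot measurements (area, perimeter, ellipse angle, circularity, maximum
caliper, Feret angle, aspect ratio, roundness, solidity), and the mode shade of
the colour rectangle packed as 65536·r + 256·g + b.  All lengths are in
giraffe units (GU; 1 GU = analysis-rectangle height), areas in GU².

Conventions
-----------
* Perimeter: chain-code length of the outer 8-connected boundary traced
  through pixel centres — straight steps count 1 px, diagonal steps √2 px.
  A single pixel counts 4 px (its square boundary).
* Ellipse fit: second central moments (with the 1/12 unit-square pixel term),
  axes rescaled so the ellipse area π·major·minor/4 equals the pixel area.
  Under this normalisation roundness·aspect_ratio = 1 exactly.
* Convex hulls (Feret, solidity) are taken over pixel *corner* points so thin
  and single-pixel components have positive hull area.
* Angles are mathematical (y up), degrees in [0, 180).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull

SQRT2 = float(np.sqrt(2.0))

# Moore neighbourhood in clockwise order starting East, as (dy, dx)
_MOORE = [(0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1)]


@dataclass
class SpotRecord:
    """Geometry of a single retained spot, in GU."""

    area: float
    perimeter: float
    ellipse_major: float
    ellipse_minor: float
    ellipse_angle_deg: float
    circularity: float
    max_caliper: float
    feret_angle_deg: float
    aspect_ratio: float
    roundness: float
    solidity: float


@dataclass
class AnimalTraitProfile:
    """The 11 per-animal traits (10 measurements + mode shade)."""

    number_of_spots: int
    mean_area: float
    mean_perimeter: float
    mean_angle: float
    mean_circularity: float
    mean_max_caliper: float
    mean_feret_angle: float
    mean_aspect_ratio: float
    mean_roundness: float
    mean_solidity: float
    mode_shade: int

    #: CSV column order (shared by the pipeline's trait tables)
    COLUMNS = ("number", "area", "perimeter", "angle", "circularity",
               "max_caliper", "feret_angle", "aspect_ratio", "roundness",
               "solidity", "mode_shade")

    def to_row(self) -> dict:
        return {
            "number": self.number_of_spots,
            "area": self.mean_area,
            "perimeter": self.mean_perimeter,
            "angle": self.mean_angle,
            "circularity": self.mean_circularity,
            "max_caliper": self.mean_max_caliper,
            "feret_angle": self.mean_feret_angle,
            "aspect_ratio": self.mean_aspect_ratio,
            "roundness": self.mean_roundness,
            "solidity": self.mean_solidity,
            "mode_shade": self.mode_shade,
        }


class NoMeasurableSpotsError(ValueError):
    """Raised when an animal has no retained spots to aggregate."""


_MOORE_INDEX = {off: k for k, off in enumerate(_MOORE)}


def trace_perimeter(component: np.ndarray, gu_per_px: float = 1.0) -> float:
    """Chain-code perimeter of the outer boundary of a connected component.

    ``component`` is a boolean raster containing one 8-connected component.
    Moore-neighbour tracing through pixel centres with Jacob's stopping
    criterion; straight steps count 1 px, diagonal steps √2 px.  A
    single-pixel component returns 4 px (its square boundary) by convention.
    """
    comp = np.asarray(component, dtype=bool)
    npx = int(comp.sum())
    if npx == 0:
        raise ValueError("empty component")
    if npx == 1:
        return 4.0 * gu_per_px
    padded = np.pad(comp, 1)
    ys, xs = np.nonzero(padded)
    order = np.lexsort((xs, ys))
    start = (int(ys[order[0]]), int(xs[order[0]]))
    backtrack = (start[0], start[1] - 1)  # West of the raster-first pixel: background
    cur = start
    length = 0.0
    first_move = None
    for _ in range(8 * npx + 8):
        d0 = _MOORE_INDEX[(backtrack[0] - cur[0], backtrack[1] - cur[1])]
        move = None
        last_bg = backtrack
        for k in range(1, 9):
            d = (d0 + k) % 8
            dy, dx = _MOORE[d]
            ny, nx = cur[0] + dy, cur[1] + dx
            if padded[ny, nx]:
                move = d
                nxt = (ny, nx)
                break
            last_bg = (ny, nx)
        if move is None:  # unreachable for npx > 1
            return 4.0 * gu_per_px
        if cur == start:
            if first_move is None:
                first_move = move
            elif move == first_move:
                break  # full boundary cycle completed
        dy, dx = _MOORE[move]
        length += SQRT2 if (dy != 0 and dx != 0) else 1.0
        backtrack = last_bg
        cur = nxt
    return length * gu_per_px


def pixel_corners(coords: np.ndarray) -> np.ndarray:
    """Unique corner points (x, y) of unit-square pixels at integer coords.

    ``coords`` is (n, 2) as (y, x) raster indices; corners come back as
    (m, 2) float (x, y) points in pixel units.
    """
    coords = np.asarray(coords)
    ys, xs = coords[:, 0], coords[:, 1]
    pts = np.concatenate([
        np.stack([xs, ys], 1),
        np.stack([xs + 1, ys], 1),
        np.stack([xs, ys + 1], 1),
        np.stack([xs + 1, ys + 1], 1),
    ]).astype(np.float64)
    return np.unique(pts, axis=0)


def feret_of_points(points: np.ndarray) -> tuple[float, float]:
    """Maximum pairwise distance and its angle over an (n, 2) (x, y) set.

    Points are reduced to their convex hull first (the maximising pair is
    always a pair of hull vertices); the angle of the maximising segment is
    folded into [0, 180), measured against the x-axis with y flipped to
    mathematical (counter-clockwise) orientation.
    """
    pts = np.asarray(points, dtype=np.float64)
    if len(pts) > 4:
        try:
            hull = ConvexHull(pts)
            pts = pts[hull.vertices]
        except Exception:  # collinear/degenerate: keep all points
            pass
    diff = pts[:, None, :] - pts[None, :, :]
    d2 = (diff ** 2).sum(-1)
    i, j = np.unravel_index(int(np.argmax(d2)), d2.shape)
    if i > j:  # deterministic segment orientation
        i, j = j, i
    dmax = float(np.sqrt(d2[i, j]))
    dx = pts[j, 0] - pts[i, 0]
    dy = pts[j, 1] - pts[i, 1]
    angle = float(np.degrees(np.arctan2(-dy, dx))) % 180.0
    return dmax, angle


def feret(coords: np.ndarray, gu_per_px: float = 1.0) -> tuple[float, float]:
    """Maximum caliper (Feret diameter) of a component and its angle.

    The caliper is the largest pairwise distance between pixel-centre points
    of the component (reduced to convex-hull vertices first); a single pixel
    falls back to its corner square (caliper √2 px).  The angle is folded
    into [0, 180), mathematical orientation.
    """
    coords = np.asarray(coords)
    if len(coords) == 0:
        raise ValueError("empty component")
    if len(coords) == 1:
        dmax, angle = feret_of_points(pixel_corners(coords))
        return dmax * gu_per_px, angle
    centers = np.stack([coords[:, 1], coords[:, 0]], axis=1).astype(np.float64)
    dmax, angle = feret_of_points(centers)
    return dmax * gu_per_px, angle


def solidity(coords: np.ndarray) -> float:
    """Pixel area / convex-hull area over pixel corners, capped at 1."""
    coords = np.asarray(coords)
    npx = len(coords)
    if npx == 0:
        raise ValueError("empty component")
    pts = pixel_corners(coords)
    try:
        hull_area = float(ConvexHull(pts).volume)
    except Exception:
        return 1.0
    if hull_area <= 0:
        return 1.0
    return min(1.0, npx / hull_area)


def fit_ellipse(coords: np.ndarray, gu_per_px: float = 1.0) -> tuple[float, float, float]:
    """Moment-based ellipse fit: (major, minor, angle_deg).

    Axes come from the second central moments (plus the 1/12 per-pixel
    unit-square term) and are rescaled so π·major·minor/4 equals the pixel
    area; the angle of the major axis is in degrees, [0, 180), mathematical
    orientation (y up).
    """
    coords = np.asarray(coords, dtype=np.float64)
    npx = len(coords)
    if npx == 0:
        raise ValueError("empty component")
    ys, xs = coords[:, 0], coords[:, 1]
    # centre pixels and flip y to mathematical orientation
    x = xs - xs.mean()
    y = -(ys - ys.mean())
    mu20 = float((x * x).mean()) + 1.0 / 12.0
    mu02 = float((y * y).mean()) + 1.0 / 12.0
    mu11 = float((x * y).mean())
    common = np.sqrt(max(0.0, (mu20 - mu02) ** 2 + 4 * mu11 ** 2))
    lam1 = (mu20 + mu02 + common) / 2.0
    lam2 = (mu20 + mu02 - common) / 2.0
    lam2 = max(lam2, 1e-12)
    a0 = 2.0 * np.sqrt(lam1)  # semi-axes of the moment ellipse
    b0 = 2.0 * np.sqrt(lam2)
    # rescale so the ellipse area equals the pixel area
    scale = np.sqrt(npx / (np.pi * a0 * b0))
    major = 2.0 * a0 * scale
    minor = 2.0 * b0 * scale
    if common < 1e-12:
        angle = 0.0
    else:
        angle = float(np.degrees(0.5 * np.arctan2(2.0 * mu11, mu20 - mu02))) % 180.0
    return major * gu_per_px, minor * gu_per_px, angle


def circularity(area: float, perimeter: float) -> float:
    """4π·Area/Perimeter², capped at 1; 1.0 is a perfect circle."""
    if area <= 0 or perimeter <= 0:
        raise ValueError("area and perimeter must be positive")
    return min(1.0, 4.0 * np.pi * area / perimeter ** 2)


def roundness(area: float, major: float) -> float:
    """4·Area/(π·Major²), capped at 1 — the reciprocal of aspect ratio."""
    if major <= 0:
        raise ValueError("major axis must be positive")
    return min(1.0, 4.0 * area / (np.pi * major ** 2))


def mode_shade(color_rect: np.ndarray) -> int:
    """Most frequent packed 24-bit RGB value 65536·r + 256·g + b.

    Ties break toward the smallest packed value.
    """
    if color_rect.ndim != 3 or color_rect.shape[2] != 3 or color_rect.dtype != np.uint8:
        raise ValueError("expected an 8-bit RGB raster")
    flat = color_rect.reshape(-1, 3).astype(np.int64)
    packed = flat[:, 0] * 65536 + flat[:, 1] * 256 + flat[:, 2]
    values, counts = np.unique(packed, return_counts=True)
    return int(values[int(np.argmax(counts))])  # unique() sorts → smallest wins ties


def measure_spot(labels: np.ndarray, spot_id: int, gu_per_px: float) -> SpotRecord:
    """All per-spot traits for component ``spot_id`` of a labelled map."""
    mask = labels == spot_id
    coords = np.argwhere(mask)
    if coords.size == 0:
        raise ValueError(f"no pixels with label {spot_id}")
    area = float(len(coords)) * gu_per_px ** 2
    # trace on the tight bounding box for speed
    y0, x0 = coords.min(0)
    y1, x1 = coords.max(0) + 1
    perim = trace_perimeter(mask[y0:y1, x0:x1], gu_per_px)
    major, minor, angle = fit_ellipse(coords, gu_per_px)
    caliper, feret_angle = feret(coords, gu_per_px)
    sol = solidity(coords)
    circ = circularity(area, perim)
    asp = major / minor
    rnd = roundness(area, major)
    return SpotRecord(area=area, perimeter=perim, ellipse_major=major,
                      ellipse_minor=minor, ellipse_angle_deg=angle,
                      circularity=circ, max_caliper=caliper,
                      feret_angle_deg=feret_angle, aspect_ratio=asp,
                      roundness=rnd, solidity=sol)


def measure_all(labeled) -> list[SpotRecord]:
    """SpotRecord for every retained component of a LabeledSpotMap."""
    return [measure_spot(labeled.labels, int(sid), labeled.gu_per_px)
            for sid in labeled.spot_ids]


def aggregate_profile(spots: list[SpotRecord], color_rect: np.ndarray) -> AnimalTraitProfile:
    """Per-animal profile: arithmetic means over retained spots + mode shade."""
    if len(spots) == 0:
        raise NoMeasurableSpotsError("no measurable spots: animal excluded")
    mean = lambda f: float(np.mean([getattr(s, f) for s in spots]))  # noqa: E731
    return AnimalTraitProfile(
        number_of_spots=len(spots),
        mean_area=mean("area"),
        mean_perimeter=mean("perimeter"),
        mean_angle=mean("ellipse_angle_deg"),
        mean_circularity=mean("circularity"),
        mean_max_caliper=mean("max_caliper"),
        mean_feret_angle=mean("feret_angle_deg"),
        mean_aspect_ratio=mean("aspect_ratio"),
        mean_roundness=mean("roundness"),
        mean_solidity=mean("solidity"),
        mode_shade=mode_shade(color_rect),
    )
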