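"""Synthetic inputs with known ground truth for the whole pipeline.

Five generators emulate the study's raw material: spotted-coat photographs
(dark blobs on a lighter ground inside an analysis rectangle), mother–calf
trait pairs with a stated parent-offspring regression slope, repeated trait
measurements with a stated repeatability, separated trait clusters for the
phenotype-grouping step, and robust-design encounter histories with stated
survival, temporary-emigration and detection parameters.

Every generator is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ellipe, expit
from skimage.draw import polygon as draw_polygon

from .extraction import AnalysisRectangle
from .cmr import EncounterHistorySet, SurveySchedule

_EDGE_PAD_PX = 16  # background margin around the analysis rectangle


@dataclass(frozen=True)
class CoatSceneParams:
    """Parameters of one synthetic coat scene.

    Defaults are pitched at the observed coat statistics of wild Masai
    giraffes: roughly 19 spots in the rectangle, mean spot area ≈ 0.04 GU²
    (mean effective radius ≈ 0.11 GU), mean fitted-ellipse aspect ratio
    ≈ 1.7, moderately roughened boundaries, dark spots on a lighter ground.
    """

    rect_width_px: int = 400
    rect_height_px: int = 300
    n_spots: int = 19
    mean_radius_gu: float = 0.11
    radius_cv: float = 0.3
    aspect_ratio_mean: float = 1.7
    aspect_ratio_cv: float = 0.2
    boundary_roughness: float = 0.15
    spot_shade: int = 60
    background_shade: int = 180
    illumination_gradient: float = 0.1
    noise_sd: float = 4.0
    #: keep spot centres this far (GU) inside the rectangle; 0 lets spots
    #: cross the edge (they are then excluded downstream, as on real flanks)
    placement_margin_gu: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rect_height_px < 64:
            raise ValueError("rect_height_px must be >= 64")
        if not (0 <= self.spot_shade < self.background_shade <= 255):
            raise ValueError("spots must be darker than the coat ground")
        if self.n_spots < 0:
            raise ValueError("n_spots must be >= 0")
        if self.aspect_ratio_mean < 1:
            raise ValueError("aspect_ratio_mean must be >= 1")
        if not (0 <= self.boundary_roughness <= 1):
            raise ValueError("boundary_roughness must lie in [0, 1]")
        if self.mean_radius_gu > 0.5:
            raise ValueError("requested spot radius exceeds half the rectangle height")


@dataclass
class GroundTruthSpot:
    """Analytic geometry of one rendered spot (GU units)."""

    center: tuple[float, float]  # (x, y) in GU, rectangle origin
    analytic_area: float
    analytic_perimeter: float
    major_axis: float
    minor_axis: float
    orientation_deg: float
    touches_edge: bool
    merged: bool = False


@dataclass(frozen=True)
class PODesign:
    """Design of a mother–calf paired-trait simulation.

    ``po_slope`` is the expected offspring-on-mother regression slope, i.e.
    h²/2 under the single-parent regression convention.
    """

    n_pairs: int
    trait_mean: float = 0.5
    trait_var: float = 0.01
    po_slope: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.trait_var <= 0:
            raise ValueError("trait_var must be positive")
        if not (0.0 <= self.po_slope <= 1.0):
            raise ValueError("po_slope must lie in [0, 1]")
        if self.n_pairs < 3:
            raise ValueError("need at least 3 pairs for a regression")


@dataclass(frozen=True)
class CMRSimDesign:
    """Robust-design encounter-history simulation.

    Survival is logit-linear in age (seasons since first capture as a
    neonate), with optional phenotype-group intercept offsets (and slopes)
    and an optional individual covariate acting on intervals whose starting
    age falls inside ``cov_window_ages``.  γ″ is the probability an inside
    animal moves out of the study area before the next occasion; γ′ the
    probability an outside animal stays out.  Detection within a primary
    occasion uses p before the first within-occasion capture and c after.
    """

    schedule: SurveySchedule
    n_released_per_occasion: int = 20
    s_intercept: float = 1.7  # logit scale; expit(1.7) ≈ 0.85 per season
    s_age_slope: float = 0.0
    group_offsets: tuple[float, ...] = ()  # per group beyond baseline group 0
    group_age_slopes: tuple[float, ...] = ()
    cov_beta: float = 0.0
    cov_window_ages: tuple[int, ...] = (0,)
    gamma_prime: float = 0.1
    gamma_dprime: float = 0.1
    p_per_occasion: tuple[float, ...] | float = 0.6
    c_per_occasion: tuple[float, ...] | float = 0.6
    covariate_mean: float = 0.0
    covariate_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.schedule.n_primary < 2:
            raise ValueError("schedule needs at least 2 primary occasions")
        for g in (self.gamma_prime, self.gamma_dprime):
            if not (0.0 <= g <= 1.0):
                raise ValueError("emigration probabilities must lie in [0, 1]")

    def _per_occasion(self, value) -> np.ndarray:
        arr = np.broadcast_to(np.asarray(value, dtype=float),
                              (self.schedule.n_primary,)).copy()
        if np.any((arr < 0) | (arr > 1)):
            raise ValueError("detection probabilities must lie in [0, 1]")
        return arr


# ---------------------------------------------------------------------------
# coat scenes


def _smooth_circular_noise(rng: np.random.Generator, n: int, smooth: int = 12) -> np.ndarray:
    """Zero-mean periodic noise on n boundary vertices, unit max amplitude."""
    raw = rng.standard_normal(n)
    kernel = np.exp(-0.5 * (np.arange(-3 * smooth, 3 * smooth + 1) / smooth) ** 2)
    kernel /= kernel.sum()
    sm = np.convolve(np.tile(raw, 3), kernel, mode="same")[n : 2 * n]
    sm -= sm.mean()
    peak = np.max(np.abs(sm))
    return sm / peak if peak > 0 else sm


def _ellipse_perimeter(a: float, b: float) -> float:
    """Exact ellipse perimeter 4·a·E(e²) with semi-axes a >= b."""
    if a < b:
        a, b = b, a
    m = 1.0 - (b / a) ** 2
    return float(4.0 * a * ellipe(m))


def _polygon_area_perimeter(xs: np.ndarray, ys: np.ndarray) -> tuple[float, float]:
    """Shoelace area and polyline length of a closed polygon."""
    x2, y2 = np.roll(xs, -1), np.roll(ys, -1)
    area = 0.5 * abs(float(np.sum(xs * y2 - x2 * ys)))
    perim = float(np.sum(np.hypot(x2 - xs, y2 - ys)))
    return area, perim


def gen_coat_image(
    params: CoatSceneParams, n_boundary_vertices: int = 256
) -> tuple[np.ndarray, AnalysisRectangle, list[GroundTruthSpot]]:
    """Render a synthetic coat photograph.

    Returns an 8-bit RGB image, the analysis rectangle placed inside it, and
    the ground-truth list of rendered spots.  Spot boundaries are ellipse
    polygons, radially perturbed by smoothed periodic noise with amplitude
    ``boundary_roughness × semi-minor axis``.  Spots may cross the rectangle
    edge (flagged ``touches_edge``) and overlapping spots are flagged
    ``merged`` since the raster fuses them into one component.
    """
    rng = np.random.default_rng(params.seed)
    pad = _EDGE_PAD_PX
    H = params.rect_height_px + 2 * pad
    W = params.rect_width_px + 2 * pad
    rect = AnalysisRectangle(x0=pad, y0=pad, x1=pad + params.rect_width_px,
                             y1=pad + params.rect_height_px)
    px_per_gu = float(params.rect_height_px)
    spot_canvas = np.zeros((H, W), dtype=np.int32)
    truths: list[GroundTruthSpot] = []
    w_gu = params.rect_width_px / px_per_gu
    m = params.placement_margin_gu
    placed: list[tuple[float, float, float]] = []  # (cx, cy, effective radius)
    for i in range(params.n_spots):
        r = params.mean_radius_gu * max(
            0.05, 1.0 + params.radius_cv * rng.standard_normal())
        if r > 0.5:
            raise ValueError("requested spot radius exceeds half the rectangle height")
        aspect = max(1.0, params.aspect_ratio_mean * (
            1.0 + params.aspect_ratio_cv * rng.standard_normal()))
        a = r * np.sqrt(aspect)   # semi-major, GU
        b = r / np.sqrt(aspect)   # semi-minor, GU
        theta = rng.uniform(0.0, 180.0)
        # sequential placement repelling existing spots, like the light
        # reticulation separating spots on a real coat; spots that cannot be
        # separated are still placed and flagged merged by the raster below
        best, best_score = None, -np.inf
        for _ in range(60):
            cx = rng.uniform(m, max(m, w_gu - m))
            cy = rng.uniform(m, max(m, 1.0 - m))
            if not placed:
                best = (cx, cy)
                break
            score = min(np.hypot(cx - px, cy - py) - (r + pr)
                        for px, py, pr in placed)
            if score > best_score:
                best, best_score = (cx, cy), score
            if score > 0.02:
                break
        cx, cy = best
        placed.append((cx, cy, r))
        phi = np.linspace(0.0, 2.0 * np.pi, n_boundary_vertices, endpoint=False)
        ex = a * np.cos(phi)
        ey = b * np.sin(phi)
        if params.boundary_roughness > 0:
            radial = np.hypot(ex, ey)
            bump = params.boundary_roughness * b * _smooth_circular_noise(
                rng, n_boundary_vertices)
            scale = np.clip((radial + bump) / radial, 0.05, None)
            ex, ey = ex * scale, ey * scale
        th = np.deg2rad(theta)
        # y flips because raster y runs downward while theta is mathematical
        bx = cx + ex * np.cos(th) - ey * np.sin(th)
        by = cy - (ex * np.sin(th) + ey * np.cos(th))
        if params.boundary_roughness > 0:
            area, perim = _polygon_area_perimeter(bx, by)
        else:
            area = np.pi * a * b
            perim = _ellipse_perimeter(a, b)
        touches = bool(bx.min() < 0 or by.min() < 0
                       or bx.max() > params.rect_width_px / px_per_gu
                       or by.max() > 1.0)
        rr, cc = draw_polygon(by * px_per_gu + pad, bx * px_per_gu + pad,
                              shape=spot_canvas.shape)
        merged = False
        if rr.size:
            hit = np.unique(spot_canvas[rr, cc])
            hit = hit[hit > 0]
            if hit.size:
                merged = True
                for h in hit:
                    truths[h - 1].merged = True
            spot_canvas[rr, cc] = i + 1
        truths.append(GroundTruthSpot(
            center=(cx, cy), analytic_area=float(area),
            analytic_perimeter=float(perim), major_axis=float(2 * a),
            minor_axis=float(2 * b), orientation_deg=float(theta),
            touches_edge=touches, merged=merged))
    shade = np.full((H, W), float(params.background_shade))
    shade[spot_canvas > 0] = float(params.spot_shade)
    if params.illumination_gradient > 0:
        ramp = np.linspace(1.0 - params.illumination_gradient / 2.0,
                           1.0 + params.illumination_gradient / 2.0, W)
        shade *= ramp[None, :]
    if params.noise_sd > 0:
        shade += params.noise_sd * rng.standard_normal((H, W))
    gray = np.clip(np.round(shade), 0, 255).astype(np.uint8)
    image = np.repeat(gray[:, :, None], 3, axis=2)
    return image, rect, truths


# ---------------------------------------------------------------------------
# mother–calf pairs, repeated measurements, trait clusters


def gen_po_pairs(design: PODesign) -> pd.DataFrame:
    """Mother–calf trait pairs with expected regression slope ``po_slope``.

    Mothers are N(mean, var); calf = mean + slope·(mother − mean) + e with
    var(e) = var·(1 − slope²) so the calf variance equals the mother variance.
    """
    rng = np.random.default_rng(design.seed)
    sd = np.sqrt(design.trait_var)
    mothers = design.trait_mean + sd * rng.standard_normal(design.n_pairs)
    noise_sd = sd * np.sqrt(1.0 - design.po_slope ** 2)
    calves = (design.trait_mean
              + design.po_slope * (mothers - design.trait_mean)
              + noise_sd * rng.standard_normal(design.n_pairs))
    return pd.DataFrame({
        "pair_id": np.arange(design.n_pairs),
        "mother_value": mothers,
        "calf_value": calves,
    })


def gen_repeat_measurements(
    n_individuals: int,
    n_reps: int,
    R_true: float,
    total_var: float = 1.0,
    seed: int = 0,
    trait_name: str = "trait",
    mean: float = 0.0,
) -> pd.DataFrame:
    """Repeated trait measurements with a stated repeatability.

    Individual means carry variance R_true·total_var and within-individual
    residuals (1 − R_true)·total_var, the one-way variance decomposition
    under which the intraclass correlation equals ``R_true``.
    """
    if n_individuals < 2 or n_reps < 2:
        raise ValueError("need >= 2 individuals and >= 2 repeats")
    if not (0.0 <= R_true <= 1.0):
        raise ValueError("R_true must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    sd_a = np.sqrt(R_true * total_var)
    sd_w = np.sqrt((1.0 - R_true) * total_var)
    ind_means = mean + sd_a * rng.standard_normal(n_individuals)
    values = ind_means[:, None] + sd_w * rng.standard_normal((n_individuals, n_reps))
    rows = []
    for i in range(n_individuals):
        for j in range(n_reps):
            rows.append((f"ind{i:03d}", f"photo{j}", trait_name, values[i, j]))
    return pd.DataFrame(rows, columns=["individual_id", "photo_id",
                                       "trait_name", "value"])


def gen_clustered_traits(
    k: int, n_per_cluster: int, separation: float, n_dims: int, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Spherical unit-variance clusters with centres ``separation`` SDs apart.

    Centres sit at scaled coordinate vectors (pairwise distance exactly
    ``separation``); requires ``n_dims >= k`` when k > 1.  Returns (X, labels).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if n_per_cluster < 1:
        raise ValueError("n_per_cluster must be >= 1")
    if k > 1 and n_dims < k:
        raise ValueError("need n_dims >= k to place equidistant centres")
    rng = np.random.default_rng(seed)
    centers = np.zeros((k, n_dims))
    if k > 1:
        centers[:, :k] = np.eye(k) * (separation / np.sqrt(2.0))
    X = np.concatenate([
        centers[g] + rng.standard_normal((n_per_cluster, n_dims))
        for g in range(k)
    ])
    labels = np.repeat(np.arange(k), n_per_cluster)
    return X, labels


# ---------------------------------------------------------------------------
# encounter histories


def gen_encounter_histories(design: CMRSimDesign) -> EncounterHistorySet:
    """Simulate robust-design encounter histories with known parameters.

    Cohorts of neonates enter at every primary occasion except the last; each
    is first captured at the first secondary event of its cohort occasion
    (histories are conditioned on first detection).  The hidden state
    (alive-inside / alive-outside / dead) evolves between primaries with
    age-dependent survival and the temporary-emigration pair (γ′, γ″);
    detection within a primary uses p for the first within-occasion capture
    and c afterwards.  Outside and dead animals are never detected.
    """
    rng = np.random.default_rng(design.seed)
    sched = design.schedule
    T, J = sched.n_primary, sched.n_secondary
    p_occ = design._per_occasion(design.p_per_occasion)
    c_occ = design._per_occasion(design.c_per_occasion)
    n_groups = len(design.group_offsets) + 1 if design.group_offsets else 1
    ids, cohorts, groups, covs = [], [], [], []
    for f in range(T - 1):
        for _ in range(design.n_released_per_occasion):
            ids.append(len(ids))
            cohorts.append(f)
            groups.append(rng.integers(n_groups))
            covs.append(design.covariate_mean
                        + design.covariate_sd * rng.standard_normal())
    n = len(ids)
    cohorts = np.asarray(cohorts)
    groups = np.asarray(groups)
    covs = np.asarray(covs)
    histories = np.zeros((n, T * J), dtype=np.uint8)
    INSIDE, OUTSIDE, DEAD = 0, 1, 2
    for i in range(n):
        f = cohorts[i]
        state = INSIDE
        histories[i, f * J] = 1  # forced first capture as a neonate
        captured_this_primary = True
        for j in range(1, J):
            pr = c_occ[f] if captured_this_primary else p_occ[f]
            if rng.random() < pr:
                histories[i, f * J + j] = 1
                captured_this_primary = True
        for t in range(f + 1, T):
            age = t - 1 - f  # age at the start of the interval (seasons)
            logit = design.s_intercept + design.s_age_slope * age
            g = groups[i]
            if g > 0 and design.group_offsets:
                logit += design.group_offsets[g - 1]
                if design.group_age_slopes:
                    logit += design.group_age_slopes[g - 1] * age
            if design.cov_beta != 0.0 and age in design.cov_window_ages:
                logit += design.cov_beta * covs[i]
            s = expit(logit)
            if state == DEAD or rng.random() > s:
                state = DEAD
                continue
            if state == INSIDE:
                state = OUTSIDE if rng.random() < design.gamma_dprime else INSIDE
            else:
                state = OUTSIDE if rng.random() < design.gamma_prime else INSIDE
            if state == INSIDE:
                captured_this_primary = False
                for j in range(J):
                    pr = c_occ[t] if captured_this_primary else p_occ[t]
                    if rng.random() < pr:
                        histories[i, t * J + j] = 1
                        captured_this_primary = True
    covariates = pd.DataFrame({"cov": covs})
    return EncounterHistorySet(
        histories=histories,
        freq=np.ones(n, dtype=int),
        schedule=sched,
        groups=groups if n_groups > 1 else None,
        covariates=covariates,
        age_at_first=np.zeros(n, dtype=int),
    )
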