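"""Shared fixtures: small rendered scenes and raster helpers."""

import numpy as np
import pytest

from spotpatterns import CoatSceneParams, gen_coat_image
from spotpatterns.extraction import extract_spot_map


def render_blob(mask_2d: np.ndarray) -> np.ndarray:
    """Boolean mask → coordinate array (n, 2) of (y, x) pixels."""
    return np.argwhere(np.asarray(mask_2d, dtype=bool))


def rasterize_ellipse(semi_a: float, semi_b: float, angle_deg: float = 0.0,
                      size: int = 0) -> np.ndarray:
    """Boolean raster of an ellipse rotated by ``angle_deg`` (mathematical,
    counter-clockwise, y up)."""
    if size == 0:
        size = int(2 * max(semi_a, semi_b)) + 10
    c = size / 2.0 - 0.5
    yy, xx = np.mgrid[0:size, 0:size]
    x = xx - c
    y = -(yy - c)  # flip raster y to mathematical orientation
    th = np.deg2rad(angle_deg)
    u = x * np.cos(th) + y * np.sin(th)
    v = -x * np.sin(th) + y * np.cos(th)
    return (u / semi_a) ** 2 + (v / semi_b) ** 2 <= 1.0


def random_component(rng: np.random.Generator, size: int = 40) -> np.ndarray:
    """One random connected blob: union of a few random disks."""
    yy, xx = np.mgrid[0:size, 0:size]
    mask = np.zeros((size, size), dtype=bool)
    cy, cx = size / 2, size / 2
    for _ in range(rng.integers(1, 5)):
        r = rng.uniform(3, size / 5)
        oy = cy + rng.uniform(-size / 6, size / 6)
        ox = cx + rng.uniform(-size / 6, size / 6)
        mask |= (yy - oy) ** 2 + (xx - ox) ** 2 <= r ** 2
    return mask


@pytest.fixture(scope="session")
def clean_circle_scene():
    """One smooth interior circle, radius 0.1 GU, noise-free."""
    params = CoatSceneParams(
        n_spots=1, mean_radius_gu=0.1, radius_cv=0.0, aspect_ratio_mean=1.0,
        aspect_ratio_cv=0.0, boundary_roughness=0.0,
        illumination_gradient=0.0, noise_sd=0.0, placement_margin_gu=0.3,
        seed=5)
    image, rect, truth = gen_coat_image(params)
    labeled, color_rect = extract_spot_map(image, rect)
    return image, rect, truth, labeled, color_rect


@pytest.fixture(scope="session")
def default_scene():
    """A realistic multi-spot scene with noise and roughened boundaries."""
    params = CoatSceneParams(seed=1)
    image, rect, truth = gen_coat_image(params)
    labeled, color_rect = extract_spot_map(image, rect)
    return image, rect, truth, labeled, color_rect
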