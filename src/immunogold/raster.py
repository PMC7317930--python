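"""Rasterization of synthetic scenes into micrograph-like images.

Particles are drawn as dark anti-aliased disks (~10 nm across) on a bright
textured background: a base grey level, a low-frequency multiplicative-free
shading field (Gaussian-filtered noise) and per-pixel additive Gaussian
noise.  The output is a float image in [0, 1]; :func:`to_uint16` converts
for 16-bit TIFF export.  Ground-truth coordinates are unchanged by
rasterization; the image origin in nm is reported so detections can be
mapped back into the scene frame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage


@dataclass(frozen=True)
class NoiseModel:
    """Raster noise/texture parameters (intensities on a 0-1 scale)."""

    background_level: float = 0.78
    particle_contrast: float = 0.55
    shading_amplitude: float = 0.06
    shading_sigma_px: float = 150.0
    noise_sigma: float = 0.03


QUIET = NoiseModel(shading_amplitude=0.0, noise_sigma=0.0)


def _disk_coverage(shape, centers_px, radius_px):
    """Anti-aliased disk coverage in [0, 1] accumulated by maximum."""
    cov = np.zeros(shape)
    r_out = radius_px + 1.0
    h, w = shape
    for cx, cy in centers_px:
        c0, c1 = int(np.floor(cx - r_out)), int(np.ceil(cx + r_out)) + 1
        r0, r1 = int(np.floor(cy - r_out)), int(np.ceil(cy + r_out)) + 1
        c0, r0 = max(c0, 0), max(r0, 0)
        c1, r1 = min(c1, w), min(r1, h)
        if c0 >= c1 or r0 >= r1:
            continue
        yy, xx = np.mgrid[r0:r1, c0:c1]
        d = np.hypot(xx + 0.5 - cx, yy + 0.5 - cy)
        patch = np.clip(radius_px + 0.5 - d, 0.0, 1.0)
        np.maximum(cov[r0:r1, c0:c1], patch, out=cov[r0:r1, c0:c1])
    return cov


def rasterize(
    scene,
    nm_per_px: float | None = None,
    noise: NoiseModel = NoiseModel(),
    rng: np.random.Generator | None = None,
    *,
    particle_diameter_nm: float = 10.0,
    margin_nm: float = 50.0,
) -> np.ndarray:
    """Render a scene; stores the image and origin on the scene and returns it."""
    if nm_per_px is None:
        nm_per_px = scene.nm_per_px
    if not 0.5 <= nm_per_px <= 5.0:
        raise ValueError("nm_per_px must be in [0.5, 5]")
    if rng is None:
        rng = np.random.default_rng(scene.seed)
    radius_px = 0.5 * particle_diameter_nm / nm_per_px
    if 2 * radius_px < 2.0:
        warnings.warn(
            "particle diameter below 2 px at this scale; detection unreliable",
            stacklevel=2,
        )

    bounds = np.array([p.polygon.bounds for p in scene.profiles])
    if len(bounds):
        minx = bounds[:, 0].min() - margin_nm
        miny = bounds[:, 1].min() - margin_nm
        maxx = bounds[:, 2].max() + margin_nm
        maxy = bounds[:, 3].max() + margin_nm
    else:
        minx = miny = 0.0
        maxx = maxy = 100 * nm_per_px
    w = int(np.ceil((maxx - minx) / nm_per_px))
    h = int(np.ceil((maxy - miny) / nm_per_px))

    img = np.full((h, w), noise.background_level)
    if noise.shading_amplitude > 0:
        # low-frequency field: filter on a coarse grid, then upsample
        ds = max(int(noise.shading_sigma_px / 12), 1)
        hs, ws = int(np.ceil(h / ds)) + 1, int(np.ceil(w / ds)) + 1
        field = rng.normal(0.0, 1.0, size=(hs, ws))
        field = ndimage.gaussian_filter(field, noise.shading_sigma_px / ds)
        sd = field.std()
        if sd > 0:
            field = ndimage.zoom(field / sd, ds, order=1)
            img += noise.shading_amplitude * field[:h, :w]

    if len(scene.particles):
        centers_px = np.column_stack(
            [
                (scene.particles["x_nm"].to_numpy() - minx) / nm_per_px,
                (scene.particles["y_nm"].to_numpy() - miny) / nm_per_px,
            ]
        )
        cov = _disk_coverage((h, w), centers_px, radius_px)
        img -= noise.particle_contrast * cov

    if noise.noise_sigma > 0:
        img += rng.normal(0.0, noise.noise_sigma, size=(h, w))

    img = np.clip(img, 0.0, 1.0)
    scene.raster = img
    scene.raster_origin_nm = (minx, miny)
    scene.nm_per_px = nm_per_px
    return img


def to_uint16(img: np.ndarray) -> np.ndarray:
    return np.round(np.clip(img, 0.0, 1.0) * 65535).astype(np.uint16)


def from_integer(img: np.ndarray) -> np.ndarray:
    """Normalise an integer image to float [0, 1]."""
    if np.issubdtype(img.dtype, np.integer):
        return img.astype(float) / np.iinfo(img.dtype).max
    return img.astype(float)
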