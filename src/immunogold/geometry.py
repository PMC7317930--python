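"""Profile geometry: membrane-profile polygons in nm coordinates.

Coordinates are continuous nanometres with the origin at the image top-left
and y increasing downwards (image convention).  Polygons are closed simple
rings; areas are reported in square micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import shapely.affinity
from shapely.geometry import LineString, Point, Polygon

from .compartments import CompartmentClass

NM2_PER_UM2 = 1e6


@dataclass
class ProfileGeometry:
    """One membrane profile (P-face, E-face or cross-fracture).

    Parameters
    ----------
    id : str
        Unique profile identifier within a scene.
    polygon : shapely.Polygon
        Simple closed outline, nm coordinates.
    face : str
        ``"P"``, ``"E"`` or ``"cross_fracture"``.
    compartment : CompartmentClass
    subregions : dict
        Optional named interior polygons, e.g. ``{"active_zone": Polygon}``.
    membrane_contour : shapely.LineString, optional
        Plasma-membrane contour for pre-embedding profiles (defaults to the
        polygon boundary when membrane analysis is requested).
    animal_id : str
        Experimental-unit tag used for between-animal aggregation.
    """

    id: str
    polygon: Polygon
    face: str = "P"
    compartment: Optional[CompartmentClass] = None
    subregions: dict[str, Polygon] = field(default_factory=dict)
    membrane_contour: Optional[LineString] = None
    animal_id: str = "a1"

    def __post_init__(self) -> None:
        if not self.polygon.is_valid or self.polygon.is_empty:
            raise ValueError(f"profile {self.id}: polygon is not simple/valid")
        if self.polygon.area <= 0:
            raise ValueError(f"profile {self.id}: zero-area polygon")
        for name, sub in self.subregions.items():
            if not self.polygon.buffer(1e-6).contains(sub):
                raise ValueError(
                    f"profile {self.id}: subregion {name!r} not contained in outline"
                )

    @property
    def area_um2(self) -> float:
        return self.polygon.area / NM2_PER_UM2

    def subregion_area_um2(self, name: str) -> float:
        return self.subregions[name].area / NM2_PER_UM2

    def contour(self) -> LineString:
        if self.membrane_contour is not None:
            return self.membrane_contour
        return LineString(self.polygon.exterior.coords)


def radial_polygon(
    area_um2: float,
    rng: np.random.Generator,
    *,
    n_vertices: int = 24,
    roughness: float = 0.12,
    elongation: float = 1.0,
    center_nm: tuple[float, float] = (0.0, 0.0),
) -> Polygon:
    """Random star-shaped polygon of exact target area.

    Radii are smoothly perturbed around a circle, the shape optionally
    stretched along x, then rescaled so ``polygon.area`` equals the target.
    Star-shapedness about the generation centre guarantees simplicity.
    """
    if area_um2 <= 0:
        raise ValueError("area must be positive")
    theta = np.linspace(0.0, 2 * np.pi, n_vertices, endpoint=False)
    # low-frequency perturbation so adjacent radii stay coherent
    harmonics = np.zeros_like(theta)
    for k in (2, 3, 5):
        harmonics += rng.normal(0, 1) * np.cos(k * theta) + rng.normal(0, 1) * np.sin(
            k * theta
        )
    r = 1.0 + roughness * harmonics / np.sqrt(6)
    r = np.clip(r, 0.35, None)
    x = r * np.cos(theta) * elongation
    y = r * np.sin(theta)
    poly = Polygon(np.column_stack([x, y]))
    scale = np.sqrt(area_um2 * NM2_PER_UM2 / poly.area)
    poly = shapely.affinity.scale(poly, scale, scale, origin=(0, 0))
    return shapely.affinity.translate(poly, xoff=center_nm[0], yoff=center_nm[1])


def interior_subpolygon(
    polygon: Polygon,
    area_fraction: float,
    *,
    origin: Optional[tuple[float, float]] = None,
) -> Polygon:
    """Scaled-down copy of ``polygon`` about an interior origin.

    For star-shaped polygons scaling about the star centre keeps the copy
    strictly inside; used for active-zone subregions.
    """
    if not 0 < area_fraction < 1:
        raise ValueError("area_fraction must be in (0, 1)")
    if origin is None:
        c = polygon.centroid
        origin = (c.x, c.y)
    f = np.sqrt(area_fraction)
    sub = shapely.affinity.scale(polygon, f, f, origin=origin)
    if not polygon.buffer(1e-6).contains(sub):
        sub = shapely.affinity.scale(
            polygon, f, f, origin=(polygon.centroid.x, polygon.centroid.y)
        )
    return sub


def sample_uniform_in_polygon(
    polygon: Polygon, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Uniform points inside a polygon by bounding-box rejection."""
    if n == 0:
        return np.empty((0, 2))
    minx, miny, maxx, maxy = polygon.bounds
    out = np.empty((n, 2))
    filled = 0
    # vectorised rejection; acceptance ratio = area / bbox area
    batch = max(16, int(n / max(polygon.area / ((maxx - minx) * (maxy - miny)), 0.05)))
    while filled < n:
        pts = np.column_stack(
            [rng.uniform(minx, maxx, batch), rng.uniform(miny, maxy, batch)]
        )
        keep = shapely.contains_xy(polygon, pts[:, 0], pts[:, 1])
        take = min(int(keep.sum()), n - filled)
        out[filled : filled + take] = pts[keep][:take]
        filled += take
    return out


def point_to_contour_distance(contour: LineString, xy: np.ndarray) -> np.ndarray:
    """Perpendicular distance of each point to a membrane contour (nm)."""
    return np.array([contour.distance(Point(p)) for p in np.atleast_2d(xy)])
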