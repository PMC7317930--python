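"""Synthetic replica and pre-embedding scene generation with ground truth.

The SDS-FRL point pattern is a superposition of a clustered parent-offspring
(Thomas-like) process and a homogeneous scattered process:

* cluster centres: homogeneous Poisson at ``lambda_c`` centres/um^2,
* offspring per centre: ``K = 3 + Poisson(mu_k - 3)`` — always at least
  three particles, so every planted cluster satisfies the min-3 membership
  rule used by the cluster analysis; the scattered process supplies
  sub-threshold groups,
* offspring displacement: isotropic Gaussian with scale ``sigma_r``,
  truncated at ``3 sigma_r`` so cluster support is bounded,
* scattered particles: homogeneous Poisson at ``lambda_s`` particles/um^2.

The expected total count on a profile of area ``A`` um^2 is
``A * (lambda_c * mu_k + lambda_s)``.

Every generated particle carries its generating label (``cluster`` with a
cluster id, ``scattered``, ``background``, ``az``/``extrasynaptic``,
``membrane``/``intracellular``), which is what makes each downstream stage
testable against known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString, Point, Polygon

from .calibration import Calibration, PointProcessRecord
from .compartments import CompartmentClass, Klass, Layer
from .geometry import (
    NM2_PER_UM2,
    ProfileGeometry,
    interior_subpolygon,
    radial_polygon,
    sample_uniform_in_polygon,
)

#: canonical particle-table schema
PARTICLE_COLUMNS = ["scene_id", "profile_id", "x_nm", "y_nm", "label", "cluster_id"]


def empty_particles() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "scene_id": pd.Series(dtype=str),
            "profile_id": pd.Series(dtype=str),
            "x_nm": pd.Series(dtype=float),
            "y_nm": pd.Series(dtype=float),
            "label": pd.Series(dtype=str),
            "cluster_id": pd.Series(dtype="Int64"),
        }
    )


def _particles_frame(
    xy: np.ndarray,
    label: str | Sequence[str],
    profile_id: str,
    cluster_id=None,
    scene_id: str = "",
) -> pd.DataFrame:
    n = len(xy)
    if cluster_id is None:
        cluster_id = pd.array([pd.NA] * n, dtype="Int64")
    return pd.DataFrame(
        {
            "scene_id": [scene_id] * n,
            "profile_id": [profile_id] * n,
            "x_nm": xy[:, 0] if n else np.array([]),
            "y_nm": xy[:, 1] if n else np.array([]),
            "label": label if not isinstance(label, str) else [label] * n,
            "cluster_id": cluster_id,
        }
    )


def _truncated_gaussian_offsets(
    n: int, sigma: float, rng: np.random.Generator, max_radius_factor: float = 3.0
) -> np.ndarray:
    """Isotropic Gaussian displacements truncated at ``3 sigma``."""
    out = np.empty((n, 2))
    filled = 0
    while filled < n:
        cand = rng.normal(0.0, sigma, size=(2 * (n - filled) + 8, 2))
        keep = np.hypot(cand[:, 0], cand[:, 1]) <= max_radius_factor * sigma
        take = min(int(keep.sum()), n - filled)
        out[filled : filled + take] = cand[keep][:take]
        filled += take
    return out


def sample_point_pattern(
    profile: ProfileGeometry,
    record: PointProcessRecord,
    rng: np.random.Generator,
    *,
    scene_id: str = "",
) -> pd.DataFrame:
    """Clustered + scattered SDS-FRL point pattern on a P-face profile.

    Offspring whose truncated-Gaussian displacement would leave the profile
    are re-drawn, so particle counts (and hence densities) are conserved at
    the cost of slight anisotropy against the membrane edge.
    """
    if profile.face != "P":
        raise ValueError("SDS-FRL point patterns are generated on P-face profiles")
    if profile.polygon.area <= 0:
        raise ValueError("zero-area profile")
    area = profile.area_um2
    frames = []

    n_parents = rng.poisson(record.clustered_intensity * area)
    if n_parents > 0:
        parents = sample_uniform_in_polygon(profile.polygon, n_parents, rng)
        extra = max(record.offspring_mean - 3.0, 0.0)
        sizes = 3 + rng.poisson(extra, size=n_parents)
        for ci, (cx, cy) in enumerate(parents):
            pts = np.empty((sizes[ci], 2))
            for j in range(sizes[ci]):
                for _ in range(200):
                    off = _truncated_gaussian_offsets(1, record.cluster_radius_nm, rng)[0]
                    p = (cx + off[0], cy + off[1])
                    if shapely.contains_xy(profile.polygon, p[0], p[1]):
                        pts[j] = p
                        break
                else:  # pathologically thin profile: fall back to the parent
                    pts[j] = (cx, cy)
            frames.append(
                _particles_frame(
                    pts,
                    "cluster",
                    profile.id,
                    cluster_id=pd.array([ci] * sizes[ci], dtype="Int64"),
                    scene_id=scene_id,
                )
            )

    n_scattered = rng.poisson(record.scattered_intensity * area)
    if n_scattered > 0:
        pts = sample_uniform_in_polygon(profile.polygon, n_scattered, rng)
        frames.append(_particles_frame(pts, "scattered", profile.id, scene_id=scene_id))

    if not frames:
        return empty_particles()
    return pd.concat(frames, ignore_index=True)


def sample_background(
    profile: ProfileGeometry,
    intensity_per_um2: float,
    rng: np.random.Generator,
    *,
    scene_id: str = "",
) -> pd.DataFrame:
    """Homogeneous nonspecific labeling (E-face background process)."""
    if intensity_per_um2 < 0:
        raise ValueError("negative background intensity")
    n = rng.poisson(intensity_per_um2 * profile.area_um2)
    if n == 0:
        return empty_particles()
    pts = sample_uniform_in_polygon(profile.polygon, n, rng)
    return _particles_frame(pts, "background", profile.id, scene_id=scene_id)


def sample_presynaptic_pattern(
    profile: ProfileGeometry,
    az_intensity: float,
    extra_intensity: float,
    rng: np.random.Generator,
    *,
    scene_id: str = "",
) -> pd.DataFrame:
    """Independent homogeneous processes inside and outside the active zone."""
    if "active_zone" not in profile.subregions:
        raise ValueError("profile has no active_zone subregion")
    if az_intensity < 0 or extra_intensity < 0:
        raise ValueError("intensities must be non-negative")
    az = profile.subregions["active_zone"]
    if not profile.polygon.buffer(1e-6).contains(az):
        raise ValueError("active zone not contained in terminal outline")
    extra_region = profile.polygon.difference(az)

    frames = []
    n_az = rng.poisson(az_intensity * az.area / NM2_PER_UM2)
    if n_az:
        pts = sample_uniform_in_polygon(az, n_az, rng)
        frames.append(_particles_frame(pts, "az", profile.id, scene_id=scene_id))
    n_ex = rng.poisson(extra_intensity * extra_region.area / NM2_PER_UM2)
    if n_ex:
        pts = sample_uniform_in_polygon(extra_region, n_ex, rng)
        frames.append(
            _particles_frame(pts, "extrasynaptic", profile.id, scene_id=scene_id)
        )
    if not frames:
        return empty_particles()
    return pd.concat(frames, ignore_index=True)


def _inward_normal(contour: LineString, s: float, eps: float = 1.0) -> np.ndarray:
    a = contour.interpolate(max(s - eps, 0.0))
    b = contour.interpolate(min(s + eps, contour.length))
    t = np.array([b.x - a.x, b.y - a.y])
    norm = np.hypot(*t)
    if norm == 0:
        return np.array([0.0, 0.0])
    t /= norm
    return np.array([-t[1], t[0]])  # either side; caller tests both


def sample_pre_embedding(
    profile: ProfileGeometry,
    total_count_mean: float,
    p_membrane: float,
    d_offset_nm: float,
    rng: np.random.Generator,
    *,
    scene_id: str = "",
) -> pd.DataFrame:
    """Membrane/intracellular particle split for pre-embedding profiles.

    Each particle is membrane-associated with probability ``p_membrane`` and
    placed within ``d_offset_nm`` of the membrane contour; intracellular
    particles are uniform in the profile interior eroded by the same
    distance (silver-enhanced particles further than the association
    distance from any membrane are scored intracellular).
    """
    if not 0 <= p_membrane <= 1:
        raise ValueError("p_membrane must be in [0, 1]")
    contour = profile.contour()
    if contour is None or contour.length <= 0:
        raise ValueError("membrane contour absent or degenerate")
    n = int(rng.poisson(total_count_mean))
    if n == 0:
        return empty_particles()
    is_mem = rng.random(n) < p_membrane

    interior = profile.polygon.buffer(-d_offset_nm)
    if interior.is_empty:
        interior = profile.polygon  # degenerate thin profile

    pts = np.empty((n, 2))
    labels = np.where(is_mem, "membrane", "intracellular")
    n_intra = int((~is_mem).sum())
    if n_intra:
        pts[~is_mem] = sample_uniform_in_polygon(interior, n_intra, rng)
    for i in np.flatnonzero(is_mem):
        for _ in range(500):
            s = rng.uniform(0.0, contour.length)
            u = rng.uniform(0.0, d_offset_nm)
            base = contour.interpolate(s)
            nrm = _inward_normal(contour, s)
            for sign in (1.0, -1.0):
                cand = (base.x + sign * u * nrm[0], base.y + sign * u * nrm[1])
                if shapely.contains_xy(profile.polygon, cand[0], cand[1]):
                    pts[i] = cand
                    break
            else:
                continue
            break
        else:
            pts[i] = (base.x, base.y)
    return _particles_frame(pts, list(labels), profile.id, scene_id=scene_id)


def _connected_at(pts: np.ndarray, link_nm: float) -> bool:
    n = len(pts)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if np.hypot(*(pts[i] - pts[j])) <= link_nm:
                parent[find(i)] = find(j)
    return len({find(i) for i in range(n)}) == 1


def plant_clusters(
    profiles: Sequence[ProfileGeometry],
    n_clusters_total: int,
    size_range: tuple[int, int],
    size_geometric_p: float,
    cluster_radius_nm: float,
    min_center_separation_nm: float,
    rng: np.random.Generator,
    *,
    scene_id: str = "",
    connectivity_distance_nm: float = 50.0,
) -> pd.DataFrame:
    """Plant an exact number of well-separated clusters across profiles.

    Cluster sizes are ``3 + Geometric(p)`` truncated to ``size_range``;
    centres follow a hard-core (minimum-separation) process inside each
    profile eroded by the cluster support radius, so clusters never touch
    each other or a profile boundary.  Member displacements are resampled
    until each planted cluster is internally single-linkage connected at
    ``connectivity_distance_nm`` — a planted cluster is, by definition, one
    aggregation, so its members must form one linkage component.  Cluster
    counts are apportioned to profiles multinomially by area.
    """
    lo, hi = size_range
    if lo < 3:
        raise ValueError("minimum cluster size is 3")
    margin = 3.0 * cluster_radius_nm + 5.0
    areas = np.array([p.polygon.area for p in profiles], float)
    counts = rng.multinomial(n_clusters_total, areas / areas.sum())

    frames = []
    next_id = 0
    for profile, n_here in zip(profiles, counts):
        if n_here == 0:
            continue
        core = profile.polygon.buffer(-margin)
        if core.is_empty:
            raise ValueError(f"profile {profile.id} too small for planting margin")
        centers: list[tuple[float, float]] = []
        attempts = 0
        while len(centers) < n_here:
            attempts += 1
            if attempts > 500 * n_here:
                raise RuntimeError(
                    "could not place hard-core cluster centres; lower the "
                    "separation or the per-profile count"
                )
            cand = sample_uniform_in_polygon(core, 1, rng)[0]
            if all(
                np.hypot(cand[0] - cx, cand[1] - cy) >= min_center_separation_nm
                for cx, cy in centers
            ):
                centers.append((cand[0], cand[1]))
        for cx, cy in centers:
            while True:
                size = 3 + int(rng.geometric(size_geometric_p)) - 1
                if size <= hi:
                    break
            for _ in range(1000):
                offs = _truncated_gaussian_offsets(size, cluster_radius_nm, rng)
                if _connected_at(offs, connectivity_distance_nm):
                    break
            pts = np.column_stack([cx + offs[:, 0], cy + offs[:, 1]])
            frames.append(
                _particles_frame(
                    pts,
                    "cluster",
                    profile.id,
                    cluster_id=pd.array([next_id] * size, dtype="Int64"),
                    scene_id=scene_id,
                )
            )
            next_id += 1
    if not frames:
        return empty_particles()
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# scene assembly
# ---------------------------------------------------------------------------


@dataclass
class Scene:
    """One synthetic micrograph: profiles, truth particles, raster metadata."""

    profiles: list[ProfileGeometry]
    particles: pd.DataFrame
    mode: str = "sds_frl"  # or "pre_embedding"
    nm_per_px: float = 1.0
    seed: Optional[int] = None
    raster: Optional[np.ndarray] = None
    raster_origin_nm: tuple[float, float] = (0.0, 0.0)
    meta: dict = field(default_factory=dict)

    def profile(self, profile_id: str) -> ProfileGeometry:
        for p in self.profiles:
            if p.id == profile_id:
                return p
        raise KeyError(profile_id)


def make_profile(
    compartment: CompartmentClass,
    area_um2: float,
    rng: np.random.Generator,
    *,
    profile_id: str = "p0",
    face: str = "P",
    animal_id: str = "a1",
    with_active_zone: bool = False,
    az_area_fraction: float = 0.125,
    center_nm: tuple[float, float] = (0.0, 0.0),
) -> ProfileGeometry:
    """Random membrane profile of the requested compartment class."""
    elongation = {
        Klass.APICAL_DENDRITE: 2.5,
        Klass.OBLIQUE_DENDRITE: 2.0,
        Klass.AXON_TERMINAL: 1.3,
    }.get(compartment.klass, 1.0)
    poly = radial_polygon(
        area_um2, rng, elongation=elongation, center_nm=center_nm
    )
    subregions = {}
    if with_active_zone:
        # offset the AZ from the centroid towards the membrane apposition
        c = poly.centroid
        subregions["active_zone"] = interior_subpolygon(
            poly, az_area_fraction, origin=(c.x, c.y)
        )
    return ProfileGeometry(
        id=profile_id,
        polygon=poly,
        face=face,
        compartment=compartment,
        subregions=subregions,
        animal_id=animal_id,
    )


def condition_scene(
    calibration: Calibration,
    genotype: str,
    age_months: int,
    compartment_key: str,
    n_profiles: int,
    seed: int,
    *,
    n_animals: Optional[int] = None,
    with_eface: bool = False,
) -> Scene:
    """All profiles of one (genotype, age, compartment) condition.

    Profiles are laid out on a grid (one synthetic micrograph per
    condition), tagged round-robin with animal ids, and carry a multiplicative
    lognormal between-animal effect on the generating intensity.
    """
    rng = np.random.default_rng(seed)
    comp = CompartmentClass.from_key(compartment_key)
    record = calibration.point_process_record(genotype, age_months, compartment_key)
    area = calibration.profile_area_um2(comp.klass.value)
    cv = float(calibration.raw.get("animal_effect_cv", 0.0))
    if n_animals is None:
        n_animals = int(calibration.raw.get("n_animals", 4))
    sigma_ln = np.sqrt(np.log(1 + cv**2)) if cv > 0 else 0.0
    animal_factor = {
        f"a{i+1}": float(np.exp(rng.normal(-0.5 * sigma_ln**2, sigma_ln)))
        if sigma_ln > 0
        else 1.0
        for i in range(n_animals)
    }

    # grid layout with clearance between profiles
    pitch = np.sqrt(area * NM2_PER_UM2) * 3.0 + 200.0
    ncol = int(np.ceil(np.sqrt(n_profiles)))
    profiles, frames = [], []
    scene_id = f"{genotype}_{age_months}mo_{compartment_key.replace('/', '_')}"
    for i in range(n_profiles):
        cx = (i % ncol + 0.5) * pitch
        cy = (i // ncol + 0.5) * pitch
        animal = f"a{i % n_animals + 1}"
        prof = make_profile(
            comp,
            area,
            rng,
            profile_id=f"{scene_id}_p{i:03d}",
            animal_id=animal,
            center_nm=(cx, cy),
        )
        profiles.append(prof)
        f = animal_factor[animal]
        rec_i = PointProcessRecord(
            clustered_intensity=record.clustered_intensity * f,
            offspring_mean=record.offspring_mean,
            cluster_radius_nm=record.cluster_radius_nm,
            scattered_intensity=record.scattered_intensity * f,
            eface_background=record.eface_background,
        )
        frames.append(sample_point_pattern(prof, rec_i, rng, scene_id=scene_id))
        if with_eface:
            eprof = make_profile(
                comp,
                area * 0.6,
                rng,
                profile_id=f"{scene_id}_e{i:03d}",
                face="E",
                animal_id=animal,
                center_nm=(cx + pitch / 2.0, cy),
            )
            profiles.append(eprof)
            frames.append(
                sample_background(
                    eprof, record.eface_background, rng, scene_id=scene_id
                )
            )
    particles = (
        pd.concat(frames, ignore_index=True) if frames else empty_particles()
    )
    return Scene(
        profiles=profiles,
        particles=particles,
        mode="sds_frl",
        nm_per_px=calibration.nm_per_px,
        seed=seed,
        meta={
            "genotype": genotype,
            "age_months": age_months,
            "compartment": compartment_key,
            "generating_density_per_um2": record.total_density,
        },
    )
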