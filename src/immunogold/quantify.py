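"""Compartment-wise quantification: particle assignment, surface densities,
background correction, presynaptic partitioning and the pre-embedding
membrane/intracellular split.

Densities are particles per square micrometre of membrane profile.  The
gradient table aggregates in two stages — profiles to animal means, animal
means to group mean +/- SEM — so the experimental unit is the animal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import shapely

from .compartments import GRADIENT_COMPARTMENTS
from .geometry import NM2_PER_UM2, ProfileGeometry, point_to_contour_distance

#: profiles smaller than this are excluded from density analyses
MIN_PROFILE_AREA_UM2 = 0.01


@dataclass(frozen=True)
class DensityRecord:
    profile_id: str
    n_particles: int
    area_um2: float
    density_per_um2: float
    corrected_density: Optional[float] = None
    background_flag: bool = False
    condition: Optional[dict] = None


@dataclass(frozen=True)
class PartitionRecord:
    profile_id: str
    counts: dict[str, int]
    percentages: Optional[dict[str, float]]  # None when total == 0

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def assign_particles(
    particles: pd.DataFrame, profiles: Sequence[ProfileGeometry]
) -> pd.DataFrame:
    """Point-in-polygon assignment of particles to profiles.

    Boundary points within 1 nm of an edge are assigned to the containing
    profile; particles in no profile get ``profile_id = "outside"``.
    Overlapping profiles are an input error.
    """
    for i in range(len(profiles)):
        for j in range(i + 1, len(profiles)):
            inter = profiles[i].polygon.intersection(profiles[j].polygon)
            if inter.area > 1e-6:
                raise ValueError(
                    f"overlapping profiles: {profiles[i].id} and {profiles[j].id}"
                )
    out = particles.copy()
    x = out["x_nm"].to_numpy(float)
    y = out["y_nm"].to_numpy(float)
    assigned = np.full(len(out), "outside", dtype=object)
    unass = np.ones(len(out), bool)
    for prof in profiles:
        if not unass.any():
            break
        inside = np.zeros(len(out), bool)
        inside[unass] = shapely.contains_xy(prof.polygon, x[unass], y[unass])
        # boundary tolerance: points within 1 nm of the outline
        near = unass & ~inside
        if near.any():
            inside[near] = shapely.dwithin(
                prof.polygon, shapely.points(np.column_stack([x, y])[near]), 1.0
            )
        assigned[inside] = prof.id
        unass &= ~inside
    out["profile_id"] = assigned
    return out


def compute_density(
    particles: pd.DataFrame, profile: ProfileGeometry, *, condition: dict | None = None
) -> DensityRecord:
    """Particles per um^2 on one profile (count / area, exact ratio)."""
    area = profile.area_um2
    if area <= 0:
        raise ValueError(f"profile {profile.id}: zero area")
    n = int((particles["profile_id"] == profile.id).sum())
    return DensityRecord(
        profile_id=profile.id,
        n_particles=n,
        area_um2=area,
        density_per_um2=n / area,
        condition=condition,
    )


def background_correct(
    pface_density: float, eface_density: float
) -> tuple[float, bool]:
    """Subtract nonspecific E-face labeling; floor at zero with a flag."""
    if pface_density < 0 or eface_density < 0:
        raise ValueError("densities must be non-negative")
    corrected = pface_density - eface_density
    if corrected < 0:
        return 0.0, True
    return corrected, False


def split_presynaptic(
    particles: pd.DataFrame, profile: ProfileGeometry
) -> tuple[PartitionRecord, dict[str, DensityRecord]]:
    """Partition terminal particles into active-zone vs extrasynaptic.

    Returns the count partition and per-subregion density records (using
    the active-zone and remaining-membrane areas respectively).
    """
    if "active_zone" not in profile.subregions:
        raise ValueError("terminal profile has no active_zone subregion")
    az = profile.subregions["active_zone"]
    az_area = az.area / NM2_PER_UM2
    if az_area <= 0:
        raise ValueError("active zone has zero area")
    mine = particles[particles["profile_id"] == profile.id]
    x = mine["x_nm"].to_numpy(float)
    y = mine["y_nm"].to_numpy(float)
    in_az = shapely.contains_xy(az, x, y)
    # boundary tolerance consistent with assign_particles
    near = ~in_az
    if near.any():
        in_az[near] = shapely.dwithin(
            az, shapely.points(np.column_stack([x, y])[near]), 1.0
        )
    n_az = int(in_az.sum())
    n_ex = len(mine) - n_az
    total = n_az + n_ex
    counts = {"az": n_az, "extrasynaptic": n_ex}
    percentages = (
        {k: 100.0 * v / total for k, v in counts.items()} if total else None
    )
    extra_area = profile.area_um2 - az_area
    densities = {
        "az": DensityRecord(profile.id, n_az, az_area, n_az / az_area),
        "extrasynaptic": DensityRecord(
            profile.id, n_ex, extra_area, n_ex / extra_area
        ),
    }
    return PartitionRecord(profile.id, counts, percentages), densities


def classify_membrane(
    particles: pd.DataFrame, profile: ProfileGeometry, d_mem_nm: float = 25.0
) -> tuple[PartitionRecord, pd.DataFrame]:
    """Membrane vs intracellular split for pre-embedding profiles.

    A particle is membrane-associated iff its perpendicular distance to the
    membrane contour is at most ``d_mem_nm`` (count is monotone
    non-decreasing in the threshold).
    """
    if d_mem_nm <= 0:
        raise ValueError("d_mem_nm must be positive")
    contour = profile.contour()
    if contour is None or contour.length <= 0:
        raise ValueError("degenerate membrane contour")
    mine = particles[particles["profile_id"] == profile.id].copy()
    if len(mine):
        dist = point_to_contour_distance(
            contour, mine[["x_nm", "y_nm"]].to_numpy(float)
        )
    else:
        dist = np.array([])
    mine["assigned_label"] = np.where(dist <= d_mem_nm, "membrane", "intracellular")
    counts = {
        "membrane": int((mine["assigned_label"] == "membrane").sum()),
        "intracellular": int((mine["assigned_label"] == "intracellular").sum()),
    }
    total = counts["membrane"] + counts["intracellular"]
    percentages = (
        {k: 100.0 * v / total for k, v in counts.items()} if total else None
    )
    return PartitionRecord(profile.id, counts, percentages), mine


def density_records_frame(records: Sequence[DensityRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "profile_id": r.profile_id,
            "n_particles": r.n_particles,
            "area_um2": r.area_um2,
            "density_per_um2": r.density_per_um2,
        }
        if r.condition:
            row.update(r.condition)
        rows.append(row)
    return pd.DataFrame(rows)


def density_gradient_table(records: pd.DataFrame) -> pd.DataFrame:
    """Two-stage gradient table: profile -> animal mean -> group mean +/- SEM.

    ``records`` needs columns ``density_per_um2``, ``animal_id``,
    ``genotype`` and ``compartment`` (layer/class key).  Rows are ordered
    soma -> apical -> oblique -> spine within each layer.  Groups with a
    single animal get ``sem = NaN`` and ``sem_defined = False``.
    """
    required = {"density_per_um2", "animal_id", "genotype", "compartment"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    usable = records[records["area_um2"] >= MIN_PROFILE_AREA_UM2] if (
        "area_um2" in records.columns
    ) else records
    animal = (
        usable.groupby(["genotype", "compartment", "animal_id"], observed=True)[
            "density_per_um2"
        ]
        .mean()
        .reset_index()
    )
    order = {c.key: i for i, c in enumerate(GRADIENT_COMPARTMENTS)}
    rows = []
    for (geno, comp), grp in animal.groupby(["genotype", "compartment"], observed=True):
        vals = grp["density_per_um2"].to_numpy()
        n = len(vals)
        sem = float(np.std(vals, ddof=1) / np.sqrt(n)) if n >= 2 else float("nan")
        rows.append(
            {
                "genotype": geno,
                "compartment": comp,
                "mean_density_per_um2": float(vals.mean()),
                "sem": sem,
                "n_animals": n,
                "sem_defined": n >= 2,
            }
        )
    table = pd.DataFrame(rows)
    table["_order"] = table["compartment"].map(lambda k: order.get(k, len(order)))
    table = (
        table.sort_values(["_order", "genotype"])
        .drop(columns="_order")
        .reset_index(drop=True)
    )
    return table
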