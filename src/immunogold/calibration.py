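"""Packaged generator calibration: per-condition intensities and geometry.

The calibration file transcribes the emulated study's group means — surface
densities per compartment and age, presynaptic active-zone/extrasynaptic
densities, pre-embedding membrane fractions, cluster totals — and the
generator parameters (cluster radius, offspring mean, scattered fraction)
that realise them.  The decomposition of a total density ``D`` into a
clustered parent-offspring process plus a scattered homogeneous process is

    lambda_c * mu_k + lambda_s = D,   lambda_s = f_s * D,
    lambda_c = (1 - f_s) * D / mu_k,

so the expected total count on a profile of area ``A`` is exactly ``D * A``.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import yaml

GENOTYPES = ("WT", "APP_PS1")
AGES_MONTHS = (1, 6, 12)


@dataclass(frozen=True)
class PointProcessRecord:
    """Generating intensities for one (genotype, age, compartment) cell."""

    clustered_intensity: float  # cluster centres / um^2
    offspring_mean: float  # particles per cluster (>= 3)
    cluster_radius_nm: float
    scattered_intensity: float  # particles / um^2
    eface_background: float  # particles / um^2

    def __post_init__(self) -> None:
        if self.clustered_intensity < 0 or self.scattered_intensity < 0:
            raise ValueError("intensities must be non-negative")
        if self.cluster_radius_nm <= 0:
            raise ValueError("cluster radius must be positive")
        if self.eface_background < 0:
            raise ValueError("background intensity must be non-negative")

    @property
    def total_density(self) -> float:
        """Expected particles / um^2 (clustered + scattered)."""
        return self.clustered_intensity * self.offspring_mean + self.scattered_intensity


class Calibration:
    """Typed access to the packaged calibration YAML."""

    def __init__(self, raw: dict):
        self.raw = raw
        self._validate()

    @classmethod
    def load(cls, path: Optional[str | Path] = None) -> "Calibration":
        if path is None:
            ref = importlib.resources.files("immunogold.data") / "calibration.yaml"
            text = ref.read_text()
        else:
            text = Path(path).read_text()
        return cls(yaml.safe_load(text))

    def _validate(self) -> None:
        pp = self.raw["point_process"]
        if not 0 <= pp["scattered_fraction"] < 1:
            raise ValueError("scattered_fraction must be in [0, 1)")
        if pp["cluster_radius_nm"] <= 0:
            raise ValueError("cluster_radius_nm must be positive")
        if self.raw["raster"]["nm_per_px"] <= 0:
            raise ValueError("nm_per_px must be positive")
        for age_key, by_geno in self.raw["sds_frl_densities"].items():
            for geno, table in by_geno.items():
                for key, rec in table.items():
                    if rec["value"] < 0:
                        raise ValueError(f"negative density for {age_key}/{geno}/{key}")

    # -- SDS-FRL surface densities -------------------------------------
    def density(self, genotype: str, age_months: int, compartment_key: str) -> float:
        """Total generating surface density, particles/um^2."""
        table = self.raw["sds_frl_densities"][f"age_{age_months}"][genotype]
        return float(table[compartment_key]["value"])

    def gradient_keys(self, age_months: int = 6) -> list[str]:
        return list(self.raw["sds_frl_densities"][f"age_{age_months}"]["WT"].keys())

    def point_process_record(
        self, genotype: str, age_months: int, compartment_key: str
    ) -> PointProcessRecord:
        pp = self.raw["point_process"]
        total = self.density(genotype, age_months, compartment_key)
        f_s = float(pp["scattered_fraction"])
        mu = float(pp["offspring_mean"][genotype])
        lam_s = f_s * total
        lam_c = (1.0 - f_s) * total / mu if mu > 0 else 0.0
        return PointProcessRecord(
            clustered_intensity=lam_c,
            offspring_mean=mu,
            cluster_radius_nm=float(pp["cluster_radius_nm"]),
            scattered_intensity=lam_s,
            eface_background=float(pp["eface_background_per_um2"]),
        )

    # -- geometry ------------------------------------------------------
    def profile_area_um2(self, klass: str) -> float:
        return float(self.raw["profile_areas_um2"][klass])

    def n_profiles(self, klass: str) -> int:
        return int(self.raw["n_profiles"][klass])

    @property
    def nm_per_px(self) -> float:
        return float(self.raw["raster"]["nm_per_px"])

    @property
    def particle_diameter_nm(self) -> float:
        return float(self.raw["raster"]["particle_diameter_nm"])

    # -- presynaptic ---------------------------------------------------
    def presynaptic(self, genotype: str, layer: str, age_months: int = 12) -> dict:
        rec = self.raw["presynaptic"][f"age_{age_months}"][genotype][layer]
        return {"az": float(rec["az"]), "extra": float(rec["extra"])}

    @property
    def az_area_fraction(self) -> float:
        return float(self.raw["presynaptic"]["az_area_fraction"])

    # -- pre-embedding -------------------------------------------------
    def membrane_fraction(
        self, genotype: str, age_months: int, layer: str, site: str = "postsynaptic"
    ) -> float:
        table = self.raw["pre_embedding"][f"{site}_membrane_pct"]
        return float(table[f"age_{age_months}"][genotype][layer]) / 100.0

    @property
    def membrane_offset_nm(self) -> float:
        return float(self.raw["pre_embedding"]["membrane_offset_nm"])

    # -- clusters ------------------------------------------------------
    def cluster_condition(self, layer: str, genotype: str) -> dict:
        rec = self.raw["clusters"]["conditions"][layer][genotype]
        return {
            "total": int(rec["total"]),
            "size_range": tuple(rec["size_range"]),
            "size_geometric_p": float(self.raw["clusters"]["size_geometric_p"][genotype]),
            "reference_area_um2": float(self.raw["clusters"]["reference_area_um2"]),
            "min_center_separation_nm": float(
                self.raw["clusters"]["min_center_separation_nm"]
            ),
        }

    # -- histoblot -----------------------------------------------------
    @property
    def histoblot_regions(self) -> dict[str, float]:
        return {k: float(v) for k, v in self.raw["histoblot"]["regions"].items()}
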