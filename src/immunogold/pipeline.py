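"""End-to-end orchestration: simulate -> detect -> quantify -> cluster -> stats.

Each ``recover_*`` function regenerates one of the calibrated study
conditions from a seed, runs the measurement chain and reports the recovered
quantity next to the generating value, so recovery can be checked without
any external data.  :func:`reproduce` drives all stages and writes the
report tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as igio
from .calibration import Calibration
from .cluster import ClusterParams, clusters_frame, composition_histogram, link_clusters
from .compartments import CompartmentClass, Klass, Layer
from .detect import DetectionParams, detect_particles, match_to_truth
from .geometry import ProfileGeometry
from .quantify import (
    assign_particles,
    classify_membrane,
    compute_density,
    density_gradient_table,
    density_records_frame,
    split_presynaptic,
)
from .raster import NoiseModel, rasterize
from .simulate import (
    Scene,
    condition_scene,
    make_profile,
    plant_clusters,
    sample_pre_embedding,
    sample_presynaptic_pattern,
)
from .groupstats import bonferroni_pairwise, two_way_anova


def detect_in_scene(
    scene: Scene,
    params: DetectionParams = DetectionParams(),
    noise: NoiseModel = NoiseModel(),
    *,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Rasterize profile by profile and pool detections in scene coordinates.

    Per-profile rasters keep image sizes bounded regardless of how the
    profiles are laid out in the scene.
    """
    rng = np.random.default_rng(seed if seed is not None else scene.seed)
    frames = []
    for prof in scene.profiles:
        sub = Scene(
            profiles=[prof],
            particles=scene.particles[
                scene.particles["profile_id"] == prof.id
            ].reset_index(drop=True),
            nm_per_px=scene.nm_per_px,
            seed=scene.seed,
        )
        img = rasterize(sub, scene.nm_per_px, noise, rng)
        det = detect_particles(
            img, scene.nm_per_px, params, origin_nm=sub.raster_origin_nm
        )
        frames.append(det)
    if not frames:
        return pd.DataFrame(columns=["x_nm", "y_nm", "radius_nm", "response"])
    return pd.concat(frames, ignore_index=True)


def _pooled_density(records) -> dict:
    dens = np.array([r.density_per_um2 for r in records])
    n = len(dens)
    sem = float(np.std(dens, ddof=1) / np.sqrt(n)) if n >= 2 else float("nan")
    return {"mean": float(dens.mean()), "sem": sem, "n_profiles": n}


def recover_density_condition(
    cal: Calibration,
    genotype: str,
    age_months: int,
    compartment_key: str,
    seed: int,
    *,
    use_detection: bool = True,
    noise: NoiseModel = NoiseModel(),
    detection_params: DetectionParams = DetectionParams(),
    n_profiles: Optional[int] = None,
) -> dict:
    """Full generate -> (detect) -> quantify chain for one condition."""
    comp = CompartmentClass.from_key(compartment_key)
    if n_profiles is None:
        n_profiles = cal.n_profiles(comp.klass.value)
    scene = condition_scene(
        cal, genotype, age_months, compartment_key, n_profiles, seed
    )
    if use_detection:
        det = detect_in_scene(scene, detection_params, noise)
        particles = assign_particles(det, scene.profiles)
        report = match_to_truth(det, scene.particles, gate_nm=10.0)
    else:
        particles = scene.particles
        report = None
    records = [compute_density(particles, p) for p in scene.profiles]
    out = _pooled_density(records)
    out.update(
        {
            "generating_density": scene.meta["generating_density_per_um2"],
            "genotype": genotype,
            "age_months": age_months,
            "compartment": compartment_key,
            "records": records,
        }
    )
    if report is not None:
        out["detection_recall"] = report.recall
        out["detection_precision"] = report.precision
    return out


def recover_presynaptic(
    cal: Calibration,
    genotype: str,
    layer: str,
    seed: int,
    *,
    n_terminals: int = 400,
    age_months: int = 12,
) -> dict:
    """Active-zone vs extrasynaptic density recovery on axon terminals."""
    rng = np.random.default_rng(seed)
    intens = cal.presynaptic(genotype, layer, age_months)
    comp = CompartmentClass(Layer.SR_PROX if layer == "sr" else Layer.SLM,
                           Klass.AXON_TERMINAL)
    area = cal.profile_area_um2("axon_terminal")
    counts = {"az": 0, "extra": 0}
    areas = {"az": 0.0, "extra": 0.0}
    frames = []
    for i in range(n_terminals):
        prof = make_profile(
            comp,
            area,
            rng,
            profile_id=f"t{i:03d}",
            with_active_zone=True,
            az_area_fraction=cal.az_area_fraction,
        )
        pts = sample_presynaptic_pattern(
            prof, intens["az"], intens["extra"], rng
        )
        part, dens = split_presynaptic(pts, prof)
        counts["az"] += part.counts["az"]
        counts["extra"] += part.counts["extrasynaptic"]
        areas["az"] += dens["az"].area_um2
        areas["extra"] += dens["extrasynaptic"].area_um2
        frames.append(part)
    out = {}
    for sub in ("az", "extra"):
        lam = counts[sub] / areas[sub]
        out[sub] = {
            "density": lam,
            "se": float(np.sqrt(lam / areas[sub])),  # Poisson pooled-count SE
            "n_particles": counts[sub],
            "pooled_area_um2": areas[sub],
            "generating_density": intens[sub],
        }
    out["genotype"], out["layer"] = genotype, layer
    return out


def recover_membrane_fraction(
    cal: Calibration,
    genotype: str,
    age_months: int,
    layer: str,
    seed: int,
    *,
    min_particles: int = 2000,
    d_mem_nm: Optional[float] = None,
) -> dict:
    """Pre-embedding membrane-percentage recovery pooled over profiles."""
    rng = np.random.default_rng(seed)
    p_mem = cal.membrane_fraction(genotype, age_months, layer)
    d_offset = cal.membrane_offset_nm
    if d_mem_nm is None:
        d_mem_nm = d_offset
    per_profile = float(cal.raw["pre_embedding"]["mean_particles_per_profile"])
    n_profiles = int(np.ceil(min_particles / per_profile * 1.15))
    comp = CompartmentClass(
        Layer.SR_PROX if layer == "sr" else Layer.SLM, Klass.OBLIQUE_DENDRITE
    )
    mem = intra = 0
    for i in range(n_profiles):
        prof = make_profile(comp, 1.0, rng, profile_id=f"d{i:03d}")
        pts = sample_pre_embedding(prof, per_profile, p_mem, d_offset, rng)
        pts = pts.assign(profile_id=prof.id)
        part, _ = classify_membrane(pts, prof, d_mem_nm)
        mem += part.counts["membrane"]
        intra += part.counts["intracellular"]
    total = mem + intra
    pct = 100.0 * mem / total if total else float("nan")
    return {
        "membrane_pct": pct,
        "generating_pct": 100.0 * p_mem,
        "n_particles": total,
        "genotype": genotype,
        "age_months": age_months,
        "layer": layer,
    }


def recover_cluster_composition(
    cal: Calibration,
    layer: str,
    genotype: str,
    seed: int,
    *,
    params: ClusterParams = ClusterParams(),
) -> dict:
    """Planted-cluster recovery over the pooled reference oblique-dendrite area."""
    cond = cal.cluster_condition(layer, genotype)
    rng = np.random.default_rng(seed)
    area_each = cal.profile_area_um2("oblique_dendrite")
    n_profiles = int(round(cond["reference_area_um2"] / area_each))
    comp_layer = {"sr_prox": Layer.SR_PROX, "sr_dist": Layer.SR_DIST, "slm": Layer.SLM}[
        layer
    ]
    comp = CompartmentClass(comp_layer, Klass.OBLIQUE_DENDRITE)
    profiles = [
        make_profile(comp, area_each, rng, profile_id=f"c{i:03d}")
        for i in range(n_profiles)
    ]
    particles = plant_clusters(
        profiles,
        cond["total"],
        cond["size_range"],
        cond["size_geometric_p"],
        float(cal.raw["point_process"]["cluster_radius_nm"]),
        cond["min_center_separation_nm"],
        rng,
    )
    all_clusters = []
    sizes = []
    for prof in profiles:
        mine = particles[particles["profile_id"] == prof.id]
        clus, _ = link_clusters(mine, params)
        if clus:
            all_clusters.append(clusters_frame(clus, prof.id))
        sizes.extend(c.size for c in clus)
    pooled_area = sum(p.area_um2 for p in profiles)
    hist = composition_histogram(
        sizes, pooled_area, cond["reference_area_um2"]
    )
    return {
        "histogram": hist,
        "clusters": pd.concat(all_clusters, ignore_index=True)
        if all_clusters
        else pd.DataFrame(),
        "planted_total": cond["total"],
        "recovered_total": hist["total_clusters"],
        "size_range": hist["size_range"],
        "genotype": genotype,
        "layer": layer,
        "particles": particles,
        "profiles": profiles,
    }


def gradient_dataset(
    cal: Calibration, age_months: int, seed: int
) -> pd.DataFrame:
    """Per-profile densities for all 11 compartments x both genotypes."""
    rows = []
    seq = np.random.SeedSequence([seed, age_months])
    children = seq.spawn(2 * len(cal.gradient_keys(age_months)))
    i = 0
    for genotype in ("WT", "APP_PS1"):
        for key in cal.gradient_keys(age_months):
            sub_seed = int(children[i].generate_state(1)[0] % (2**31))
            i += 1
            comp = CompartmentClass.from_key(key)
            scene = condition_scene(
                cal, genotype, age_months, key,
                cal.n_profiles(comp.klass.value), sub_seed,
            )
            for prof in scene.profiles:
                rec = compute_density(scene.particles, prof)
                rows.append(
                    {
                        "profile_id": prof.id,
                        "genotype": genotype,
                        "age_months": age_months,
                        "compartment": key,
                        "animal_id": prof.animal_id,
                        "n_particles": rec.n_particles,
                        "area_um2": rec.area_um2,
                        "density_per_um2": rec.density_per_um2,
                    }
                )
    return pd.DataFrame(rows)


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "immunogold_run"
    calibration_path: Optional[str] = None
    use_detection: bool = True
    stages: tuple[str, ...] = (
        "gradient",
        "detection",
        "presynaptic",
        "pre_embedding",
        "clusters",
        "stats",
    )


def reproduce(config: RunConfig) -> dict:
    """Regenerate all report tables from seeds; returns recovered summaries."""
    cal = Calibration.load(config.calibration_path)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = {"seed": config.seed, "config_hash": igio.config_hash(cal.raw)}
    results: dict = {"provenance": prov}

    if "gradient" in config.stages:
        records = gradient_dataset(cal, 6, config.seed)
        igio.write_table(records, out / "density_records.csv", prov)
        table = density_gradient_table(records)
        igio.write_table(table, out / "gradient_table.csv", prov)
        results["gradient_table"] = table
        if "stats" in config.stages:
            aov = two_way_anova(records)
            pw = bonferroni_pairwise(records, m=11)
            igio.write_table(pw, out / "comparisons.csv", prov)
            (out / "stats_report.md").write_text(aov.summary() + "\n")
            results["anova"] = aov
            results["pairwise"] = pw

    if "detection" in config.stages:
        rec = recover_density_condition(
            cal, "WT", 6, "slm/oblique_dendrite", config.seed,
            use_detection=config.use_detection,
        )
        rec.pop("records")
        results["detection_recovery"] = rec

    if "presynaptic" in config.stages:
        results["presynaptic"] = {
            f"{g}_{lay}": recover_presynaptic(cal, g, lay, config.seed + 7)
            for g, lay in (("WT", "sr"), ("APP_PS1", "slm"))
        }

    if "pre_embedding" in config.stages:
        partition_rows = []
        for g, age, lay in (
            ("APP_PS1", 1, "sr"),
            ("WT", 12, "slm"),
            ("APP_PS1", 12, "slm"),
        ):
            r = recover_membrane_fraction(cal, g, age, lay, config.seed + 11)
            partition_rows.append(r)
        pr = pd.DataFrame(partition_rows)
        igio.write_table(pr, out / "partition_records.csv", prov)
        results["pre_embedding"] = pr

    if "clusters" in config.stages:
        comp_rows = []
        for g in ("WT", "APP_PS1"):
            r = recover_cluster_composition(cal, "sr_prox", g, config.seed + 13)
            igio.write_table(r["clusters"], out / f"clusters_{g}.csv", prov)
            comp_rows.append(
                {
                    "genotype": g,
                    "layer": "sr_prox",
                    "planted_total": r["planted_total"],
                    "recovered_total": r["recovered_total"],
                    "size_min": r["size_range"][0],
                    "size_max": r["size_range"][1],
                }
            )
        comp = pd.DataFrame(comp_rows)
        igio.write_table(comp, out / "composition.csv", prov)
        results["clusters"] = comp

    summary = {
        k: v for k, v in results.items() if k in ("provenance",)
    }
    summary["files"] = sorted(p.name for p in out.iterdir())
    (out / "provenance.json").write_text(json.dumps(prov, indent=1))
    return results
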