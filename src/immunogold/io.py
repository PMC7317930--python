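"""File formats: particle CSV, profile GeoJSON, TIFF images, YAML configs.

Coordinates are serialised in nm with two-decimal fixed point (lossless at
0.01 nm); profiles are GeoJSON FeatureCollections in a flat planar frame
(no geographic CRS).  Every written table carries provenance comment lines
(config hash, seed) that readers skip.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml
from shapely.geometry import LineString, Polygon, mapping, shape

from .compartments import CompartmentClass, Klass, Layer
from .geometry import ProfileGeometry
from .simulate import PARTICLE_COLUMNS, empty_particles

_REQUIRED = ["scene_id", "profile_id", "x_nm", "y_nm", "label"]


def config_hash(obj) -> str:
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def _provenance_header(provenance: Optional[dict]) -> str:
    if not provenance:
        return ""
    lines = [f"# {k}: {v}" for k, v in provenance.items()]
    return "\n".join(lines) + "\n"


def write_particles(
    particles: pd.DataFrame, path: str | Path, provenance: Optional[dict] = None
) -> None:
    path = Path(path)
    out = particles.copy()
    for col in ("x_nm", "y_nm"):
        if col in out.columns:
            out[col] = out[col].map(lambda v: f"{v:.2f}")
    with open(path, "w") as fh:
        fh.write(_provenance_header(provenance))
        out.to_csv(fh, index=False)


def read_particles(path: str | Path) -> pd.DataFrame:
    """Read a particle table, validating the schema row by row.

    Empty files yield an empty particle set; malformed rows raise with the
    offending line number.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        return empty_particles()
    df = pd.read_csv(path, comment="#", dtype=str, keep_default_na=False)
    if df.empty and len(df.columns) == 0:
        return empty_particles()
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing columns {missing}")
    n_comment = sum(1 for line in text.splitlines() if line.startswith("#"))
    out = df.copy()
    for col in ("x_nm", "y_nm"):
        vals = []
        for i, v in enumerate(df[col]):
            try:
                vals.append(float(v))
            except ValueError:
                line_no = n_comment + 2 + i  # header + 1-based data row
                raise ValueError(
                    f"{path.name} line {line_no}: invalid {col} value {v!r}"
                ) from None
        out[col] = vals
    if "cluster_id" in out.columns:
        cid = []
        for i, v in enumerate(df["cluster_id"]):
            if v in ("", "NA", "<NA>", "nan"):
                cid.append(pd.NA)
                continue
            try:
                cid.append(int(float(v)))
            except ValueError:
                line_no = n_comment + 2 + i
                raise ValueError(
                    f"{path.name} line {line_no}: invalid cluster_id {v!r}"
                ) from None
        out["cluster_id"] = pd.array(cid, dtype="Int64")
    else:
        out["cluster_id"] = pd.array([pd.NA] * len(out), dtype="Int64")
    cols = PARTICLE_COLUMNS + [c for c in out.columns if c not in PARTICLE_COLUMNS]
    return out[cols]


def write_profiles(
    profiles: Sequence[ProfileGeometry],
    path: str | Path,
    provenance: Optional[dict] = None,
) -> None:
    features = []
    for p in profiles:
        props = {
            "id": p.id,
            "face": p.face,
            "animal_id": p.animal_id,
            "role": "profile",
        }
        if p.compartment is not None:
            props["layer"] = p.compartment.layer.value
            props["klass"] = p.compartment.klass.value
        features.append(
            {"type": "Feature", "properties": props, "geometry": mapping(p.polygon)}
        )
        for name, sub in p.subregions.items():
            features.append(
                {
                    "type": "Feature",
                    "properties": {"id": f"{p.id}:{name}", "role": name, "parent": p.id},
                    "geometry": mapping(sub),
                }
            )
        if p.membrane_contour is not None:
            features.append(
                {
                    "type": "Feature",
                    "properties": {
                        "id": f"{p.id}:membrane_contour",
                        "role": "membrane_contour",
                        "parent": p.id,
                    },
                    "geometry": mapping(p.membrane_contour),
                }
            )
    doc = {"type": "FeatureCollection", "features": features}
    if provenance:
        doc["provenance"] = provenance
    Path(path).write_text(json.dumps(doc, indent=1))


def read_profiles(path: str | Path) -> list[ProfileGeometry]:
    doc = json.loads(Path(path).read_text())
    mains: dict[str, dict] = {}
    subs: list[dict] = []
    for feat in doc["features"]:
        role = feat["properties"].get("role", "profile")
        if role == "profile":
            mains[feat["properties"]["id"]] = feat
        else:
            subs.append(feat)
    profiles = []
    for pid, feat in mains.items():
        props = feat["properties"]
        compartment = None
        if "layer" in props and "klass" in props:
            compartment = CompartmentClass(Layer(props["layer"]), Klass(props["klass"]))
        subregions = {}
        contour = None
        for sub in subs:
            if sub["properties"].get("parent") != pid:
                continue
            geom = shape(sub["geometry"])
            if sub["properties"]["role"] == "membrane_contour":
                contour = LineString(geom)
            else:
                subregions[sub["properties"]["role"]] = Polygon(geom)
        profiles.append(
            ProfileGeometry(
                id=pid,
                polygon=Polygon(shape(feat["geometry"])),
                face=props.get("face", "P"),
                compartment=compartment,
                subregions=subregions,
                membrane_contour=contour,
                animal_id=props.get("animal_id", "a1"),
            )
        )
    return profiles


def write_image(img: np.ndarray, path: str | Path, nm_per_px: float) -> None:
    """16-bit TIFF with the pixel pitch recorded in the image description."""
    from .raster import to_uint16

    tifffile.imwrite(
        Path(path),
        to_uint16(img) if img.dtype != np.uint16 else img,
        description=json.dumps({"nm_per_px": nm_per_px}),
    )


def read_image(path: str | Path) -> tuple[np.ndarray, Optional[float]]:
    with tifffile.TiffFile(Path(path)) as tf:
        img = tf.asarray()
        nm_per_px = None
        desc = tf.pages[0].description
        if desc:
            try:
                nm_per_px = float(json.loads(desc).get("nm_per_px"))
            except (ValueError, TypeError, json.JSONDecodeError):
                pass
    return img, nm_per_px


def read_config(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text()) or {}


def write_config(cfg: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))


def write_provenance(path: str | Path, **fields) -> None:
    Path(path).write_text(json.dumps(fields, indent=1, default=str))


def write_table(
    df: pd.DataFrame, path: str | Path, provenance: Optional[dict] = None
) -> None:
    with open(Path(path), "w") as fh:
        fh.write(_provenance_header(provenance))
        df.to_csv(fh, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path), comment="#")
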