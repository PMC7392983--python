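"""Reading and writing the pipeline's plain-text artifacts.

Boundaries, subcity units, and roads travel as GeoJSON FeatureCollections
in longitude/latitude; panoramas and covariates as CSV.  Synthetic cities
are written through the same formats so synthetic and real runs are
interchangeable.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import mapping, shape

from .errors import InvalidInputError
from .providers import Panorama
from .spatial import AzimuthalEquidistant


def _feature(geom, properties: dict) -> dict:
    return {"type": "Feature", "geometry": mapping(geom), "properties": properties}


def _collection(features: list[dict]) -> dict:
    return {"type": "FeatureCollection", "features": features}


def write_geojson(path: Path, features: list[dict]) -> None:
    Path(path).write_text(json.dumps(_collection(features)))


def read_geojson(path: Path) -> list[tuple[object, dict]]:
    path = Path(path)
    if not path.exists():
        raise InvalidInputError(f"missing GeoJSON file: {path}")
    try:
        payload = json.loads(path.read_text())
        feats = payload["features"]
        return [(shape(f["geometry"]), f.get("properties", {}) or {}) for f in feats]
    except (KeyError, ValueError, TypeError) as exc:
        raise InvalidInputError(f"malformed GeoJSON in {path}: {exc}") from exc


def load_boundaries(path: Path) -> list[dict]:
    """City boundary features -> list of {city_id, country, geometry}."""
    out = []
    for geom, props in read_geojson(path):
        for key in ("city_id", "country"):
            if key not in props:
                raise InvalidInputError(
                    f"boundary feature in {path} missing property {key!r}"
                )
        out.append({"city_id": props["city_id"], "country": props["country"], "geometry": geom})
    return out


def load_units(path: Path) -> list[dict]:
    out = []
    for geom, props in read_geojson(path):
        for key in ("subcity_id", "city_id", "area_km2"):
            if key not in props:
                raise InvalidInputError(f"unit feature in {path} missing property {key!r}")
        rec = dict(props)
        rec["geometry"] = geom
        out.append(rec)
    return out


def load_roads(path: Path) -> dict[str, list]:
    """Road features grouped by city_id."""
    grouped: dict[str, list] = {}
    for geom, props in read_geojson(path):
        if "city_id" not in props:
            raise InvalidInputError(f"road feature in {path} missing property 'city_id'")
        grouped.setdefault(props["city_id"], []).append(geom)
    return grouped


def load_panoramas(path: Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InvalidInputError(f"missing panorama file: {path}")
    frame = pd.read_csv(path)
    needed = {"pano_id", "city_id", "lon", "lat", "capture_year", "capture_month"}
    missing = needed - set(frame.columns)
    if missing:
        raise InvalidInputError(f"panorama CSV {path} missing columns {sorted(missing)}")
    return frame


def load_covariates(path: Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InvalidInputError(f"missing covariate file: {path}")
    frame = pd.read_csv(path)
    if "subcity_id" not in frame.columns:
        raise InvalidInputError(f"covariate CSV {path} missing 'subcity_id'")
    return frame


# --- synthetic-study serialization ------------------------------------------

_ANCHOR_LON0, _ANCHOR_LAT0 = -70.0, -15.0


def _city_anchor(index: int) -> AzimuthalEquidistant:
    # spread anchors ~1 degree apart so cities never overlap on the globe
    return AzimuthalEquidistant(
        _ANCHOR_LON0 + 1.0 * (index % 30), _ANCHOR_LAT0 - 1.0 * (index // 30)
    )


def write_study(study, out_dir: Path) -> dict[str, Path]:
    """Serialize a synthetic study as the pipeline's geographic input files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    b_feats, u_feats, r_feats = [], [], []
    pano_rows = []
    for i, city in enumerate(study.cities):
        proj = _city_anchor(i)
        center = np.array(
            [[city.boundary.polygon.centroid.x, city.boundary.polygon.centroid.y]]
        )

        def to_geo(geom, proj=proj, center=center):
            return shapely.transform(geom, lambda pts: proj.inverse(pts - center))

        b_feats.append(
            _feature(
                to_geo(city.boundary.polygon),
                {"city_id": city.city_id, "country": city.country},
            )
        )
        unit_meta = city.unit_table.set_index("subcity_id")
        for unit in city.units:
            u_feats.append(
                _feature(
                    to_geo(unit.polygon),
                    {
                        "subcity_id": unit.subcity_id,
                        "city_id": city.city_id,
                        "country": city.country,
                        "area_km2": float(unit_meta.loc[unit.subcity_id, "area_km2"]),
                    },
                )
            )
        r_feats.append(
            _feature(to_geo(city.roads.to_multilinestring()), {"city_id": city.city_id})
        )
        for p in city.panoramas:
            lon, lat = proj.inverse(np.array([[p.x, p.y]]) - center)[0]
            pano_rows.append(
                {
                    "pano_id": p.pano_id,
                    "city_id": city.city_id,
                    "lon": lon,
                    "lat": lat,
                    "capture_year": p.capture_year,
                    "capture_month": p.capture_month,
                }
            )

    paths = {
        "boundaries": out_dir / "boundaries.geojson",
        "units": out_dir / "units.geojson",
        "roads": out_dir / "roads.geojson",
        "panoramas": out_dir / "panoramas.csv",
        "covariates": out_dir / "covariates.csv",
        "truth": out_dir / "truth.json",
    }
    write_geojson(paths["boundaries"], b_feats)
    write_geojson(paths["units"], u_feats)
    write_geojson(paths["roads"], r_feats)
    pd.DataFrame(
        pano_rows,
        columns=["pano_id", "city_id", "lon", "lat", "capture_year", "capture_month"],
    ).to_csv(paths["panoramas"], index=False)
    study.unit_table.to_csv(paths["covariates"], index=False)
    paths["truth"].write_text(json.dumps(study.truth, indent=1))
    return paths


def panoramas_from_frame(frame: pd.DataFrame, projection: AzimuthalEquidistant) -> list[Panorama]:
    """Project a lon/lat panorama table into a city's planar frame."""
    if len(frame) == 0:
        return []
    xy = projection.forward(frame[["lon", "lat"]].to_numpy(float))
    return [
        Panorama(
            pano_id=str(row.pano_id),
            x=float(x),
            y=float(y),
            capture_year=int(row.capture_year),
            capture_month=int(row.capture_month),
        )
        for row, (x, y) in zip(frame.itertuples(index=False), xy)
    ]


def sha256_file(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
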