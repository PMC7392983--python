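"""Synthetic cities with known ground truth for end-to-end pipeline testing.

Each city is a square with a rectangular road grid whose vertical-road
density varies with a per-unit latent socioeconomic factor, a partition
into vertical-strip subcity units, covariates driven by that single latent
factor, and panoramas placed along roads.  Candidate panorama sites are
retained with a logistic probability in the standardized latent factor and
local road density; retained panoramas get capture dates from a linear
age model with unit-level noise.  Everything is reproducible from a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from shapely.geometry import box

from .coverage import REF_MONTH, REF_YEAR
from .errors import DegenerateConfigError, InvalidInputError
from .providers import Panorama
from .spatial import CityBoundary, RoadNetwork, _chord_lengths

COUNTRY_CYCLE = ("AR", "BR", "CL", "CO", "MX", "GT")  # GT pools to Central America

#: Per-covariate (scale on the standardized latent factor, baseline) pairs.
_PERCENT_SCALES = {
    "pct_piped_water": 12.0,
    "pct_sewer": 14.0,
    "pct_durable_walls": 10.0,
    "pct_labor": 8.0,
    "pct_secondary_edu": 11.0,
    "pct_above_poverty": 13.0,
}


@dataclass(frozen=True)
class SyntheticCityConfig:
    city_size_m: float = 4000.0
    n_subcities: int = 4
    road_grid_spacing_m: float = 400.0
    ses_between_sd: float = 1.0
    beta0_avail: float = -0.5
    beta_ses_avail: float = 0.5
    beta_road_avail: float = 0.0
    age_mean_months: float = 60.0
    beta_ses_age: float = 3.0
    age_unit_sd: float = 3.0
    age_within_sd: float = 6.0
    panorama_spacing_m: float = 150.0
    covariate_noise_sd: float = 4.0

    def __post_init__(self) -> None:
        if self.n_subcities < 1:
            raise InvalidInputError("n_subcities must be >= 1")
        if min(self.city_size_m, self.road_grid_spacing_m, self.panorama_spacing_m) <= 0:
            raise InvalidInputError("sizes and spacings must be positive")
        if min(self.ses_between_sd, self.age_unit_sd, self.age_within_sd) < 0:
            raise InvalidInputError("standard deviations must be non-negative")


@dataclass
class SyntheticUnit:
    subcity_id: str
    polygon: object


@dataclass
class SyntheticCity:
    city_id: str
    country: str
    boundary: CityBoundary
    roads: RoadNetwork
    units: list[SyntheticUnit]
    unit_table: pd.DataFrame
    panoramas: list[Panorama]
    truth: dict


@dataclass
class SyntheticStudy:
    cities: list[SyntheticCity]
    truth: dict

    @property
    def unit_table(self) -> pd.DataFrame:
        return pd.concat([c.unit_table for c in self.cities], ignore_index=True)


def _age_to_year_month(age_months: int) -> tuple[int, int]:
    total = REF_YEAR * 12 + REF_MONTH - int(age_months)
    year = (total - 1) // 12
    month = total - 12 * year
    return year, month


def _walk_polyline(vertices: np.ndarray, step: float) -> np.ndarray:
    """Points every ``step`` meters along a polyline, starting at its head."""
    deltas = np.diff(vertices, axis=0)
    seg_len = np.linalg.norm(deltas, axis=1)
    total = float(seg_len.sum())
    if total <= 0:
        return np.empty((0, 2))
    distances = np.arange(0.0, total + 1e-9, step)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    seg_idx = np.clip(np.searchsorted(cum, distances, side="right") - 1, 0, len(seg_len) - 1)
    local = (distances - cum[seg_idx]) / np.where(seg_len[seg_idx] > 0, seg_len[seg_idx], 1.0)
    return vertices[seg_idx] + deltas[seg_idx] * local[:, None]


def simulate_city(
    config: SyntheticCityConfig,
    seed: int,
    city_id: str = "C000",
    country: str = "AR",
) -> SyntheticCity:
    """Generate one city; byte-identical output for identical (config, seed)."""
    rng = np.random.default_rng(seed)
    size = config.city_size_m
    boundary = CityBoundary(
        city_id=city_id,
        country=country,
        polygon=box(0.0, 0.0, size, size),
        crs_note="synthetic planar meters",
    )

    k = config.n_subcities
    strip_w = size / k
    latent = rng.normal(0.0, config.ses_between_sd, size=k)
    ses_std = latent / config.ses_between_sd if config.ses_between_sd > 0 else np.zeros(k)

    units, records = [], []
    for j in range(k):
        uid = f"{city_id}-u{j:02d}"
        poly = box(j * strip_w, 0.0, (j + 1) * strip_w, size)
        units.append(SyntheticUnit(subcity_id=uid, polygon=poly))
        rec = {
            "subcity_id": uid,
            "city_id": city_id,
            "country": country,
            "area_km2": poly.area / 1e6,
            "ses_latent_std": ses_std[j],
            "pop_density": max(
                10.0,
                5000.0 + 2500.0 * ses_std[j] + rng.normal(0.0, 100.0 * config.covariate_noise_sd),
            ),
        }
        for name, scale in _PERCENT_SCALES.items():
            raw = 50.0 + scale * ses_std[j] + rng.normal(0.0, config.covariate_noise_sd)
            rec[name] = float(np.clip(raw, 0.0, 100.0))
        records.append(rec)
    unit_table = pd.DataFrame(records)

    # Horizontal roads span the city at the base spacing; vertical roads run
    # inside each strip with density jittered by the unit's latent factor.
    polylines: list[np.ndarray] = []
    yv = config.road_grid_spacing_m
    while yv < size:
        polylines.append(np.array([[0.0, yv], [size, yv]]))
        yv += config.road_grid_spacing_m
    for j in range(k):
        dens = config.road_grid_spacing_m / (1.0 + 0.15 * ses_std[j])
        dens = float(np.clip(dens, config.road_grid_spacing_m / 2, config.road_grid_spacing_m * 2))
        x0, x1 = j * strip_w, (j + 1) * strip_w
        xv = x0 + dens / 2.0
        while xv < x1:
            polylines.append(np.array([[xv, 0.0], [xv, size]]))
            xv += dens
    roads = RoadNetwork(polylines)
    if roads.total_length_m <= 0:
        raise DegenerateConfigError("configuration yields an empty road network")

    # candidate panorama sites along every road polyline
    sites = [_walk_polyline(line, config.panorama_spacing_m) for line in polylines]
    sites = np.concatenate([s for s in sites if len(s)]) if sites else np.empty((0, 2))
    if len(sites) == 0:
        raise DegenerateConfigError("configuration yields no candidate panorama sites")
    site_unit = np.clip((sites[:, 0] // strip_w).astype(int), 0, k - 1)
    local_road = _chord_lengths(sites, roads._seg_a, roads._seg_b, 100.0)
    sd_road = local_road.std(ddof=1) if len(local_road) > 1 else 0.0
    road_z = (local_road - local_road.mean()) / sd_road if sd_road > 0 else np.zeros(len(sites))

    logit = (
        config.beta0_avail
        + config.beta_ses_avail * ses_std[site_unit]
        + config.beta_road_avail * road_z
    )
    keep = rng.random(len(sites)) < 1.0 / (1.0 + np.exp(-logit))

    unit_age_effect = rng.normal(0.0, config.age_unit_sd, size=k)
    panoramas: list[Panorama] = []
    ages_mean = (
        config.age_mean_months
        - config.beta_ses_age * ses_std[site_unit]
        + unit_age_effect[site_unit]
    )
    ages = rng.normal(ages_mean, config.age_within_sd)
    ages = np.maximum(np.rint(ages), 0.0).astype(int)
    for i in np.nonzero(keep)[0]:
        year, month = _age_to_year_month(ages[i])
        panoramas.append(
            Panorama(
                pano_id=f"{city_id}-pano{i:06d}",
                x=float(sites[i, 0]),
                y=float(sites[i, 1]),
                capture_year=year,
                capture_month=month,
            )
        )

    truth = {
        "config": asdict(config),
        "seed": seed,
        "ses_latent_std": ses_std.tolist(),
        "unit_age_effect": unit_age_effect.tolist(),
        "n_candidate_sites": int(len(sites)),
        "n_panoramas": int(keep.sum()),
    }
    return SyntheticCity(
        city_id=city_id,
        country=country,
        boundary=boundary,
        roads=roads,
        units=units,
        unit_table=unit_table,
        panoramas=panoramas,
        truth=truth,
    )


def simulate_study(
    n_cities: int,
    seed: int,
    base_config: SyntheticCityConfig | None = None,
    size_range_m: tuple[float, float] = (3000.0, 6000.0),
    n_subcities_range: tuple[int, int] = (2, 6),
) -> SyntheticStudy:
    """A multi-city study frame with varying sizes and round-robin countries."""
    if n_cities < 2:
        raise InvalidInputError("a study needs at least 2 cities")
    base = base_config or SyntheticCityConfig()
    rng = np.random.default_rng(seed)
    cities = []
    for i in range(n_cities):
        cfg_kwargs = asdict(base)
        cfg_kwargs["city_size_m"] = float(rng.uniform(*size_range_m))
        cfg_kwargs["n_subcities"] = int(rng.integers(n_subcities_range[0], n_subcities_range[1] + 1))
        cfg_kwargs["road_grid_spacing_m"] = float(
            base.road_grid_spacing_m * rng.uniform(0.8, 1.25)
        )
        cfg = SyntheticCityConfig(**cfg_kwargs)
        city_seed = int(rng.integers(0, 2**31 - 1))
        cities.append(
            simulate_city(
                cfg,
                seed=city_seed,
                city_id=f"C{i:03d}",
                country=COUNTRY_CYCLE[i % len(COUNTRY_CYCLE)],
            )
        )
    truth = {
        "seed": seed,
        "n_cities": n_cities,
        "base_config": asdict(base),
        "per_city": {c.city_id: c.truth for c in cities},
    }
    return SyntheticStudy(cities=cities, truth=truth)


def draw_point_outcomes(
    eligible_frame: pd.DataFrame,
    unit_table: pd.DataFrame,
    rng: np.random.Generator,
    beta0: float = -0.5,
    beta_ses: float = 0.0,
    beta_road: float = 0.0,
    re_sd_intercept: float = 0.0,
    age_mean_months: float = 60.0,
    beta_ses_age: float = 0.0,
    age_unit_sd: float = 0.0,
    age_within_sd: float = 6.0,
) -> pd.DataFrame:
    """Draw availability and ages for eligible points directly from the
    generative models (per-point Bernoulli on the logistic scale, normal
    ages truncated at zero).

    This is the estimator-validation harness: it produces an audited-style
    frame whose point-level availability follows the logistic model exactly
    with the injected coefficients, so parameter recovery, test
    calibration, and interval coverage can be measured against known truth.

    The injected effects are per standard deviation of the exposure in the
    analysis set — the scale on which the model battery reports them:
    ``beta_ses`` multiplies the latent factor Z-scored across the eligible
    points, ``beta_ses_age`` multiplies it Z-scored across the subcity
    units, and the road term uses road length Z-scored across the points.
    """
    frame = eligible_frame[eligible_frame["subcity_id"].notna()].copy()
    latent = unit_table.set_index("subcity_id")["ses_latent_std"]
    s_raw = frame["subcity_id"].map(latent).to_numpy(float)
    s = (s_raw - s_raw.mean()) / s_raw.std(ddof=1) if s_raw.std(ddof=1) > 0 else s_raw
    unit_s = frame.groupby("subcity_id")["subcity_id"].first().map(latent)
    unit_sd = unit_s.std(ddof=1)
    unit_z = (unit_s - unit_s.mean()) / unit_sd if unit_sd > 0 else unit_s * 0.0
    s_age = frame["subcity_id"].map(unit_z).to_numpy(float)
    road = frame["road_length_m"].to_numpy(float)
    road_sd = road.std(ddof=1)
    road_z = (road - road.mean()) / road_sd if road_sd > 0 else np.zeros(len(road))

    cities = frame["city_id"].to_numpy()
    city_levels, city_codes = np.unique(cities, return_inverse=True)
    city_re = rng.normal(0.0, re_sd_intercept, size=len(city_levels))

    logit = beta0 + beta_ses * s + beta_road * road_z + city_re[city_codes]
    available = rng.random(len(frame)) < 1.0 / (1.0 + np.exp(-logit))

    unit_levels, unit_codes = np.unique(frame["subcity_id"].to_numpy(), return_inverse=True)
    unit_eff = rng.normal(0.0, age_unit_sd, size=len(unit_levels))
    ages = rng.normal(
        age_mean_months - beta_ses_age * s_age + unit_eff[unit_codes], age_within_sd
    )
    ages = np.maximum(np.rint(ages), 0.0).astype(int)

    out = frame.copy()
    out["available"] = available
    out["status"] = np.where(available, "OK", "ZERO_RESULTS")
    out["age_months"] = np.where(available, ages, np.nan)
    years_months = [_age_to_year_month(a) for a in ages]
    out["capture_year"] = np.where(available, [ym[0] for ym in years_months], np.nan)
    out["capture_month"] = np.where(available, [ym[1] for ym in years_months], np.nan)
    out["analysis_ok"] = True
    return out
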