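"""Stage functions chaining the sampling, audit, aggregation and models.

Each stage is a pure function of its inputs; the CLI wraps these with file
artifacts and a manifest.  ``run_study_pipeline`` drives the whole chain on
an in-memory synthetic study, which is how the test-suite exercises every
stage end to end.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import ses
from .coverage import aggregate_coverage, availability_report
from .models import run_model_battery
from .providers import SyntheticProvider, audit_points
from .spatial import (
    SamplePoint,
    annotate_road_length,
    assign_subcity,
    filter_eligible,
    generate_point_grid,
    points_to_frame,
    project_city,
)

DEFAULT_SPACING_M = 500.0
DEFAULT_RADIUS_M = 100.0

ALL_EXPOSURES = list(ses.ALL_COVARIATES) + [
    "index_without_poverty",
    "index_with_poverty",
]
ALL_OUTCOMES = ["availability", "mean_age_months", "sd_age_months"]


def sample_city_features(
    boundary_feature: dict,
    road_geoms: list,
    unit_features: list[dict],
    spacing_m: float = DEFAULT_SPACING_M,
    radius_m: float = DEFAULT_RADIUS_M,
):
    """Project one city's geographic inputs and build its sample frame.

    Returns (points, projection); points carry road lengths, eligibility
    and subcity assignment.
    """
    boundary, roads, proj = project_city(
        boundary_feature["city_id"],
        boundary_feature["country"],
        boundary_feature["geometry"],
        road_geoms,
    )
    points = generate_point_grid(boundary, spacing_m=spacing_m, projection=proj)
    annotate_road_length(points, roads, radius_m=radius_m)

    @dataclass
    class _Unit:
        subcity_id: str
        polygon: object

    units = [
        _Unit(u["subcity_id"], proj.transform_geometry(u["geometry"]))
        for u in unit_features
    ]
    assign_subcity(points, units)
    return points, proj


@dataclass
class PipelineResult:
    sample_frame: pd.DataFrame
    audited: pd.DataFrame
    audit_report: dict
    overall: dict
    coverage_subcity: pd.DataFrame
    coverage_city: pd.DataFrame
    coverage_country: pd.DataFrame


def run_study_pipeline(
    study,
    spacing_m: float = DEFAULT_SPACING_M,
    radius_m: float = DEFAULT_RADIUS_M,
    ref_year: int = 2019,
    ref_month: int = 4,
) -> PipelineResult:
    """Run sampling -> audit -> aggregation on an in-memory synthetic study."""
    frames, audits = [], []
    country_of_city = {}
    for city in study.cities:
        country_of_city[city.city_id] = city.country
        points = generate_point_grid(city.boundary, spacing_m=spacing_m)
        annotate_road_length(points, city.roads, radius_m=radius_m)
        assign_subcity(points, city.units)
        frames.append(points_to_frame(points))
        eligible = filter_eligible(points)
        provider = SyntheticProvider(city.panoramas)
        audited, _ = audit_points(
            eligible, provider, radius_m=radius_m, ref_year=ref_year, ref_month=ref_month
        )
        audits.append(audited)
    sample_frame = pd.concat(frames, ignore_index=True)
    audited = pd.concat(audits, ignore_index=True)
    audited["country"] = audited["city_id"].map(country_of_city)
    return summarize_audit(sample_frame, audited)


def summarize_audit(sample_frame: pd.DataFrame, audited: pd.DataFrame) -> PipelineResult:
    from .providers import audit_report as _report

    complete = audited[audited["analysis_ok"].astype(bool)]
    return PipelineResult(
        sample_frame=sample_frame,
        audited=audited,
        audit_report=_report(audited),
        overall=availability_report(audited),
        coverage_subcity=aggregate_coverage(complete, "subcity"),
        coverage_city=aggregate_coverage(complete, "city"),
        coverage_country=aggregate_coverage(complete, "country")
        if "country" in complete.columns
        else pd.DataFrame(),
    )


def run_full_analysis(
    study,
    exposures: list[str] | None = None,
    outcomes: list[str] | None = None,
    strata: str = "all",
    **pipeline_kwargs,
) -> tuple[PipelineResult, pd.DataFrame]:
    """Pipeline plus the model battery on a synthetic study."""
    result = run_study_pipeline(study, **pipeline_kwargs)
    battery = run_model_battery(
        result.audited,
        result.coverage_subcity,
        study.unit_table,
        exposures=exposures or ALL_EXPOSURES,
        outcomes=outcomes or ALL_OUTCOMES,
        strata=strata,
    )
    return result, battery


__all__ = [
    "ALL_EXPOSURES",
    "ALL_OUTCOMES",
    "PipelineResult",
    "run_full_analysis",
    "run_study_pipeline",
    "sample_city_features",
    "summarize_audit",
    "SamplePoint",
]
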