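"""Street-imagery metadata providers and the point-audit stage.

The pipeline only ever talks to the small provider interface below, so a
deterministic synthetic provider (backed by an in-memory panorama store)
can stand in for the real metadata web service.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Protocol

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .coverage import image_age_months
from .errors import InvalidInputError
from .spatial import SamplePoint

STATUS_OK = "OK"
STATUS_ZERO = "ZERO_RESULTS"
STATUS_ERROR = "ERROR"


@dataclass(frozen=True)
class ImageryMetadata:
    """One metadata response for a query point."""

    status: str
    capture_year: int | None = None
    capture_month: int | None = None
    pano_x: float | None = None
    pano_y: float | None = None

    def __post_init__(self) -> None:
        if self.status == STATUS_OK:
            if self.capture_year is None or self.capture_month is None:
                raise InvalidInputError("OK metadata requires a capture date")
            if not 1 <= self.capture_month <= 12:
                raise InvalidInputError("capture_month must be in 1..12")


@dataclass(frozen=True)
class Panorama:
    pano_id: str
    x: float
    y: float
    capture_year: int
    capture_month: int


class ImageryProvider(Protocol):
    def query(self, x: float, y: float, radius_m: float) -> ImageryMetadata: ...


class SyntheticProvider:
    """Deterministic provider over a fixed panorama store.

    Selection rule: the closest panorama within the radius wins; panoramas
    tied on distance (within 1e-9 m) are broken by most recent capture
    date, then by smallest pano_id.  ``fail_predicate(x, y)`` can force an
    ERROR response to exercise the complete-case pathway.
    """

    DIST_TIE_TOL = 1e-9

    def __init__(
        self,
        panoramas: Iterable[Panorama],
        fail_predicate: Callable[[float, float], bool] | None = None,
    ):
        self.panoramas = list(panoramas)
        self.fail_predicate = fail_predicate
        self._xy = np.array([[p.x, p.y] for p in self.panoramas], float).reshape(-1, 2)
        self._tree = cKDTree(self._xy) if len(self.panoramas) else None

    def _select(self, candidates: list[int], x: float, y: float) -> Panorama:
        def key(i: int):
            p = self.panoramas[i]
            d = float(np.hypot(p.x - x, p.y - y))
            # quantize distance so near-exact ties fall together
            dq = round(d / self.DIST_TIE_TOL)
            return (dq, -(p.capture_year * 12 + p.capture_month), p.pano_id)

        return self.panoramas[min(candidates, key=key)]

    def query(self, x: float, y: float, radius_m: float = 100.0) -> ImageryMetadata:
        if self.fail_predicate is not None and self.fail_predicate(x, y):
            return ImageryMetadata(status=STATUS_ERROR)
        if self._tree is None:
            return ImageryMetadata(status=STATUS_ZERO)
        candidates = self._tree.query_ball_point([x, y], r=radius_m)
        if not candidates:
            return ImageryMetadata(status=STATUS_ZERO)
        best = self._select(candidates, x, y)
        return ImageryMetadata(
            status=STATUS_OK,
            capture_year=best.capture_year,
            capture_month=best.capture_month,
            pano_x=best.x,
            pano_y=best.y,
        )

    def query_exhaustive(self, x: float, y: float, radius_m: float = 100.0) -> ImageryMetadata:
        """Reference implementation: linear scan of the whole store.

        The KD-tree path must agree with this exactly; kept as the oracle
        side of that check.
        """
        if self.fail_predicate is not None and self.fail_predicate(x, y):
            return ImageryMetadata(status=STATUS_ERROR)
        dists = np.hypot(self._xy[:, 0] - x, self._xy[:, 1] - y)
        candidates = [i for i, d in enumerate(dists) if d <= radius_m]
        if not candidates:
            return ImageryMetadata(status=STATUS_ZERO)
        best = self._select(candidates, x, y)
        return ImageryMetadata(
            status=STATUS_OK,
            capture_year=best.capture_year,
            capture_month=best.capture_month,
            pano_x=best.x,
            pano_y=best.y,
        )


class HttpMetadataProvider:
    """Thin adapter for a street-imagery metadata HTTP endpoint.

    Provided for completeness of the provider interface; it performs no key
    management and is not exercised by the test suite (no network).  Any
    transport failure maps to an ERROR response rather than raising.
    """

    def __init__(self, url_template: str, timeout_s: float = 10.0):
        self.url_template = url_template
        self.timeout_s = timeout_s

    def query(self, x: float, y: float, radius_m: float = 100.0) -> ImageryMetadata:
        import json
        import urllib.request

        try:
            url = self.url_template.format(lat=y, lon=x, radius=radius_m)
            with urllib.request.urlopen(url, timeout=self.timeout_s) as resp:
                payload = json.loads(resp.read().decode("utf-8"))
        except Exception:
            return ImageryMetadata(status=STATUS_ERROR)
        status = payload.get("status")
        if status != "OK":
            return ImageryMetadata(status=STATUS_ZERO)
        date = payload.get("date", "")
        try:
            year, month = (int(t) for t in date.split("-")[:2])
        except ValueError:
            return ImageryMetadata(status=STATUS_ERROR)
        loc = payload.get("location", {})
        return ImageryMetadata(
            status=STATUS_OK,
            capture_year=year,
            capture_month=month,
            pano_x=loc.get("lng"),
            pano_y=loc.get("lat"),
        )


def query_metadata(
    point: SamplePoint, provider: ImageryProvider, radius_m: float = 100.0
) -> ImageryMetadata:
    """Query one sample point against a provider."""
    return provider.query(point.x, point.y, radius_m)


def audit_points(
    points: list[SamplePoint],
    provider: ImageryProvider,
    radius_m: float = 100.0,
    ref_year: int = 2019,
    ref_month: int = 4,
) -> tuple[pd.DataFrame, dict]:
    """Audit every eligible point and build the completeness report.

    Returns the audited frame (one row per point, ERROR rows included with
    ``analysis_ok = False``) and a report dict with counts and percentages
    of each status.  Downstream model stages use only ``analysis_ok`` rows,
    i.e. complete cases.
    """
    records = []
    for p in points:
        meta = provider.query(p.x, p.y, radius_m)
        age = (
            image_age_months(meta.capture_year, meta.capture_month, ref_year, ref_month)
            if meta.status == STATUS_OK
            else None
        )
        records.append(
            {
                "point_id": p.point_id,
                "city_id": p.city_id,
                "subcity_id": p.subcity_id,
                "x": p.x,
                "y": p.y,
                "road_length_m": p.road_length_m,
                "status": meta.status,
                "capture_year": meta.capture_year,
                "capture_month": meta.capture_month,
                "age_months": age,
                "available": meta.status == STATUS_OK,
                "analysis_ok": meta.status != STATUS_ERROR,
            }
        )
    frame = pd.DataFrame.from_records(records)
    report = audit_report(frame)
    return frame, report


def audit_report(frame: pd.DataFrame) -> dict:
    """Counts and percentages of OK / ZERO_RESULTS / ERROR in an audited frame."""
    n = len(frame)
    counts = frame["status"].value_counts().to_dict() if n else {}
    n_ok = int(counts.get(STATUS_OK, 0))
    n_zero = int(counts.get(STATUS_ZERO, 0))
    n_err = int(counts.get(STATUS_ERROR, 0))
    return {
        "n_audited": n,
        "n_ok": n_ok,
        "n_zero_results": n_zero,
        "n_error": n_err,
        "pct_ok": 100.0 * n_ok / n if n else 0.0,
        "pct_zero_results": 100.0 * n_zero / n if n else 0.0,
        "pct_error": 100.0 * n_err / n if n else 0.0,
        "n_analysis": n - n_err,
    }


def validate_excluded(
    excluded_points: list[SamplePoint],
    provider: ImageryProvider,
    sample_n: int,
    seed: int,
    radius_m: float = 100.0,
) -> float:
    """Fraction of a seeded random sample of excluded points returning imagery."""
    if sample_n > len(excluded_points):
        raise InvalidInputError(
            f"sample_n={sample_n} exceeds the {len(excluded_points)} excluded points"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(excluded_points), size=sample_n, replace=False)
    n_ok = 0
    for i in idx:
        p = excluded_points[i]
        if provider.query(p.x, p.y, radius_m).status == STATUS_OK:
            n_ok += 1
    return n_ok / sample_n if sample_n else 0.0
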