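"""Association models: point-level availability and subcity-level age outcomes.

Availability is modeled with a mixed-effects logistic regression (one
exposure at a time, controls for road length, country, and unit area;
city-grouped random intercept plus random slopes on the per-city
standardized X/Y coordinates).  Image age and image-age variance are
modeled at the subcity level with a linear mixed model carrying a city
random intercept.  All continuous exposures and controls are Z-scored over
the complete-case analysis set of the model being fit; the combined SES
indices enter untransformed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

from . import ses
from .errors import InvalidInputError, RankDeficiencyError, StreetcoverError
from .glmm import GLMMResult, fit_logistic_glmm

#: Central American countries pooled into one factor level.
CENTRAL_AMERICA = frozenset({"SV", "NI", "PA", "CR", "GT"})
CENTRAL_AMERICA_LEVEL = "CA"

INDEX_EXPOSURES = ("index_without_poverty", "index_with_poverty")

OUTCOME_AVAILABILITY = "availability"
OUTCOME_MEAN_AGE = "mean_age_months"
OUTCOME_SD_AGE = "sd_age_months"


def pool_central_america(countries: pd.Series) -> pd.Series:
    """Recode the five Central American country codes to one pooled level."""
    return countries.where(~countries.isin(CENTRAL_AMERICA), CENTRAL_AMERICA_LEVEL)


def standardize_xy(frame: pd.DataFrame) -> pd.DataFrame:
    """Per-city Z-standardized coordinates around the sampled-point center of mass.

    Adds ``x_std``/``y_std`` columns.  A city with a single point (or zero
    coordinate spread on an axis) gets zeros on that axis with a warning.
    """
    frame = frame.copy()
    frame["x_std"] = 0.0
    frame["y_std"] = 0.0
    for city, grp in frame.groupby("city_id"):
        if len(grp) < 2:
            warnings.warn(f"city {city}: single sampled point, x/y set to 0", stacklevel=2)
            continue
        for axis, out in (("x", "x_std"), ("y", "y_std")):
            vals = grp[axis].to_numpy(float)
            sd = vals.std(ddof=1)
            if sd == 0:
                warnings.warn(
                    f"city {city}: zero spread on {axis}, {out} set to 0", stacklevel=2
                )
                continue
            frame.loc[grp.index, out] = (vals - vals.mean()) / sd
    return frame


@dataclass
class ModelResult:
    """One battery cell, formatted like the results table."""

    outcome: str
    exposure: str
    n: int
    estimate: float
    se: float
    p_value: float
    odds_ratio: float | None
    converged: bool
    variance_components: dict = field(default_factory=dict)
    stratum: str = "all"
    message: str = ""

    def conf_int(self, level: float = 0.95) -> tuple[float, float]:
        z = norm.ppf(0.5 + level / 2.0)
        return self.estimate - z * self.se, self.estimate + z * self.se


@dataclass
class AvailabilityDesign:
    """Assembled point-level design for the mixed logistic model."""

    X: np.ndarray
    y: np.ndarray
    groups: np.ndarray
    Z: np.ndarray
    fe_names: list[str]
    re_names: list[str]
    exposure: str
    n: int


@dataclass
class SubcityDesign:
    """Assembled unit-level design for the linear mixed model."""

    X: np.ndarray
    y: np.ndarray
    groups: np.ndarray
    fe_names: list[str]
    exposure: str
    outcome: str
    n: int


def _zscore_inplace(arr: np.ndarray) -> np.ndarray:
    return ses.zscore(arr)


def _country_dummies(countries: pd.Series) -> tuple[np.ndarray, list[str]]:
    pooled = pool_central_america(countries.astype(str))
    levels = sorted(pooled.unique())
    cols, names = [], []
    for lev in levels[1:]:  # first level is the reference
        cols.append((pooled == lev).to_numpy(float))
        names.append(f"country[{lev}]")
    if cols:
        return np.column_stack(cols), names
    return np.empty((len(countries), 0)), names


def _merge_exposures(rows: pd.DataFrame, units: pd.DataFrame) -> pd.DataFrame:
    """Attach unit covariates, area, country, and both SES indices."""
    ses.validate_units(units)
    try:
        idx = ses.index_table(units)
    except StreetcoverError:
        # a degenerate covariate breaks the combined indices but must not
        # block the single-covariate models
        idx = pd.DataFrame(
            {
                "subcity_id": units["subcity_id"],
                "index_without_poverty": np.nan,
                "index_with_poverty": np.nan,
            }
        )
    unit_cols = ["subcity_id", "area_km2"]
    for extra in ("country", "city_id"):
        if extra in units.columns:
            unit_cols.append(extra)
    unit_cols += [c for c in ses.ALL_COVARIATES if c in units.columns]
    # the unit table is authoritative for any column both sides carry
    overlap = (set(unit_cols) - {"subcity_id"}) & set(rows.columns)
    rows = rows.drop(columns=list(overlap))
    merged = rows.merge(units[unit_cols], on="subcity_id", how="left")
    merged = merged.merge(idx, on="subcity_id", how="left")
    return merged


def build_availability_design(
    audited: pd.DataFrame,
    units: pd.DataFrame,
    exposure: str,
    include_road_control: bool = True,
) -> AvailabilityDesign:
    """Complete-case point-level design for one exposure.

    ``audited`` is the audit-stage frame (must carry point coordinates,
    road lengths, city and subcity ids, and ``available``); ERROR rows and
    rows missing the exposure or any control are dropped, then every
    continuous term is Z-scored over what remains.
    """
    rows = audited[audited.get("analysis_ok", True) == True]  # noqa: E712
    rows = rows[rows["subcity_id"].notna()]
    merged = _merge_exposures(rows, units)
    if exposure not in merged.columns:
        raise InvalidInputError(f"unknown exposure {exposure!r}")
    needed = [exposure, "road_length_m", "area_km2", "country", "x", "y"]
    merged = merged.dropna(subset=needed)
    if merged.empty:
        raise InvalidInputError("no complete-case rows for this design")
    merged = standardize_xy(merged)

    exp_vals = merged[exposure].to_numpy(float)
    # the combined indices are already sums of Z-scores and enter as-is
    exp_term = exp_vals if exposure in INDEX_EXPOSURES else _zscore_inplace(exp_vals)
    cols = [np.ones(len(merged)), exp_term]
    names = ["intercept", exposure]
    if include_road_control:
        cols.append(_zscore_inplace(merged["road_length_m"].to_numpy(float)))
        names.append("road_length_z")
    cols.append(_zscore_inplace(merged["area_km2"].to_numpy(float)))
    names.append("area_z")
    dummies, dummy_names = _country_dummies(merged["country"])
    X = np.column_stack(cols + ([dummies] if dummy_names else []))
    names += dummy_names

    Z = np.column_stack(
        [np.ones(len(merged)), merged["x_std"].to_numpy(), merged["y_std"].to_numpy()]
    )
    return AvailabilityDesign(
        X=X,
        y=merged["available"].astype(int).to_numpy(),
        groups=merged["city_id"].to_numpy(),
        Z=Z,
        fe_names=names,
        re_names=["re_intercept", "re_x", "re_y"],
        exposure=exposure,
        n=len(merged),
    )


def fit_availability_model(
    design: AvailabilityDesign,
    random_intercept: bool = True,
    fix_zero_variance: bool = False,
) -> ModelResult:
    """Laplace-approximation mixed logistic fit; exposure reported per SD."""
    Z = design.Z if random_intercept else design.Z[:, 1:]
    re_names = design.re_names if random_intercept else design.re_names[1:]
    res = fit_logistic_glmm(
        design.X,
        design.y,
        design.groups,
        Z=Z,
        fe_names=design.fe_names,
        re_names=re_names,
        fix_zero_variance=fix_zero_variance,
    )
    return _result_from_glmm(res, design)


def _result_from_glmm(res: GLMMResult, design: AvailabilityDesign) -> ModelResult:
    i = design.fe_names.index(design.exposure)
    return ModelResult(
        outcome=OUTCOME_AVAILABILITY,
        exposure=design.exposure,
        n=res.n,
        estimate=float(res.beta[i]),
        se=float(res.se[i]),
        p_value=float(res.p_values[i]),
        odds_ratio=float(np.exp(res.beta[i])),
        converged=res.converged,
        variance_components={
            name: float(sd**2) for name, sd in zip(res.re_names, res.re_sd)
        },
        message=res.message,
    )


def build_subcity_design(
    coverage: pd.DataFrame,
    units: pd.DataFrame,
    exposure: str,
    outcome: str,
) -> SubcityDesign:
    """Complete-case unit-level design for the linear mixed model.

    ``coverage`` is the subcity aggregation (``unit_id`` keyed) and must
    expose the requested outcome column; units with an undefined outcome
    (no available imagery, or a single image for the SD outcome) drop out.
    """
    if outcome not in (OUTCOME_MEAN_AGE, OUTCOME_SD_AGE):
        raise InvalidInputError(f"unknown subcity outcome {outcome!r}")
    rows = coverage.rename(columns={"unit_id": "subcity_id"})[
        ["subcity_id", outcome]
    ]
    merged = _merge_exposures(rows, units)
    if "city_id" not in merged.columns:
        if "city_id" in units.columns:
            merged = merged.merge(units[["subcity_id", "city_id"]], on="subcity_id")
        else:
            raise InvalidInputError("units table must carry city_id")
    if exposure not in merged.columns:
        raise InvalidInputError(f"unknown exposure {exposure!r}")
    merged = merged.dropna(subset=[outcome, exposure, "area_km2", "country"])
    if merged.empty:
        raise InvalidInputError("no complete-case rows for this design")

    exp_vals = merged[exposure].to_numpy(float)
    exp_term = exp_vals if exposure in INDEX_EXPOSURES else _zscore_inplace(exp_vals)
    cols = [np.ones(len(merged)), exp_term,
            _zscore_inplace(merged["area_km2"].to_numpy(float))]
    names = ["intercept", exposure, "area_z"]
    dummies, dummy_names = _country_dummies(merged["country"])
    if dummy_names:
        cols.append(dummies)
        names += dummy_names
    X = np.column_stack(cols)
    if len(merged) <= X.shape[1]:
        raise RankDeficiencyError(
            f"{len(merged)} units cannot identify {X.shape[1]} fixed effects"
        )
    return SubcityDesign(
        X=X,
        y=merged[outcome].to_numpy(float),
        groups=merged["city_id"].to_numpy(),
        fe_names=names,
        exposure=exposure,
        outcome=outcome,
        n=len(merged),
    )


def fit_subcity_model(design: SubcityDesign, force_zero_re: bool = False) -> ModelResult:
    """REML linear mixed model with a city random intercept.

    ``force_zero_re`` pins the random-intercept variance at zero, which
    must reproduce ordinary least squares (checked against that oracle).
    """
    i = design.fe_names.index(design.exposure)
    if force_zero_re:
        # at the boundary cov_re = 0 the marginal covariance is sigma^2 I,
        # so the REML solution is least squares with the usual REML scale
        n, p = design.X.shape
        beta_hat, *_ = np.linalg.lstsq(design.X, design.y, rcond=None)
        resid = design.y - design.X @ beta_hat
        scale = float(resid @ resid) / (n - p)
        cov_beta = scale * np.linalg.inv(design.X.T @ design.X)
        b = float(beta_hat[i])
        se = float(np.sqrt(cov_beta[i, i]))
        p_val = float(2.0 * norm.sf(abs(b) / se)) if se > 0 else float("nan")
        return ModelResult(
            outcome=design.outcome,
            exposure=design.exposure,
            n=design.n,
            estimate=b,
            se=se,
            p_value=p_val,
            odds_ratio=None,
            converged=True,
            variance_components={"city_intercept": 0.0, "residual": scale},
        )
    # noiseless limit: an exactly linear outcome degenerates the REML
    # problem, so return the interpolating solution directly
    beta_exact, *_ = np.linalg.lstsq(design.X, design.y, rcond=None)
    rss = float(np.sum((design.y - design.X @ beta_exact) ** 2))
    if rss <= 1e-10 * max(1.0, float(design.y @ design.y)):
        return ModelResult(
            outcome=design.outcome,
            exposure=design.exposure,
            n=design.n,
            estimate=float(beta_exact[i]),
            se=0.0,
            p_value=float("nan"),
            odds_ratio=None,
            converged=True,
            variance_components={"city_intercept": 0.0, "residual": 0.0},
        )
    model = sm.MixedLM(design.y, design.X, groups=design.groups)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(reml=True)
    b = float(fit.fe_params[i])
    se = float(fit.bse_fe[i])
    p = float(2.0 * norm.sf(abs(b) / se)) if se > 0 else float("nan")
    return ModelResult(
        outcome=design.outcome,
        exposure=design.exposure,
        n=design.n,
        estimate=b,
        se=se,
        p_value=p,
        odds_ratio=None,
        converged=bool(getattr(fit, "converged", True)),
        variance_components={
            "city_intercept": float(np.atleast_2d(fit.cov_re)[0, 0]),
            "residual": float(fit.scale),
        },
    )


def run_model_battery(
    audited: pd.DataFrame,
    coverage_subcity: pd.DataFrame,
    units: pd.DataFrame,
    exposures: list[str],
    outcomes: list[str],
    strata: str = "all",
) -> pd.DataFrame:
    """One model per exposure x outcome (x country stratum); failures recorded.

    Returns the results table with columns outcome, exposure, stratum, n,
    b, OR, SE, p, converged.
    """
    if strata == "all":
        labels = ["all"]
    elif strata == "per-country":
        labels = sorted(pool_central_america(units["country"].astype(str)).unique())
    else:
        raise InvalidInputError(f"unknown strata mode {strata!r}")

    rows = []
    for label in labels:
        if label == "all":
            sub_units = units
        else:
            pooled = pool_central_america(units["country"].astype(str))
            sub_units = units[pooled == label]
        keep_ids = set(sub_units["subcity_id"])
        sub_audit = audited[audited["subcity_id"].isin(keep_ids)]
        sub_cov = coverage_subcity[coverage_subcity["unit_id"].isin(keep_ids)]
        for outcome in outcomes:
            for exposure in exposures:
                rows.append(
                    _battery_cell(sub_audit, sub_cov, sub_units, exposure, outcome, label)
                )
    frame = pd.DataFrame(rows)
    return frame


def _battery_cell(audited, coverage, units, exposure, outcome, stratum) -> dict:
    try:
        if outcome == OUTCOME_AVAILABILITY:
            design = build_availability_design(audited, units, exposure)
            result = fit_availability_model(design)
        else:
            design = build_subcity_design(coverage, units, exposure, outcome)
            result = fit_subcity_model(design)
        return {
            "outcome": outcome,
            "exposure": exposure,
            "stratum": stratum,
            "n": result.n,
            "b": result.estimate,
            "OR": result.odds_ratio,
            "SE": result.se,
            "p": result.p_value,
            "converged": result.converged,
            "error": "",
        }
    except Exception as exc:  # a failing cell must not abort the battery
        return {
            "outcome": outcome,
            "exposure": exposure,
            "stratum": stratum,
            "n": 0,
            "b": np.nan,
            "OR": np.nan,
            "SE": np.nan,
            "p": np.nan,
            "converged": False,
            "error": f"{type(exc).__name__}: {exc}",
        }
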