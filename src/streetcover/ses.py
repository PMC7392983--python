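"""Subcity socioeconomic covariates and the combined Z-score indices.

The combined index is an unweighted sum of Z-scored covariates across the
analysis set; one version includes the above-poverty share and one leaves
it out (poverty is unavailable in some countries).  Higher values indicate
better socioeconomic conditions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DegenerateSpreadError, InvalidInputError

#: Covariates entering the core (without-poverty) combined index.
CORE_INDEX_COVARIATES = (
    "pct_piped_water",
    "pct_sewer",
    "pct_durable_walls",
    "pct_labor",
    "pct_secondary_edu",
)

#: The optional poverty covariate added in the with-poverty index.
POVERTY_COVARIATE = "pct_above_poverty"

#: All subcity covariates modeled individually (population density is a
#: variable of interest but does not enter the combined indices).
ALL_COVARIATES = ("pop_density",) + CORE_INDEX_COVARIATES + (POVERTY_COVARIATE,)

PERCENT_COVARIATES = CORE_INDEX_COVARIATES + (POVERTY_COVARIATE,)


def validate_units(units: pd.DataFrame) -> None:
    """Check SubcityUnit invariants: percent ranges and positive areas."""
    if "area_km2" in units.columns and (units["area_km2"] <= 0).any():
        raise InvalidInputError("area_km2 must be positive for every unit")
    for col in PERCENT_COVARIATES:
        if col not in units.columns:
            continue
        vals = units[col].dropna()
        if ((vals < 0) | (vals > 100)).any():
            raise InvalidInputError(f"{col} must lie in [0, 100]")


def zscore(values) -> np.ndarray:
    """Z-score a vector using the sample (n-1) standard deviation.

    Missing entries (NaN) are excluded from the mean/SD and propagate as
    NaN in the output.
    """
    arr = np.asarray(values, dtype=float)
    observed = arr[np.isfinite(arr)]
    if observed.size < 2:
        raise InvalidInputError("zscore needs at least 2 observed values")
    sd = float(np.std(observed, ddof=1))
    if sd == 0.0:
        raise DegenerateSpreadError("cannot Z-score a constant vector")
    return (arr - float(np.mean(observed))) / sd


def combined_index(
    units: pd.DataFrame, include_poverty: bool = False
) -> tuple[pd.Series, pd.Index]:
    """Sum of covariate Z-scores per unit, standardized over the analysis set.

    Returns the index (indexed like ``units``, NaN for excluded rows) and
    the index labels of units excluded for missing poverty data.  With
    ``include_poverty`` the standardization population is restricted to the
    units observed on poverty, matching a complete-case analysis.
    """
    covariates = list(CORE_INDEX_COVARIATES)
    if include_poverty:
        covariates.append(POVERTY_COVARIATE)
    missing_cols = [c for c in covariates if c not in units.columns]
    if missing_cols:
        raise InvalidInputError(f"missing covariate columns: {missing_cols}")
    mask = units[covariates].notna().all(axis=1)
    excluded = units.index[~mask]
    sub = units.loc[mask, covariates]
    z = np.column_stack([zscore(sub[c].to_numpy()) for c in covariates])
    out = pd.Series(np.nan, index=units.index, name="ses_index")
    out.loc[mask] = z.sum(axis=1)
    return out, excluded


def index_table(units: pd.DataFrame) -> pd.DataFrame:
    """Both combined indices keyed by subcity_id (the stage's CSV schema)."""
    without, _ = combined_index(units, include_poverty=False)
    has_poverty = POVERTY_COVARIATE in units.columns and units[
        POVERTY_COVARIATE
    ].notna().sum() >= 2
    if has_poverty:
        with_pov, _ = combined_index(units, include_poverty=True)
    else:
        with_pov = pd.Series(np.nan, index=units.index)
    return pd.DataFrame(
        {
            "subcity_id": units["subcity_id"].to_numpy(),
            "index_without_poverty": without.to_numpy(),
            "index_with_poverty": with_pov.to_numpy(),
        }
    )
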