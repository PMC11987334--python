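"""Per-week change slopes from a random-intercept + random-slope model.

For a longitudinally measured parameter y, the model is

    y_ij = b0 + b1 * week_ij + u0_i + u1_i * week_ij + e_ij

with independent (diagonal-covariance) patient random effects u0, u1 and
REML estimation.  b1 is the average change per week; its p-value is a
Wald z test.  Fitting is delegated to statsmodels MixedLM with the
off-diagonal random-effects covariance constrained to zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.regression.mixed_linear_model import MixedLM, MixedLMParams

from fibroscore import schema
from fibroscore.errors import InvalidArgumentError


@dataclass
class SlopeResult:
    slope_per_week: float
    intercept: float
    var_intercept: float
    var_slope: float
    var_resid: float
    p: float
    n_patients: int
    n_obs: int


def fit_slope_lmm(values, weeks, patient_ids) -> SlopeResult:
    """REML fit of the random-intercept+slope model; returns the slope."""
    y = np.asarray(values, dtype=float)
    w = np.asarray(weeks, dtype=float)
    g = np.asarray(patient_ids)
    if not (len(y) == len(w) == len(g)):
        raise InvalidArgumentError("values, weeks, patient_ids must be equal length")
    uniq, counts = np.unique(g, return_counts=True)
    if len(uniq) < 2:
        raise InvalidArgumentError("need >= 2 patients for random effects")
    if np.sum(counts >= 2) < 2:
        raise InvalidArgumentError("need >= 2 patients with >= 2 timepoints")
    if np.unique(w).size < 2:
        raise InvalidArgumentError("all weeks identical: slope is rank-deficient")

    exog = np.column_stack([np.ones_like(w), w])
    free = MixedLMParams.from_components(
        fe_params=np.ones(2), cov_re=np.eye(2)
    )  # zero off-diagonal: independent covariance structure
    model = MixedLM(y, exog, groups=g, exog_re=exog)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(reml=True, free=free, method="lbfgs", maxiter=500)
        cov_re = np.asarray(fit.cov_re)
        bse = float(fit.bse_fe[1])
        p = float(fit.pvalues[1]) if np.isfinite(bse) else float("nan")
    return SlopeResult(
        slope_per_week=float(fit.fe_params[1]),
        intercept=float(fit.fe_params[0]),
        var_intercept=max(float(cov_re[0, 0]), 0.0),
        var_slope=max(float(cov_re[1, 1]), 0.0),
        var_resid=max(float(fit.scale), 0.0),
        p=p,
        n_patients=len(uniq),
        n_obs=len(y),
    )


def slope_table(sheets: pd.DataFrame, visits: pd.DataFrame) -> pd.DataFrame:
    """Per-parameter change/week table from rater score sheets.

    ``visits`` maps biopsy_id -> (patient_id, week).  All rater/session
    rows enter the fit as repeated measurements.  Parameters failing
    fit preconditions are reported as NA with the reason.
    """
    merged = sheets.merge(visits[["biopsy_id", "patient_id", "week"]], on="biopsy_id")
    rows = []
    for p in schema.PARAMETER_NAMES:
        try:
            r = fit_slope_lmm(merged[p], merged["week"], merged["patient_id"])
            rows.append(
                {"parameter": p, "slope_per_week": r.slope_per_week, "p": r.p,
                 "var_intercept": r.var_intercept, "var_slope": r.var_slope,
                 "var_resid": r.var_resid, "note": ""}
            )
        except (InvalidArgumentError, np.linalg.LinAlgError, ValueError) as e:
            rows.append(
                {"parameter": p, "slope_per_week": np.nan, "p": np.nan,
                 "var_intercept": np.nan, "var_slope": np.nan, "var_resid": np.nan,
                 "note": str(e)}
            )
    return pd.DataFrame(rows)
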