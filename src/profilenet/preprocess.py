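"""Covariate adjustment and standardization.

Every downstream analysis consumes either age/IQ-residualized matrices
(network estimation) or z-scored matrices (community-profile analysis).
Residual regressions are ordinary least squares with an intercept, fit per
variable per wave over all participants of both groups pooled, so that
group differences remain visible after adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CohortTable

_TOL = 1e-8


@dataclass
class ResidualMatrix:
    """OLS residuals per variable for one wave, plus fitted coefficients.

    ``coefficients`` rows are (intercept, age, iq) per variable.
    """

    residuals: pd.DataFrame          # participants x variables
    coefficients: pd.DataFrame       # variables x (intercept, age, iq)
    wave: str


def residualize(cohort: CohortTable, wave: str, by_group: bool = False) -> ResidualMatrix:
    """Remove linear age and IQ effects from every variable in one wave.

    Fits, for each variable, ``y ~ 1 + age + iq`` by OLS and returns the
    residuals.  With ``by_group=True`` the regression is fit separately
    within each group instead of pooled.
    """
    values = cohort.values(wave)
    cov = cohort.covariates(wave)
    if not by_group:
        resid, coefs = _ols_residuals(values.to_numpy(), cov.to_numpy())
    else:
        resid = np.empty_like(values.to_numpy())
        coefs = np.full((values.shape[1], 3), np.nan)
        groups = cohort.groups(wave)
        for g in groups.unique():
            mask = (groups == g).to_numpy()
            resid[mask], coefs = _ols_residuals(
                values.to_numpy()[mask], cov.to_numpy()[mask]
            )
    residuals = pd.DataFrame(resid, index=values.index, columns=values.columns)
    coefficients = pd.DataFrame(
        coefs, index=values.columns, columns=["intercept", "age", "iq"]
    )
    return ResidualMatrix(residuals, coefficients, wave)


def _ols_residuals(Y: np.ndarray, covariates: np.ndarray):
    n = Y.shape[0]
    if n < 4:
        raise ValueError(f"need at least 4 rows to residualize, got {n}")
    X = np.column_stack([np.ones(n), covariates])
    # rank check catches constant or collinear covariates
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("singular design: covariates constant or collinear")
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return Y - X @ beta, beta.T


def standardize(matrix: pd.DataFrame | ResidualMatrix) -> pd.DataFrame:
    """Column-wise z-scores, (x - mean) / sd with the n-1 sample sd."""
    if isinstance(matrix, ResidualMatrix):
        matrix = matrix.residuals
    sd = matrix.std(axis=0, ddof=1)
    dead = sd.index[sd.to_numpy() <= 0].tolist()
    if dead:
        raise ValueError(f"zero-variance columns cannot be standardized: {dead}")
    return (matrix - matrix.mean(axis=0)) / sd


def covariance_matrix(matrix: pd.DataFrame | ResidualMatrix) -> pd.DataFrame:
    """Sample covariance (n-1 denominator) of a per-wave matrix."""
    if isinstance(matrix, ResidualMatrix):
        matrix = matrix.residuals
    if matrix.shape[0] < 2:
        raise ValueError("covariance needs at least 2 rows")
    return matrix.cov(ddof=1)
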