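"""Profile factors: per-cluster confirmatory factor models and factor scores.

The 24 z-scored variables collapse onto 12 profile factors.  Each
multi-indicator cluster gets its own one-factor model (unit factor
variance, free loadings, diagonal residual covariance) estimated by
maximum likelihood on the cluster's correlation matrix; single-indicator
factors pass the indicator's z-score through unchanged.  Participants are
scored by the regression (Thurstone) method.

Identification notes: a one-factor model with two indicators is not
identified with free loadings, so two-indicator clusters are fit with the
loadings constrained equal in magnitude (closed form: lambda^2 = |r|).
The first indicator's loading is always constrained positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .schema import VariableSchema

_PSI_FLOOR = 1e-4   # Heywood-case bound on residual variances


@dataclass
class FactorModel:
    """One fitted single-factor measurement model."""

    factor: str
    indicators: list[str]
    loadings: np.ndarray
    residual_variances: np.ndarray
    loglik: float
    wave: str | None = None
    converged: bool = True

    def implied_covariance(self) -> np.ndarray:
        lam = self.loadings
        return np.outer(lam, lam) + np.diag(self.residual_variances)


def _ml_discrepancy(S: np.ndarray, sigma: np.ndarray) -> float:
    p = S.shape[0]
    sign, logdet_sigma = np.linalg.slogdet(sigma)
    if sign <= 0:
        return np.inf
    _, logdet_s = np.linalg.slogdet(S)
    return float(logdet_sigma + np.trace(np.linalg.solve(sigma, S)) - logdet_s - p)


def fit_factor(z: pd.DataFrame, factor: str = "", wave: str | None = None,
               tol: float = 1e-10) -> FactorModel:
    """Maximum-likelihood one-factor model on a cluster of z-scored columns.

    Minimizes the Wishart ML discrepancy
    ``log|Sigma| + tr(S Sigma^-1) - log|S| - p`` with
    ``Sigma = lambda lambda' + diag(psi)`` and unit factor variance.
    Residual variances collapsing toward zero (Heywood cases) are bounded
    at 1e-4 with a warning.
    """
    cols = list(z.columns)
    p = len(cols)
    if p < 2:
        raise ValueError("fit_factor needs at least 2 indicators; "
                         "single-indicator factors bypass model fitting")
    n = z.shape[0]
    S = np.corrcoef(z.to_numpy(), rowvar=False)

    if p == 2:
        r = float(S[0, 1])
        lam_mag = np.sqrt(min(abs(r), 1.0 - _PSI_FLOOR))
        lam = np.array([lam_mag, np.sign(r) * lam_mag if r != 0 else 0.0])
        psi = np.clip(1.0 - lam ** 2, _PSI_FLOOR, None)
        sigma = np.outer(lam, lam) + np.diag(psi)
        ll = -0.5 * n * (_ml_discrepancy(S, sigma))
        return FactorModel(factor, cols, lam, psi, ll, wave)

    def objective(x):
        lam, psi = x[:p], x[p:]
        return _ml_discrepancy(S, np.outer(lam, lam) + np.diag(psi))

    x0 = np.concatenate([np.full(p, 0.5), np.full(p, 0.5)])
    bounds = [(-1.5, 1.5)] * p + [(_PSI_FLOOR, 4.0)] * p
    res = minimize(objective, x0, method="L-BFGS-B", bounds=bounds,
                   options={"ftol": tol, "gtol": 1e-9, "maxiter": 2000})
    if not res.success and res.fun > 1e-6:
        raise RuntimeError(f"factor model for {factor!r} did not converge: {res.message}")
    lam, psi = res.x[:p].copy(), res.x[p:].copy()
    if np.any(psi <= _PSI_FLOOR * 1.01):
        warnings.warn(f"Heywood case in factor {factor!r}: residual variance bounded")
    if lam[0] < 0:  # sign identification: first loading positive
        lam = -lam
    ll = -0.5 * n * res.fun
    return FactorModel(factor, cols, lam, psi, ll, wave, converged=bool(res.success))


@dataclass
class FactorScores:
    """Participants x 12 factor scores for one wave."""

    scores: pd.DataFrame
    wave: str | None = None
    models: dict[str, FactorModel] | None = None


def score_participants(models: dict[str, FactorModel], z: pd.DataFrame,
                       schema: VariableSchema, wave: str | None = None,
                       method: str = "regression") -> FactorScores:
    """Factor scores per participant, factors in canonical order.

    Multi-indicator factors use the regression (Thurstone) scorer
    ``f = lambda' Sigma^-1 z`` from the fitted model; single-indicator
    factors are the indicator's z-score unchanged.
    """
    if method not in {"regression", "bartlett"}:
        raise ValueError(f"unknown scoring method {method!r}")
    out = {}
    for factor in schema.factors:
        members = schema.factor_members(factor)
        if len(members) == 1:
            out[factor] = z[members[0]].to_numpy()
            continue
        if factor not in models:
            raise ValueError(f"no fitted model for multi-indicator factor {factor!r}")
        m = models[factor]
        if m.indicators != members:
            raise ValueError(
                f"model for {factor!r} was fit on {m.indicators}, schema says {members}"
            )
        lam, psi = m.loadings, m.residual_variances
        X = z[members].to_numpy()
        if method == "regression":
            sigma = m.implied_covariance()
            w = np.linalg.solve(sigma, lam)
        else:  # Bartlett
            a = lam / psi
            w = a / (lam @ a)
        out[factor] = X @ w
    scores = pd.DataFrame(out, index=z.index)[list(schema.factors)]
    return FactorScores(scores, wave=wave, models=dict(models))


def fit_and_score(z: pd.DataFrame, schema: VariableSchema,
                  wave: str | None = None) -> FactorScores:
    """Fit all multi-indicator cluster models on one wave and score everyone."""
    models = {}
    for factor in schema.factors:
        members = schema.factor_members(factor)
        if len(members) >= 2:
            models[factor] = fit_factor(z[members], factor=factor, wave=wave)
    return score_participants(models, z, schema, wave=wave)
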