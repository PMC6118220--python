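"""Sparse Gaussian graphical model estimation with EBIC selection.

The network over the 24 residualized variables is the partial-correlation
graph implied by an L1-penalized precision matrix (graphical lasso).  The
penalty weight is selected by minimizing the extended Bayesian information
criterion (EBIC) on the pooled sample of both groups within a wave; the
selected weight is then reused to fit each group's network separately.
Node importance is summarized by strength centrality (sum of absolute
partial correlations), with percentile bootstrap confidence intervals from
group-wise resampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from sklearn.covariance import graphical_lasso

from .cohort import CohortTable
from .preprocess import covariance_matrix, residualize, standardize

_EDGE_TOL = 1e-10   # |theta_ij| above this counts as an edge


class GlassoConvergenceError(RuntimeError):
    def __init__(self, lam: float, max_iter: int, msg: str = ""):
        self.lam = lam
        self.max_iter = max_iter
        super().__init__(
            f"graphical lasso did not converge at lambda={lam:g} "
            f"within {max_iter} iterations. {msg}"
        )


@dataclass
class PrecisionModel:
    """A fitted penalized precision matrix.

    ``loglik_profile`` is log det(theta) - tr(S @ theta); multiply by n/2
    for the Gaussian log-likelihood up to an additive constant shared by
    all candidates on the same data.
    """

    theta: np.ndarray
    lam: float
    loglik_profile: float
    converged: bool = True

    @property
    def n_edges(self) -> int:
        p = self.theta.shape[0]
        iu = np.triu_indices(p, 1)
        return int((np.abs(self.theta[iu]) > _EDGE_TOL).sum())


@dataclass
class NetworkModel:
    """Partial-correlation network for one group in one wave."""

    nodes: list[str]
    weights: np.ndarray       # symmetric partial correlations, zero diagonal
    lambda_selected: float
    group: str | None = None
    wave: str | None = None

    def edge_list(self) -> pd.DataFrame:
        p = len(self.nodes)
        rows = [
            (self.nodes[i], self.nodes[j], self.weights[i, j])
            for i in range(p) for j in range(i + 1, p)
            if abs(self.weights[i, j]) > _EDGE_TOL
        ]
        return pd.DataFrame(rows, columns=["node_i", "node_j", "partial_correlation"])


@dataclass
class CentralityTable:
    """Strength centrality with bootstrap 95% confidence bounds."""

    table: pd.DataFrame       # node, group, wave, estimate, ci_low, ci_high
    n_bootstrap: int
    n_failed: int = 0
    replicates: dict = field(default_factory=dict, repr=False)


def glasso(S: np.ndarray, lam: float, max_iter: int = 500, tol: float = 1e-4,
           strict: bool = False) -> PrecisionModel:
    """L1-penalized precision estimate (diagonal unpenalized).

    At ``lam == 0`` the unpenalized maximum-likelihood estimate, the inverse
    of ``S``, is returned directly.  If the coordinate-descent solver stops
    at ``max_iter`` with the duality gap still above ``tol`` the estimate is
    returned with ``converged=False`` (``strict=True`` raises instead);
    a numerically invalid estimate always raises.
    """
    S = np.asarray(S, dtype=np.float64)
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    if not np.allclose(S, S.T, atol=1e-10):
        raise ValueError("covariance matrix must be symmetric")
    converged = True
    if lam == 0.0:
        c, low = cho_factor(S)
        theta = cho_solve((c, low), np.eye(S.shape[0]))
        theta = (theta + theta.T) / 2
    else:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            try:
                _, theta = graphical_lasso(S, alpha=lam, max_iter=max_iter, tol=tol)
            except (FloatingPointError, np.linalg.LinAlgError) as exc:
                raise GlassoConvergenceError(lam, max_iter, str(exc)) from exc
        if any("did not converge" in str(w.message) for w in caught):
            if strict:
                raise GlassoConvergenceError(lam, max_iter, "duality gap above tolerance")
            converged = False
        theta = (theta + theta.T) / 2
    if not np.all(np.isfinite(theta)):
        raise GlassoConvergenceError(lam, max_iter, "non-finite estimate")
    sign, logdet = np.linalg.slogdet(theta)
    if sign <= 0:
        raise GlassoConvergenceError(lam, max_iter, "estimate not positive definite")
    return PrecisionModel(theta, lam, float(logdet - np.trace(S @ theta)), converged)


def precision_to_partial(model: PrecisionModel, nodes: list[str] | None = None,
                         group: str | None = None, wave: str | None = None) -> NetworkModel:
    """Partial correlations rho_ij = -theta_ij / sqrt(theta_ii theta_jj)."""
    theta = model.theta
    d = np.diag(theta)
    if np.any(d <= 0):
        raise ValueError("precision matrix has nonpositive diagonal entries")
    denom = np.sqrt(np.outer(d, d))
    rho = -theta / denom
    np.fill_diagonal(rho, 0.0)
    rho = np.clip((rho + rho.T) / 2, -1.0, 1.0)
    if nodes is None:
        nodes = [f"V{i}" for i in range(theta.shape[0])]
    return NetworkModel(list(nodes), rho, model.lam, group, wave)


def ebic_score(model: PrecisionModel, S: np.ndarray, n: int, gamma: float = 0.5) -> float:
    """Extended BIC: -2 loglik + E log n + 4 gamma E log p.

    E is the number of edges (nonzero off-diagonal upper-triangle entries
    of theta) and p the number of nodes.  gamma = 0 reduces to ordinary BIC.
    """
    if n <= 0:
        raise ValueError("sample size must be positive")
    if gamma < 0:
        raise ValueError("gamma must be nonnegative")
    p = model.theta.shape[0]
    E = model.n_edges
    loglik = (n / 2.0) * model.loglik_profile
    return float(-2.0 * loglik + E * np.log(n) + 4.0 * gamma * E * np.log(p))


def lambda_grid(S: np.ndarray, n_lambdas: int = 100, min_ratio: float = 0.01) -> np.ndarray:
    """Log-spaced penalty grid, descending from the empty-graph threshold.

    The largest useful penalty is max_ij |S_ij| (i != j): above it the
    graphical lasso solution has no edges.
    """
    S = np.asarray(S)
    off = np.abs(S - np.diag(np.diag(S)))
    lam_max = float(off.max())
    if lam_max <= 0:
        lam_max = 1e-3
    return np.geomspace(lam_max, min_ratio * lam_max, n_lambdas)


def select_lambda(Z: pd.DataFrame | np.ndarray, gamma: float = 0.5,
                  n_lambdas: int = 100, min_ratio: float = 0.01,
                  grid: np.ndarray | None = None):
    """EBIC-minimizing penalty on the pooled sample.

    Returns ``(lambda_star, path)`` where ``path`` is a DataFrame with one
    row per grid point (lambda, ebic, n_edges).  Ties prefer the larger
    (sparser) penalty; the grid is traversed in descending order.
    """
    Z = np.asarray(Z, dtype=np.float64)
    n = Z.shape[0]
    S = np.cov(Z, rowvar=False, ddof=1)
    if grid is None:
        grid = lambda_grid(S, n_lambdas=n_lambdas, min_ratio=min_ratio)
    grid = np.sort(np.asarray(grid, dtype=np.float64))[::-1]
    rows, best_lam, best_score = [], None, np.inf
    for lam in grid:
        try:
            model = glasso(S, lam)
        except GlassoConvergenceError:
            rows.append((lam, np.nan, -1))
            continue
        score = ebic_score(model, S, n, gamma)
        rows.append((lam, score, model.n_edges))
        if score < best_score:  # strict: ties keep the sparser (earlier) lambda
            best_score, best_lam = score, lam
    if best_lam is None:
        raise GlassoConvergenceError(float(grid[0]), 0, "no lambda on the grid produced a fit")
    path = pd.DataFrame(rows, columns=["lambda", "ebic", "n_edges"])
    return float(best_lam), path


def estimate_group_networks(cohort: CohortTable, wave: str, lam: float,
                            gamma: float = 0.5) -> dict[str, NetworkModel]:
    """Fit each group's network at a shared, pre-selected penalty."""
    Z = standardize(residualize(cohort, wave))
    groups = cohort.groups(wave)
    out = {}
    for g in sorted(groups.unique()):
        sub = Z[groups == g]
        if sub.shape[0] < 2:
            raise ValueError(f"group {g!r} has fewer than 2 participants")
        if sub.shape[0] < 5:
            warnings.warn(f"group {g!r} has only {sub.shape[0]} participants")
        S = covariance_matrix(sub).to_numpy()
        model = glasso(S, lam)
        out[g] = precision_to_partial(model, nodes=list(Z.columns), group=g, wave=wave)
    return out


def centrality(network: NetworkModel, kind: str = "strength") -> pd.Series:
    """Node centrality: strength (sum |rho|, default) or unweighted degree."""
    W = np.abs(network.weights)
    if kind == "strength":
        vals = W.sum(axis=1)
    elif kind == "degree":
        vals = (W > _EDGE_TOL).sum(axis=1).astype(float)
    else:
        raise ValueError(f"unknown centrality kind {kind!r}")
    return pd.Series(vals, index=network.nodes, name=f"{kind}_centrality")


def bootstrap_centrality(cohort: CohortTable, wave: str, B: int = 1000,
                         gamma: float = 0.5, seed: int = 0,
                         n_lambdas: int = 100, min_ratio: float = 0.01,
                         kind: str = "strength",
                         max_failure_rate: float = 0.10) -> CentralityTable:
    """Percentile-bootstrap confidence intervals for node centrality.

    Each iteration resamples participants with replacement within each
    group (group sizes preserved), reselects the penalty by EBIC on the
    pooled resample, refits both group networks, and records centralities.
    The point estimate comes from the non-resampled fit; the 95% interval
    is the 2.5/97.5 percentile across successful iterations.
    """
    if B < 1:
        raise ValueError("B must be at least 1")
    Z = standardize(residualize(cohort, wave))
    groups = cohort.groups(wave)
    group_names = sorted(groups.unique())
    idx_by_group = {g: np.flatnonzero((groups == g).to_numpy()) for g in group_names}
    Zv = Z.to_numpy()

    lam0, _ = select_lambda(Zv, gamma=gamma, n_lambdas=n_lambdas, min_ratio=min_ratio)
    point = {}
    for g in group_names:
        S = np.cov(Zv[idx_by_group[g]], rowvar=False, ddof=1)
        point[g] = centrality(
            precision_to_partial(glasso(S, lam0), nodes=list(Z.columns)), kind=kind
        )

    rng = np.random.default_rng(seed)
    reps = {g: [] for g in group_names}
    failed = 0
    for _ in range(B):
        take = {g: rng.choice(idx, size=len(idx), replace=True)
                for g, idx in idx_by_group.items()}
        pooled = np.vstack([Zv[take[g]] for g in group_names])
        try:
            lam_b, _ = select_lambda(pooled, gamma=gamma,
                                     n_lambdas=n_lambdas, min_ratio=min_ratio)
            this_iter = {}
            for g in group_names:
                S = np.cov(Zv[take[g]], rowvar=False, ddof=1)
                net = precision_to_partial(glasso(S, lam_b), nodes=list(Z.columns))
                this_iter[g] = centrality(net, kind=kind).to_numpy()
        except (GlassoConvergenceError, np.linalg.LinAlgError):
            failed += 1
            continue
        for g in group_names:
            reps[g].append(this_iter[g])
    if failed > max_failure_rate * B:
        raise RuntimeError(f"{failed}/{B} bootstrap iterations failed to fit")

    rows = []
    for g in group_names:
        R = np.asarray(reps[g])
        lo = np.percentile(R, 2.5, axis=0)
        hi = np.percentile(R, 97.5, axis=0)
        for j, node in enumerate(Z.columns):
            rows.append((node, g, wave, point[g].iloc[j], lo[j], hi[j]))
    table = pd.DataFrame(
        rows, columns=["node", "group", "wave", "estimate", "ci_low", "ci_high"]
    )
    return CentralityTable(table, n_bootstrap=B, n_failed=failed,
                           replicates={g: np.asarray(r) for g, r in reps.items()})
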