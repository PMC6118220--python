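"""Synthetic cohort generation with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes: two groups (default sizes 320 on-track, 69 delayed), two waves,
24 variables organized into 12 profile factors, linear age/IQ effects, a
sparse latent partial-correlation structure among the variables' residuals,
and participants drawn from a small number of planted profile communities.
Every quantity the pipeline estimates (networks, factor scores, community
labels) has an analytically known counterpart in the returned truth object,
so recovery and calibration tests need no external data.

Defaults mirror the cohort the pipeline is designed for: group sizes
320/69, delayed participants ~0.6 years older at wave 1 with equal IQ,
wave 2 about 0.89 years later, three planted profile communities
(a regulation-problems profile, a high-risk-taking profile, and a
balanced profile) with group mixing proportions taken from that cohort's
wave-1 profile distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CohortTable
from .schema import VariableSchema, default_schema

# 12-factor prototypes, order: EF Task, Risk Cold, EF Daily, Reg Prob,
# Soc Supp, RPI, Pro Soc, Peer Prob, NFA, Risk Hot, Emo Prob, Emo Reg.
# Problem scales keep their higher-is-worse direction.
DEFAULT_PROTOTYPES = np.array([
    # 1: regulation problems - weak daily EF / emotion regulation, low risk
    [0.0, -1.0, 1.0, 1.0, 0.0, -1.0, 0.0, 0.0, -0.5, -1.0, 0.5, 1.0],
    # 2: high risk-taking - hot and cold risk, need for arousal, low prosocial
    [0.0, 1.0, 0.0, 0.0, 0.0, 0.0, -1.0, 0.0, 1.0, 1.0, 0.0, 0.0],
    # 3: balanced / well-adapted
    [0.0, 0.0, -0.5, -0.5, 0.5, 0.0, 1.0, -0.5, 0.5, 0.0, -0.5, -0.5],
])

DEFAULT_MIXING = {
    "on-track": (0.40, 0.25, 0.35),
    "delayed": (0.33, 0.16, 0.51),
}

# factor loadings of the 24 indicators, by factor
DEFAULT_LOADINGS = {
    "EF Task": (0.7, 0.6, 0.6),
    "EF Daily": (0.8, 0.7, 0.75, 0.7, 0.75, 0.6, 0.7),
    "Reg Prob": (0.75, 0.7),
    "Soc Supp": (0.7, 0.6, 0.55, 0.6),
}
SINGLE_INDICATOR_LOADING = 0.9


@dataclass
class SynthConfig:
    """Full description of one synthetic cohort."""

    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"on-track": 320, "delayed": 69})
    schema: VariableSchema = field(default_factory=default_schema)
    prototypes: np.ndarray = field(default_factory=lambda: DEFAULT_PROTOTYPES.copy())
    mixing: dict[str, tuple] = field(default_factory=lambda: dict(DEFAULT_MIXING))
    separation: float = 2.0          # prototype scale, in factor-SD units
    factor_noise_sd: float = 1.0     # within-community spread of factor scores
    loadings: dict[str, tuple] = field(default_factory=lambda: dict(DEFAULT_LOADINGS))
    single_loading: float = SINGLE_INDICATOR_LOADING
    ggm_edges: int = 30              # planted residual partial-correlation edges
    ggm_weight_range: tuple = (0.2, 0.4)
    age_mean: dict[str, float] = field(
        default_factory=lambda: {"on-track": 13.19, "delayed": 13.81})
    age_sd: dict[str, float] = field(
        default_factory=lambda: {"on-track": 0.72, "delayed": 0.79})
    iq_mean: float = 25.4
    iq_sd: float = 3.6
    wave_gap_years: float = 0.89
    age_slope: float = 0.2           # per-variable effect of (age - mean age)
    iq_slope: float = 0.05           # per-variable effect of (iq - mean iq)
    wave_drift: float = 0.1          # common wave-2 shift of every factor
    wave_noise_sd: float = 0.3       # wave-2 factor innovation
    seed: int = 0

    def __post_init__(self) -> None:
        K = self.prototypes.shape[0]
        if self.prototypes.shape[1] != 12:
            raise ValueError("prototypes must be K x 12")
        for g, mix in self.mixing.items():
            if len(mix) != K:
                raise ValueError(f"mixing for {g!r} must have {K} entries")
            if abs(sum(mix) - 1.0) > 1e-8:
                raise ValueError(f"mixing proportions for {g!r} must sum to 1")


@dataclass
class SynthTruth:
    """Ground truth aligned 1:1 with the generated cohort."""

    community: pd.Series             # planted profile label per participant (0-based)
    precision: np.ndarray            # planted residual precision matrix (24 x 24)
    partials: np.ndarray             # implied residual partial correlations
    loadings: dict[str, np.ndarray]
    prototypes: np.ndarray
    factor_scores: dict[str, pd.DataFrame]   # wave -> planted factor scores
    age_slope: float
    iq_slope: float


def generate_ggm(p: int, n_edges: int, weight_range: tuple = (0.2, 0.4),
                 seed: int = 0, min_eig: float = 0.05, max_tries: int = 200):
    """Random sparse precision matrix with controlled partial correlations.

    The precision matrix has unit diagonal and off-diagonal entries
    -rho_ij, so the implied partial correlations are exactly the planted
    weights.  Candidates whose smallest eigenvalue falls below ``min_eig``
    are rescaled toward the diagonal; draws whose rescaled weights leave
    the requested magnitude range are rejected and redrawn (deterministic
    in the seed).
    """
    max_edges = p * (p - 1) // 2
    if n_edges > max_edges:
        raise ValueError(f"cannot place {n_edges} edges among {max_edges} pairs")
    lo, hi = weight_range
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(p, 1)
    for _ in range(max_tries):
        theta = np.eye(p)
        if n_edges > 0:
            pick = rng.choice(max_edges, size=n_edges, replace=False)
            rho = rng.uniform(lo, hi, size=n_edges) * rng.choice([-1.0, 1.0], size=n_edges)
            rows, cols = iu[0][pick], iu[1][pick]
            theta[rows, cols] = -rho
            theta[cols, rows] = -rho
        w = np.linalg.eigvalsh(theta)
        if w.min() < min_eig:
            scale = (1.0 - min_eig) / (1.0 - w.min())
            off = theta - np.eye(p)
            theta = np.eye(p) + off * scale
            if n_edges > 0 and np.abs(off[rows, cols] * scale).min() < lo:
                continue  # shrank below the requested range; redraw
        partials = -(theta - np.eye(p))
        return theta, partials
    raise ValueError("could not construct a positive-definite precision matrix "
                     "with the requested edge weights; lower n_edges or the weight range")


def _residual_correlation(config: SynthConfig):
    """Correlation matrix of the planted residual GGM."""
    theta, partials = generate_ggm(
        24, config.ggm_edges, config.ggm_weight_range,
        seed=_child(config.seed, 0))
    sigma = np.linalg.inv(theta)
    d = np.sqrt(np.diag(sigma))
    corr = sigma / np.outer(d, d)
    return theta, partials, corr


def _child(seed: int, k: int) -> int:
    return int(np.random.SeedSequence(entropy=seed, spawn_key=(k,))
               .generate_state(1)[0] % (2 ** 31))


def _variable_loadings(config: SynthConfig) -> dict[str, np.ndarray]:
    out = {}
    for factor in config.schema.factors:
        members = config.schema.factor_members(factor)
        if len(members) == 1:
            out[factor] = np.array([config.single_loading])
        else:
            lam = np.asarray(config.loadings[factor], dtype=float)
            if lam.shape[0] != len(members):
                raise ValueError(f"loadings for {factor!r} must have {len(members)} entries")
            out[factor] = lam
    return out


def generate_cohort(config: SynthConfig | None = None):
    """Draw a full two-wave cohort; returns ``(CohortTable, SynthTruth)``."""
    config = config or SynthConfig()
    schema = config.schema
    rng = np.random.default_rng(_child(config.seed, 1))
    theta, partials, resid_corr = _residual_correlation(config)
    resid_chol = np.linalg.cholesky(resid_corr)
    loadings = _variable_loadings(config)

    groups, ids = [], []
    for g, n in config.n_per_group.items():
        groups += [g] * n
        ids += [f"P{len(ids) + i + 1:04d}" for i in range(n)]
    groups = np.array(groups)
    N = len(ids)
    K = config.prototypes.shape[0]

    community = np.empty(N, dtype=int)
    for g in config.n_per_group:
        mask = groups == g
        community[mask] = rng.choice(K, size=mask.sum(), p=np.asarray(config.mixing[g]))

    # covariates: constant across waves except the common age gap
    age_t1 = np.empty(N)
    for g in config.n_per_group:
        mask = groups == g
        age_t1[mask] = rng.normal(config.age_mean[g], config.age_sd[g], mask.sum())
    iq = rng.normal(config.iq_mean, config.iq_sd, N)
    ages = {"T1": age_t1, "T2": age_t1 + config.wave_gap_years}

    proto = config.separation * config.prototypes
    f_t1 = proto[community] + rng.normal(0, config.factor_noise_sd, (N, 12))
    f_t2 = (f_t1 + config.wave_drift
            + rng.normal(0, config.wave_noise_sd, (N, 12)))
    factor_scores = {"T1": f_t1, "T2": f_t2}

    age_ref = float(np.mean(age_t1))
    rows = []
    truth_scores = {}
    for wave in ("T1", "T2"):
        F = factor_scores[wave]
        eps = rng.standard_normal((N, 24)) @ resid_chol.T
        X = np.empty((N, 24))
        col = 0
        for factor in schema.factors:
            members = schema.factor_members(factor)
            lam = loadings[factor]
            for j, _code in enumerate(members):
                resid_sd = np.sqrt(max(1.0 - lam[j] ** 2, 0.0))
                X[:, col] = lam[j] * F[:, schema.factors.index(factor)] \
                    + resid_sd * eps[:, col]
                col += 1
        # columns above follow factor order; map back to schema code order
        ordered_codes = [c for f in schema.factors for c in schema.factor_members(f)]
        df = pd.DataFrame(X, columns=ordered_codes)[schema.codes]
        df += (config.age_slope * (ages[wave] - age_ref)[:, None]
               + config.iq_slope * (iq - config.iq_mean)[:, None])
        df.insert(0, "iq", iq)
        df.insert(0, "age", ages[wave])
        df.insert(0, "wave", wave)
        df.insert(0, "group", groups)
        df.insert(0, "participant_id", ids)
        rows.append(df)
        truth_scores[wave] = pd.DataFrame(F, index=pd.Index(ids, name="participant_id"),
                                          columns=schema.factors)

    cohort = CohortTable(pd.concat(rows, ignore_index=True), schema)
    truth = SynthTruth(
        community=pd.Series(community, index=pd.Index(ids, name="participant_id"),
                            name="community"),
        precision=theta, partials=partials, loadings=loadings,
        prototypes=proto, factor_scores=truth_scores,
        age_slope=config.age_slope, iq_slope=config.iq_slope,
    )
    return cohort, truth


def sample_from_ggm(theta: np.ndarray, n: int, seed: int = 0) -> np.ndarray:
    """Draw n observations from the zero-mean Gaussian implied by a precision."""
    sigma = np.linalg.inv(theta)
    rng = np.random.default_rng(seed)
    return rng.multivariate_normal(np.zeros(theta.shape[0]), sigma, size=n,
                                   method="cholesky")


def generate_anova_fixture(n_per_group: dict[str, int] | None = None,
                           variable: str = "EFSW",
                           group_effect: float = 0.0, time_effect: float = 0.0,
                           interaction: float = 0.0, noise_sd: float = 1.0,
                           seed: int = 0,
                           schema: VariableSchema | None = None) -> CohortTable:
    """Two-group, two-wave cohort with specified cell means on one variable.

    The target variable's cell mean is
    ``group_effect * g + time_effect * t + interaction * g * t`` with
    g, t in {0, 1}; participant-level noise is iid Gaussian per cell.
    All other variables are iid standard normal, covariates carry no effect.
    """
    schema = schema or default_schema()
    n_per_group = n_per_group or {"on-track": 100, "delayed": 100}
    rng = np.random.default_rng(seed)
    groups, ids = [], []
    for g, n in n_per_group.items():
        groups += [g] * n
        ids += [f"A{len(ids) + i + 1:04d}" for i in range(n)]
    groups = np.array(groups)
    N = len(ids)
    g_ind = (groups == "delayed").astype(float)

    rows = []
    for t, wave in enumerate(("T1", "T2")):
        X = rng.standard_normal((N, 24)) * noise_sd
        df = pd.DataFrame(X, columns=schema.codes)
        df[variable] += (group_effect * g_ind + time_effect * t
                         + interaction * g_ind * t)
        df.insert(0, "iq", rng.normal(25, 3.5, N))
        df.insert(0, "age", rng.normal(13.3 + 0.9 * t, 0.7, N))
        df.insert(0, "wave", wave)
        df.insert(0, "group", groups)
        df.insert(0, "participant_id", ids)
        rows.append(df)
    return CohortTable(pd.concat(rows, ignore_index=True), schema)
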