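"""Participant subtyping by community detection on profile similarity.

Each participant's 12-factor profile is correlated with every other
participant's profile; the resulting similarity matrix, with negative
entries handled by a configurable policy (truncation to zero by default),
is treated as a weighted graph.  Louvain modularity maximization with
multiple seeded restarts partitions participants into profile communities,
and the observed modularity Q is compared against a permutation null in
which every factor column is shuffled independently across participants
(destroying within-person profile coherence while preserving marginals).

Louvain is implemented here directly — seeded node visit order, standard
two-phase local moving + aggregation, with modularity guaranteed
non-decreasing across passes — because the partition, its tie-breaking and
its reproducibility are the quantity under test, not a convenience.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

_Q_TOL = 1e-12


@dataclass
class CommunityPartition:
    assignment: np.ndarray    # community id per participant, 0-based, size-ranked
    Q: float
    n_communities: int
    participants: list | None = None

    def as_series(self) -> pd.Series:
        idx = self.participants if self.participants is not None else range(len(self.assignment))
        return pd.Series(self.assignment, index=idx, name="community")


@dataclass
class NullDistribution:
    q_null: np.ndarray
    q_observed: float
    z_observed: float

    @property
    def mean(self) -> float:
        return float(self.q_null.mean())

    @property
    def sd(self) -> float:
        return float(self.q_null.std(ddof=1))


def profile_correlations(scores: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation between every pair of participants' profiles.

    Rows are participants, columns are factors.  The diagonal is stored as
    zero for the graph-adjacency view.
    """
    X = np.asarray(scores, dtype=np.float64)
    if X.shape[1] < 3:
        raise ValueError("profiles need at least 3 factors for a meaningful correlation")
    sd = X.std(axis=1)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        ids = [scores.index[i] for i in flat]
        raise ValueError(f"constant (zero-variance) profiles for participants: {ids[:10]}")
    R = np.corrcoef(X)
    np.fill_diagonal(R, 0.0)
    return pd.DataFrame(R, index=scores.index, columns=scores.index)


def to_adjacency(sim: pd.DataFrame | np.ndarray, policy: str = "truncate") -> np.ndarray:
    """Nonnegative weighted adjacency from a profile-similarity matrix.

    Policies for negative correlations: ``truncate`` (set to 0, default),
    ``absolute`` (|r|), ``shift`` (linear map (r+1)/2).
    """
    A = np.asarray(sim, dtype=np.float64).copy()
    if policy == "truncate":
        A[A < 0] = 0.0
    elif policy == "absolute":
        A = np.abs(A)
    elif policy == "shift":
        A = (A + 1.0) / 2.0
    else:
        raise ValueError(f"unknown negative-weight policy {policy!r}")
    np.fill_diagonal(A, 0.0)
    return A


def modularity(A: np.ndarray, assignment: np.ndarray) -> float:
    """Weighted Newman modularity of a partition.

    Q = (1/2m) sum_ij [A_ij - k_i k_j / 2m] delta(c_i, c_j).
    """
    A = np.asarray(A, dtype=np.float64)
    assignment = np.asarray(assignment)
    if A.shape[0] != assignment.shape[0]:
        raise ValueError("partition does not cover all nodes")
    k = A.sum(axis=1)
    m2 = k.sum()
    if m2 <= 0:
        raise ValueError("graph has no edge weight; modularity undefined")
    _, labels = np.unique(assignment, return_inverse=True)
    within = float((A * (labels[:, None] == labels[None, :])).sum())
    sigma_tot = np.bincount(labels, weights=k)
    return float(within / m2 - ((sigma_tot / m2) ** 2).sum())


def _sweep_py(A, labels, k, sigma_tot, self_w, m2, order):
    """One local-moving sweep; returns the number of moves made."""
    n_moves = 0
    for i in order:
        ci = labels[i]
        w = np.bincount(labels, weights=A[i], minlength=A.shape[0])
        w[ci] -= self_w[i]
        sigma_tot[ci] -= k[i]
        # gain (x 2m) of joining community c: w_c - k_i * sigma_c / 2m
        gains = w - k[i] * sigma_tot / m2
        best = int(np.argmax(gains))
        if gains[best] <= gains[ci] + _Q_TOL:
            best = ci
        labels[i] = best
        sigma_tot[best] += k[i]
        if best != ci:
            n_moves += 1
    return n_moves


try:  # compiled sweep: the permutation null runs Louvain tens of thousands of times
    from numba import njit

    @njit(cache=True)
    def _sweep_nb(A, labels, k, sigma_tot, self_w, m2, order):  # pragma: no cover
        n = A.shape[0]
        n_moves = 0
        for idx in range(order.shape[0]):
            i = order[idx]
            ci = labels[i]
            w = np.zeros(n)
            for j in range(n):
                w[labels[j]] += A[i, j]
            w[ci] -= self_w[i]
            sigma_tot[ci] -= k[i]
            best = ci
            best_gain = w[ci] - k[i] * sigma_tot[ci] / m2
            for c in range(n):
                g = w[c] - k[i] * sigma_tot[c] / m2
                if g > best_gain + 1e-12:
                    best = c
                    best_gain = g
            labels[i] = best
            sigma_tot[best] += k[i]
            if best != ci:
                n_moves += 1
        return n_moves

    _sweep = _sweep_nb
except ImportError:  # pragma: no cover
    _sweep = _sweep_py


def _local_move(A: np.ndarray, rng: np.random.Generator,
                init: np.ndarray | None = None) -> np.ndarray:
    """Phase 1: greedy node moves to the neighboring community with max gain."""
    n = A.shape[0]
    labels = np.arange(n) if init is None else init.astype(np.int64).copy()
    k = A.sum(axis=1)
    m2 = k.sum()
    sigma_tot = np.bincount(labels, weights=k, minlength=n)
    self_w = np.ascontiguousarray(np.diag(A))
    while True:
        order = rng.permutation(n)
        if _sweep(A, labels, k, sigma_tot, self_w, m2, order) == 0:
            break
    return labels


def _aggregate(A: np.ndarray, labels: np.ndarray) -> np.ndarray:
    _, compact = np.unique(labels, return_inverse=True)
    nc = compact.max() + 1
    M = np.zeros((A.shape[0], nc))
    M[np.arange(A.shape[0]), compact] = 1.0
    return M.T @ A @ M


def _canonical(labels: np.ndarray) -> np.ndarray:
    """Renumber communities by descending size (first appearance breaks ties)."""
    ids, inv, counts = np.unique(labels, return_inverse=True, return_counts=True)
    first = np.full(len(ids), len(labels))
    for pos, c in enumerate(inv):
        first[c] = min(first[c], pos)
    order = sorted(range(len(ids)), key=lambda c: (-counts[c], first[c]))
    rank = np.empty(len(ids), dtype=int)
    for new, old in enumerate(order):
        rank[old] = new
    return rank[inv]


def louvain(A: np.ndarray, seed: int = 0, participants: list | None = None,
            init: str = "singletons") -> CommunityPartition:
    """Two-phase Louvain modularity maximization with seeded visit order.

    ``init`` selects the starting partition of the first local-moving
    phase: ``"singletons"`` (the classic start, every node alone) or
    ``"random"`` (a seeded random assignment).  Random starts reach local
    optima the greedy singleton start cannot, so the multi-restart driver
    mixes both.  Modularity is non-decreasing across passes either way.
    """
    A = np.asarray(A, dtype=np.float64)
    if np.any(A < 0):
        raise ValueError("Louvain requires nonnegative weights; apply to_adjacency first")
    if init not in ("singletons", "random"):
        raise ValueError(f"unknown init {init!r}")
    rng = np.random.default_rng(seed)
    n = A.shape[0]
    flat = np.arange(n)          # original node -> current aggregated community
    first_init = rng.integers(0, n, n) if init == "random" else None
    A_cur = A
    q_prev = modularity(A, flat if first_init is None else first_init)
    first_pass = True
    while True:
        local = _local_move(A_cur, rng, init=first_init if first_pass else None)
        first_pass = False
        _, compact = np.unique(local, return_inverse=True)
        flat = compact[flat]
        q_new = modularity(A, flat)
        assert q_new >= q_prev - 1e-9, "modularity decreased across a pass"
        if compact.max() + 1 == A_cur.shape[0] or q_new <= q_prev + _Q_TOL:
            q_prev = q_new
            break
        A_cur = _aggregate(A_cur, compact)
        q_prev = q_new
    labels = _canonical(flat)
    return CommunityPartition(labels, modularity(A, labels), int(labels.max() + 1),
                              participants)


def multi_restart_louvain(A: np.ndarray, restarts: int = 200, seed: int = 0,
                          participants: list | None = None) -> CommunityPartition:
    """Best-of-restarts Louvain: highest Q, ties broken toward fewer
    communities, then the lexicographically smallest canonical assignment.

    The first restart uses the classic singleton start; later restarts use
    seeded random initial partitions, which diversifies the local optima
    explored.
    """
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    best = None
    for r in range(restarts):
        part = louvain(A, seed=_child_seed(seed, r), participants=participants,
                       init="singletons" if r == 0 else "random")
        if best is None:
            best = part
            continue
        if part.Q > best.Q + _Q_TOL:
            best = part
        elif abs(part.Q - best.Q) <= _Q_TOL:
            key_new = (part.n_communities, tuple(part.assignment))
            key_old = (best.n_communities, tuple(best.assignment))
            if key_new < key_old:
                best = part
    return best


def _child_seed(seed: int, counter: int) -> int:
    return int(np.random.SeedSequence(entropy=seed, spawn_key=(counter,))
               .generate_state(1)[0] % (2 ** 31))


def null_distribution(scores: pd.DataFrame, q_observed: float,
                      permutations: int = 200, restarts: int = 200,
                      seed: int = 0, policy: str = "truncate") -> NullDistribution:
    """Permutation null for modularity.

    Each permutation shuffles every factor column independently across
    participants, then reruns the full similarity -> adjacency -> Louvain
    pipeline with the same restart effort as the observed analysis.
    z = (Q_obs - mean(Q_null)) / sd(Q_null).
    """
    if permutations < 2:
        raise ValueError("need at least 2 permutations for a null sd")
    if permutations < 20:
        warnings.warn("fewer than 20 permutations gives an unstable null sd")
    X = np.asarray(scores, dtype=np.float64)
    q_null = np.empty(permutations)
    for b in range(permutations):
        rng = np.random.default_rng(_child_seed(seed, 10_000 + b))
        Xp = np.column_stack([rng.permutation(X[:, j]) for j in range(X.shape[1])])
        sim = profile_correlations(pd.DataFrame(Xp))
        A = to_adjacency(sim, policy=policy)
        q_null[b] = multi_restart_louvain(A, restarts=restarts,
                                          seed=_child_seed(seed, 20_000 + b)).Q
    sd = q_null.std(ddof=1)
    if sd == 0:
        raise ValueError("null distribution has zero spread; z undefined")
    z = (q_observed - q_null.mean()) / sd
    return NullDistribution(q_null, float(q_observed), float(z))


def summarize_profiles(partition: CommunityPartition, scores: pd.DataFrame,
                       groups: pd.Series) -> dict[str, pd.DataFrame]:
    """Per-community mean profiles and per-group membership percentages."""
    if len(partition.assignment) != len(scores):
        raise ValueError("partition and scores cover different participants")
    labels = pd.Series(partition.assignment, index=scores.index, name="community")
    means = scores.groupby(labels).mean()
    empty = [c for c in range(partition.n_communities) if c not in means.index]
    if empty:
        warnings.warn(f"empty communities excluded from summary: {empty}")
    groups = groups.loc[scores.index]
    counts = pd.crosstab(labels, groups)
    proportions = counts / counts.sum(axis=0) * 100.0
    return {"means": means, "proportions": proportions}
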