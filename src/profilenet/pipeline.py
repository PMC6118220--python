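"""End-to-end orchestration: ANOVA, networks, factors and communities.

One call runs the full analysis a study of this design reports, per wave:
covariate residualization, pooled EBIC penalty selection, per-group network
estimation with centrality (optionally bootstrapped), factor scoring,
community detection with the permutation-null z statistic, and profile
summaries.  All randomness descends from a single master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .anova import anova_table
from .cohort import CohortTable
from .communities import (CommunityPartition, NullDistribution,
                          multi_restart_louvain, null_distribution,
                          profile_correlations, summarize_profiles, to_adjacency)
from .factors import FactorScores, fit_and_score
from .network import (CentralityTable, NetworkModel, bootstrap_centrality,
                      centrality, estimate_group_networks, select_lambda)
from .preprocess import residualize, standardize


@dataclass
class WaveResult:
    wave: str
    lambda_selected: float
    networks: dict[str, NetworkModel]
    centralities: pd.DataFrame
    bootstrap: CentralityTable | None
    factor_scores: FactorScores
    partition: CommunityPartition
    null: NullDistribution
    summary: dict[str, pd.DataFrame]


@dataclass
class PipelineResult:
    anova: pd.DataFrame
    waves: dict[str, WaveResult] = field(default_factory=dict)


def run_pipeline(cohort: CohortTable, seed: int = 0, gamma: float = 0.5,
                 n_lambdas: int = 100, bootstrap: int = 0,
                 restarts: int = 200, permutations: int = 200,
                 neg_policy: str = "truncate") -> PipelineResult:
    """Run every analysis stage on a validated cohort.

    ``bootstrap=0`` skips centrality confidence intervals (the slowest
    stage); restarts and permutations control the community analysis
    effort per wave.
    """
    result = PipelineResult(anova=anova_table(cohort))
    for w_i, wave in enumerate(("T1", "T2")):
        Z = standardize(residualize(cohort, wave))
        lam, _ = select_lambda(Z, gamma=gamma, n_lambdas=n_lambdas)
        networks = estimate_group_networks(cohort, wave, lam, gamma=gamma)
        cents = pd.DataFrame({g: centrality(net) for g, net in networks.items()})
        boot = None
        if bootstrap > 0:
            boot = bootstrap_centrality(cohort, wave, B=bootstrap, gamma=gamma,
                                        seed=seed * 4 + w_i, n_lambdas=n_lambdas)

        scores = fit_and_score(Z, cohort.schema, wave=wave)
        sim = profile_correlations(scores.scores)
        A = to_adjacency(sim, policy=neg_policy)
        partition = multi_restart_louvain(A, restarts=restarts,
                                          seed=seed * 4 + 2 + w_i,
                                          participants=list(scores.scores.index))
        null = null_distribution(scores.scores, partition.Q,
                                 permutations=permutations, restarts=restarts,
                                 seed=seed * 4 + 2 + w_i, policy=neg_policy)
        summary = summarize_profiles(partition, scores.scores, cohort.groups(wave))
        result.waves[wave] = WaveResult(
            wave=wave, lambda_selected=lam, networks=networks,
            centralities=cents, bootstrap=boot, factor_scores=scores,
            partition=partition, null=null, summary=summary,
        )
    return result
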