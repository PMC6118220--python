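"""Mixed-design ANOVA: Time Point (within) x Group (between), per variable.

With exactly two time points, the Group x Time interaction F of the
classical mixed ANOVA is identical to the one-way between-group F on the
per-participant wave-2 minus wave-1 difference scores, with degrees of
freedom (1, N - 2).  That reduction is used here; it is exact, not an
approximation.

Covariates are handled by running the test on age/IQ-residualized
variables (the shared adjustment pathway of the preprocessing step);
``adjust=False`` reproduces the raw analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortTable
from .preprocess import residualize


@dataclass
class AnovaResult:
    variable: str
    F: float
    df_num: int
    df_den: int
    p: float
    cell_means: pd.DataFrame      # group x wave means
    cell_sds: pd.DataFrame


def mixed_anova(cohort: CohortTable, variable: str, adjust: bool = True) -> AnovaResult:
    """Group x Time interaction test for one variable.

    Returns the interaction F with df (1, N-2), its p-value, and the raw
    per-group per-wave means and standard deviations.
    """
    if variable not in cohort.schema.codes:
        raise KeyError(f"unknown variable {variable!r}")
    groups = cohort.groups()
    counts = groups.value_counts()
    if (counts < 2).any() or len(counts) != 2:
        raise ValueError("mixed ANOVA needs two groups with >= 2 participants each")

    per_wave = {}
    for wave in ("T1", "T2"):
        if adjust:
            per_wave[wave] = residualize(cohort, wave).residuals[variable]
        else:
            per_wave[wave] = cohort.values(wave)[variable]
    diff = per_wave["T2"] - per_wave["T1"]

    g1, g2 = sorted(counts.index)
    d1 = diff[groups == g1].to_numpy()
    d2 = diff[groups == g2].to_numpy()
    F, p = stats.f_oneway(d1, d2)
    n = len(diff)

    raw = {w: cohort.values(w)[variable] for w in ("T1", "T2")}
    means = pd.DataFrame({w: raw[w].groupby(groups).mean() for w in raw})
    sds = pd.DataFrame({w: raw[w].groupby(groups).std(ddof=1) for w in raw})
    return AnovaResult(variable, float(F), 1, n - 2, float(p), means, sds)


def anova_table(cohort: CohortTable, adjust: bool = True) -> pd.DataFrame:
    """Interaction F and p for every variable, with cell means and SDs.

    Mirrors a per-variable report: one row per measure, per-group per-wave
    mean (SD), then the Group x Time interaction statistic.
    """
    rows = []
    for code in cohort.schema.codes:
        r = mixed_anova(cohort, code, adjust=adjust)
        row = {"variable": code, "domain": cohort.schema.domain_of(code)}
        for g in r.cell_means.index:
            for w in r.cell_means.columns:
                row[f"{g}_{w}_mean"] = r.cell_means.loc[g, w]
                row[f"{g}_{w}_sd"] = r.cell_sds.loc[g, w]
        row["F"] = r.F
        row["p"] = r.p
        rows.append(row)
    return pd.DataFrame(rows)
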