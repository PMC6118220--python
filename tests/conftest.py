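import numpy as np
import pandas as pd
import pytest

import profilenet as pn


@pytest.fixture(scope="session")
def schema():
    return pn.default_schema()


@pytest.fixture(scope="session")
def small_config():
    # small cohort keeps per-test runtime down; structure identical to default
    return pn.SynthConfig(n_per_group={"on-track": 80, "delayed": 30}, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    cohort, truth = pn.generate_cohort(small_config)
    return cohort, truth


@pytest.fixture(scope="session")
def default_cohort():
    cohort, truth = pn.generate_cohort(pn.SynthConfig(seed=11))
    return cohort, truth


@pytest.fixture()
def tiny_frame(schema):
    """Minimal valid 2-participant x 2-wave cohort frame."""
    rng = np.random.default_rng(0)
    rows = []
    for pid, grp in (("p1", "on-track"), ("p2", "delayed")):
        for wave in ("T1", "T2"):
            row = {"participant_id": pid, "group": grp, "wave": wave,
                   "age": 13.0, "iq": 25.0}
            row.update({c: float(v) for c, v in
                        zip(schema.codes, rng.standard_normal(24))})
            rows.append(row)
    return pd.DataFrame(rows)
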