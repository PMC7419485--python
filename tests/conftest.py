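import numpy as np
import pandas as pd
import pytest

import dyadvar as dv

VARS4 = ["Crawl", "Babble", "Rocks/Jiggles", "Points to Object"]


@pytest.fixture
def small_events() -> pd.DataFrame:
    """Hand-written event log: one dyad, two months, two sessions each."""
    rows = [
        # dyad, group, month, session, code, duration_s, occurrences
        ("d1", "boy", 5, 1, "Reach", 30.0, 2),
        ("d1", "boy", 5, 2, "Reach", 15.0, 1),
        ("d1", "boy", 5, 1, "Crawl", 10.0, 1),
        ("d1", "boy", 6, 1, "Reach", 5.0, 1),
        ("d1", "boy", 6, 2, "Crawl", 20.0, 3),
    ]
    return pd.DataFrame(
        rows,
        columns=["dyad_id", "group", "month", "session", "code", "duration_s", "occurrences"],
    )


@pytest.fixture
def cohort4():
    """Gaussian-latent cohort with known 4-variable lag-1 coupling."""
    a = 0.3 * np.eye(4)
    a[0, 1] = 0.2
    a[2, 3] = -0.15
    cfg = dv.GeneratorConfig(
        n_dyads_per_group=10,
        months=range(0, 30),
        variables=VARS4,
        coupling_by_group={"boy": a, "girl": a},
        seed=11,
    )
    return cfg, dv.generate_cohort(cfg)


@pytest.fixture
def model4(cohort4):
    _, panel = cohort4
    return dv.fit_var(panel, 1), panel
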