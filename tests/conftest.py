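"""Shared fixtures: one seeded synthetic study reused across the suite."""

import numpy as np
import pandas as pd
import pytest

from subtypekit.centroids import compute_centroids
from subtypekit.preprocess import median_center
from subtypekit.synthetic_cohort import (
    SyntheticCohortConfig,
    generate_mixed_cohort,
    generate_reference_panel,
)


@pytest.fixture(scope="session")
def default_config():
    return SyntheticCohortConfig(seed=1)


@pytest.fixture(scope="session")
def panel(default_config):
    return generate_reference_panel(default_config)


@pytest.fixture(scope="session")
def intrinsic_genes(panel):
    return [g for g in panel.expression.gene_symbols
            if not g.startswith(("BGG", "HKG"))]


@pytest.fixture(scope="session")
def housekeeping_genes(panel):
    return [g for g in panel.expression.gene_symbols if g.startswith("HKG")]


@pytest.fixture(scope="session")
def reference_centroids(panel, intrinsic_genes):
    return compute_centroids(median_center(panel.expression),
                             panel.true_subtype, intrinsic_genes)


@pytest.fixture(scope="session")
def mixed(default_config, reference_centroids):
    return generate_mixed_cohort(default_config, reference_centroids)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_survival_frame(times, events, group, endpoint="DFS", prefix="p"):
    return pd.DataFrame({
        "sample_id": [f"{prefix}{group}{i}" for i in range(len(times))],
        "time": times,
        "event": events,
        "endpoint": endpoint,
        "subtype": group,
    })
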