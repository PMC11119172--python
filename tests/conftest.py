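import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import proteostrat as ps

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def planted_matrix(n_clusters: int, n_per: int, n_proteins: int = 120,
                   shift: float = 3.0, seed: int = 0,
                   block: int = 24) -> tuple[ps.QuantMatrix, np.ndarray]:
    """log2-scale matrix with K well-separated sample clusters.

    Each cluster elevates its own disjoint block of proteins by ``shift``
    log2 units over N(20, 1) noise, so cluster centres are mutually
    distant in disjoint directions.
    """
    rng = np.random.default_rng(seed)
    X = rng.normal(20.0, 1.0, size=(n_proteins, n_clusters * n_per))
    for c in range(n_clusters):
        X[c * block:(c + 1) * block, c * n_per:(c + 1) * n_per] += shift
    m = ps.QuantMatrix(
        pd.DataFrame(X, index=[f"P{i:03d}" for i in range(n_proteins)],
                     columns=[f"s{i:02d}" for i in range(n_clusters * n_per)]),
        scale="log2",
    )
    truth = np.repeat(np.arange(n_clusters), n_per)
    return m, truth


@pytest.fixture
def two_cloud_matrix() -> tuple[ps.QuantMatrix, np.ndarray]:
    return planted_matrix(2, n_per=8, n_proteins=40, shift=50.0, seed=3, block=20)


@pytest.fixture
def study_cohort():
    """Study-shaped cohort with a strong exacerbation effect."""
    spec = ps.CohortSpec(
        n_per_group={"CONTROL": 10, "SCOPD": 24, "AECOPD": 10},
        n_proteins=200, n_affected=40, effect_log2fc=2.0, seed=42,
    )
    return ps.generate_cohort(spec)


@pytest.fixture
def exacerbation_table4():
    """Cluster/group layout matching the published exacerbation confrontation."""
    labels = pd.Series(["A"] * 13 + ["B"] * 21,
                       index=[f"s{i}" for i in range(34)])
    groups = ["SCOPD"] * 5 + ["AECOPD"] * 8 + ["SCOPD"] * 19 + ["AECOPD"] * 2
    ann = ps.SampleAnnotation(pd.DataFrame({"group": groups}, index=labels.index))
    return labels, ann


@pytest.fixture
def diagnosis_table2():
    """Cluster/group layout matching the published diagnosis confrontation."""
    labels = pd.Series(["A"] * 24 + ["B"] * 10,
                       index=[f"s{i}" for i in range(34)])
    groups = ["CONTROL"] * 8 + ["SCOPD"] * 16 + ["CONTROL"] * 2 + ["SCOPD"] * 8
    ann = ps.SampleAnnotation(pd.DataFrame({"group": groups}, index=labels.index))
    return labels, ann
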