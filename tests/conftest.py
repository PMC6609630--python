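import numpy as np
import pandas as pd
import pytest

from dmetpk import (
    DrugParams,
    Physiology,
    ProteinAbundanceRecord,
    StudyObservation,
    StudySet,
    data_path,
    load_drug,
    load_enzyme_table,
    load_physiology,
)


@pytest.fixture
def two_study_set() -> StudySet:
    """Hand-checkable two-study set: X={10,20}, SD={1,2}, n={3,1}.

    Known values: w={1,0.25}, mu_F=12, Q_F=20, tau2=47.5, mu_R=14.850,
    Q_R=1.000, WM=12.5, nu=18.75, cv_I=34.641%, cv_III=10%.
    """
    return StudySet(protein="TEST1", tissue="liver", observations=[
        StudyObservation(label="A, 2001", mean=10.0, sd=1.0, n=3, source="A"),
        StudyObservation(label="B, 2002", mean=20.0, sd=2.0, n=1, source="B"),
    ])


@pytest.fixture
def zero_sd_study_set() -> StudySet:
    """Same means/n but SD=0 everywhere: methods I and II must coincide."""
    return StudySet(protein="TEST0", tissue="liver", observations=[
        StudyObservation(label="A, 2001", mean=10.0, sd=0.0, n=3, source="A"),
        StudyObservation(label="B, 2002", mean=20.0, sd=0.0, n=1, source="B"),
    ])


@pytest.fixture(scope="session")
def lamotrigine() -> DrugParams:
    return load_drug(data_path("lamotrigine.yaml"))


@pytest.fixture(scope="session")
def adult_physiology() -> Physiology:
    return load_physiology(data_path("adult.yaml"))


@pytest.fixture(scope="session")
def lamotrigine_enzymes():
    return load_enzyme_table(data_path("lamotrigine_enzymes.csv"))


@pytest.fixture(scope="session")
def published_heterogeneity() -> pd.DataFrame:
    return pd.read_csv(data_path("liver_noncyp_heterogeneity.csv"), comment="#")


@pytest.fixture(scope="session")
def published_pooled() -> pd.DataFrame:
    return pd.read_csv(data_path("liver_noncyp_pooled.csv"), comment="#")


def make_records(n: int = 6, protein: str = "UGT9Z9") -> list[ProteinAbundanceRecord]:
    """Small deterministic eligible record list spread over two sources."""
    rng = np.random.default_rng(7)
    out = []
    for i in range(n):
        mean = float(30 + 5 * i)
        out.append(ProteinAbundanceRecord(
            protein_name=protein, gene_name=protein, tissue="liver",
            value=mean, value_sd=float(rng.uniform(2, 6)),
            n_donors=int(rng.integers(4, 20)),
            source=f"Lab{i % 2 + 1}", year=2010 + i,
        ))
    return out
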