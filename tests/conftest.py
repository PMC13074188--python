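import dataclasses

import numpy as np
import pytest
from scipy.special import logit

from hbpmeta.io_model import StudyDataset, StudyRecord
from hbpmeta.synthetic import published_corpus_config, simulate_dataset, simulate_from_bivariate


@pytest.fixture(scope="session")
def emulated_corpus_sim():
    """One 12-study corpus-emulating simulated dataset (fixed seed)."""
    return simulate_dataset(published_corpus_config(seed=7))


@pytest.fixture(scope="session")
def six_study_dataset():
    """Fixed 6-study dataset from the bivariate generator (seed 1)."""
    mu = [logit(0.86), logit(0.15)]
    S = np.array([[0.36, 0.3 * 0.36], [0.3 * 0.36, 0.36]])
    return simulate_from_bivariate(mu, S, k=6, seed=1)


@pytest.fixture()
def toy_dataset():
    """Three hand-written studies, one with a zero cell."""
    return StudyDataset(
        records=(
            StudyRecord("a", tp=90, fp=15, fn=10, tn=85, cutoff=25.0),
            StudyRecord("b", tp=50, fp=0, fn=5, tn=45, cutoff=40.0),
            StudyRecord("c", tp=70, fp=20, fn=30, tn=80, cutoff=60.0),
        ),
        provenance="toy",
    )


def with_covariate(dataset: StudyDataset, name: str, labels) -> StudyDataset:
    records = tuple(
        dataclasses.replace(r, covariates={**r.covariates, name: lab})
        for r, lab in zip(dataset.records, labels)
    )
    return StudyDataset(records=records, provenance=dataset.provenance)
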