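import numpy as np
import pandas as pd
import pytest

from streamrisk import (
    CaseControlDataset,
    GenotypeVector,
    RateTable,
    SnpDescriptor,
    SnpPanel,
)


@pytest.fixture
def single_snp_panel() -> SnpPanel:
    """One SNP with OR = 2, p = 0.5, hence mu = 2.25."""
    return SnpPanel(
        snps=(SnpDescriptor("rs0000001", "A", 2.0, 0.5, other_allele="G"),),
        ethnicity_label="caucasian",
    )


@pytest.fixture
def identity_panel() -> SnpPanel:
    """Three SNPs all with OR = 1: every genotype has adjusted risk 1."""
    return SnpPanel(
        snps=tuple(
            SnpDescriptor(f"rs000000{i}", "C", 1.0, 0.3) for i in (1, 2, 3)
        ),
        ethnicity_label="caucasian",
    )


@pytest.fixture
def flat_table() -> RateTable:
    """Constant annual hazard 0.01, no competing mortality."""
    return RateTable.constant(0.01, ethnicity_label="caucasian")


@pytest.fixture
def toy_cohort() -> CaseControlDataset:
    """A fixed 12-subject case-control set with overlapping scores."""
    frame = pd.DataFrame(
        {
            "subject_id": [f"t{i:02d}" for i in range(1, 13)],
            "status": [1, 1, 1, 1, 1, 0, 0, 0, 0, 0, 0, 0],
            "age": [52, 61, 47, 58, 66, 50, 44, 63, 55, 70, 49, 57],
            "risk": [2.1, 1.3, 3.2, 0.9, 1.8, 1.1, 0.7, 2.0, 1.5, 0.6, 1.2, 0.8],
        }
    )
    return CaseControlDataset(frame)


def random_cohort(rng: np.random.Generator, n: int, tie_fraction: float = 0.0):
    """Small random cohort builder for oracle comparisons."""
    status = rng.integers(0, 2, size=n)
    if status.sum() == 0:
        status[0] = 1
    if status.sum() == n:
        status[0] = 0
    scores = rng.lognormal(0.0, 0.6, size=n)
    if tie_fraction:
        quantized = np.round(scores, 1)
        pick = rng.random(n) < tie_fraction
        scores = np.where(pick, quantized, scores)
    frame = pd.DataFrame(
        {
            "subject_id": [f"r{i}" for i in range(n)],
            "status": status,
            "age": rng.integers(40, 75, size=n),
            "score": scores,
        }
    )
    return CaseControlDataset(frame)


@pytest.fixture
def genotype_factory():
    def make(subject_id: str, **counts):
        return GenotypeVector(subject_id=subject_id, counts=counts)

    return make
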