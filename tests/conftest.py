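import numpy as np
import pandas as pd
import pytest

from crpsig import (
    ClinicalTable,
    CohortConfig,
    ProteinMatrix,
    derive_outcome,
    generate_cohort,
)


def make_clinical(crp_index, crp_next, **overrides) -> ClinicalTable:
    """Minimal valid clinical table for n patients."""
    n = len(crp_index)
    base = {
        "crp_index": crp_index,
        "crp_next": crp_next,
        "donor_age": [50.0] * n,
        "donor_sex": ["male"] * n,
        "donor_status": ["living"] * n,
        "recipient_age": [51.0] * n,
        "recipient_sex": ["female"] * n,
        "dialysis_months": [12.0] * n,
        "methylprednisolone": [0] * n,
        "hospitalization_days": [7.0] * n,
        "hla_mismatches": [3] * n,
    }
    base.update(overrides)
    return ClinicalTable(
        pd.DataFrame(base, index=pd.Index([f"P{i:03d}" for i in range(n)], name="patient_id"))
    )


def make_outcome(delta: np.ndarray):
    """Outcome vector with the requested CRP changes."""
    crp_index = np.full(len(delta), 50.0) - np.minimum(delta, 0)
    return derive_outcome(make_clinical(crp_index, crp_index + np.asarray(delta, dtype=float)))


def separable_cohort(n: int = 40, n_proteins: int = 8, seed: int = 11):
    """Cohort whose first protein is an exact monotone image of delta-CRP,
    with delta well separated from 0 so classification is unambiguous."""
    rng = np.random.default_rng(seed)
    delta = np.where(rng.random(n) < 0.6, 1.0, -1.0) * rng.uniform(30, 90, n)
    ratios = np.exp(0.25 * rng.standard_normal((n, n_proteins)))
    ratios[:, 0] = np.exp(delta / 60.0)
    ids = [f"P{i:03d}" for i in range(n)]
    matrix = ProteinMatrix(
        pd.DataFrame(ratios, index=ids, columns=[f"PROT_{j:02d}" for j in range(n_proteins)])
    )
    return matrix, make_outcome(delta)


@pytest.fixture(scope="session")
def default_cohort():
    """Default-scale synthetic cohort (91 patients, 359 proteins)."""
    return generate_cohort(CohortConfig(seed=1))


@pytest.fixture(scope="session")
def small_cohort():
    """Small informative cohort for fast pipeline tests."""
    return generate_cohort(
        CohortConfig(n_patients=40, n_proteins=30, n_informative=12, n_modules=4, seed=5)
    )
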