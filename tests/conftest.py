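import numpy as np
import pandas as pd
import pytest

from modquilt.dataio import ExpressionMatrix, GenotypeMatrix, PhenotypeTable
from modquilt.synthdata import SimulationParams, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 59-sample template cohort with planted module and mQTLs."""
    params = SimulationParams(n_samples=59, n_probes=200, module_size=40,
                              n_snps=60, seed=11)
    return simulate_cohort(params)


@pytest.fixture(scope="session")
def recovery_cohort():
    """The planted-signal cohort used for parameter-recovery checks."""
    params = SimulationParams(n_samples=200, n_probes=1000, module_size=100,
                              n_snps=50, genotype_missing_rate=0.0, seed=3)
    return simulate_cohort(params)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def make_expression(values, probe_ids=None, sample_ids=None, meta=None):
    values = np.asarray(values, dtype=float)
    probe_ids = probe_ids or [f"p{i}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"s{i}" for i in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=probe_ids, columns=sample_ids), meta)


def make_genotypes(calls, sample_ids=None, snp_ids=None):
    calls = np.asarray(calls, dtype=float)
    sample_ids = sample_ids or [f"s{i}" for i in range(calls.shape[0])]
    snp_ids = snp_ids or [f"snp{j}" for j in range(calls.shape[1])]
    return GenotypeMatrix(pd.DataFrame(calls, index=sample_ids, columns=snp_ids))


def make_phenotypes(grades, sample_ids=None):
    sample_ids = sample_ids or [f"s{i}" for i in range(len(grades))]
    return PhenotypeTable(pd.DataFrame({"who_grade": grades}, index=sample_ids))
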