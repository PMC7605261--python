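import numpy as np
import pandas as pd
import pytest

from epidriver import (
    CohortOmics,
    SimulationParams,
    simulate_multi_cancer_cohorts,
)


def make_cohort(sna, cna, z=None, code="TST", genes=None, samples=None, **kwargs):
    """Build a small cohort from plain arrays."""
    sna = np.asarray(sna)
    cna = np.asarray(cna)
    if z is None:
        z = np.zeros_like(sna, dtype=float)
    genes = genes or [f"G{i}" for i in range(sna.shape[0])]
    samples = samples or [f"S{j}" for j in range(sna.shape[1])]
    idx = pd.Index(genes, name="gene")
    return CohortOmics(
        cancer_code=code,
        sna=pd.DataFrame(sna, index=idx, columns=samples),
        cna=pd.DataFrame(cna, index=idx, columns=samples),
        expr_z=pd.DataFrame(np.asarray(z, dtype=float), index=idx, columns=samples),
        **kwargs,
    )


@pytest.fixture(scope="session")
def default_sim():
    """One seeded kitchen-sink simulation shared across tests."""
    params = SimulationParams.study_default(seed=11)
    cohorts, annotations, truth = simulate_multi_cancer_cohorts(params)
    return params, cohorts, annotations, truth
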