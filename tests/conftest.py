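import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from grmfit.synthetic import cohort_genes, make_gene_table, study_timecourses
from grmfit.timecourse import prepare_inputs

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def study_tcs():
    """Synthetic nuclear-NFκB time courses, both conditions x both replicates."""
    return study_timecourses(seed=0)


@pytest.fixture(scope="session")
def inputs(study_tcs):
    """Prepared 1-s input grids: {replicate: {condition: InputGrid}}."""
    return prepare_inputs(study_tcs)


@pytest.fixture(scope="session")
def rep1(inputs):
    return inputs[1]


@pytest.fixture(scope="session")
def small_cohort(rep1):
    """One zero-noise gene per model plus its ground truth."""
    genes = cohort_genes(n_per_model=1, seed=11)
    table, truth = make_gene_table(genes, rep1)
    return genes, table, truth


def gene_fc(table, gene_id):
    row = table.loc[gene_id].to_numpy()
    n = row.size // 2
    return {"ctrl": row[:n] / row[0], "siIkBa": row[n:] / row[n]}
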