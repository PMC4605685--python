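import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from c4net.io import ExpressionMatrix
from c4net.simulate import SimulationConfig, generate_dataset

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_matrix(values, species="M", genes=None, sections=None) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i + 1}" for i in range(values.shape[0])]
    sections = sections or [f"s{j + 1}" for j in range(values.shape[1])]
    return ExpressionMatrix(
        species,
        pd.DataFrame(values, index=pd.Index(genes, name="gene_id"),
                     columns=sections),
    )


@pytest.fixture(scope="session")
def small_dataset():
    """A 900-gene four-species dataset with planted truth (seed 7)."""
    return generate_dataset(SimulationConfig(seed=7, n_genes=900))


@pytest.fixture(scope="session")
def small_pipeline(small_dataset):
    """Full pipeline result on the small dataset (paper's soft powers)."""
    from c4net.pipeline import PipelineParams, run_stages

    ds = small_dataset
    params = PipelineParams(betas={"M": 10, "G": 12, "S": 18, "R": 16})
    return run_stages(ds.matrices, ds.orthologues, ds.markers,
                      ds.annotations, params)
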