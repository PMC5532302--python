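import numpy as np
import pandas as pd
import pytest

from omidriver import CohortSpec, generate_cohort
from omidriver.benchmarks import scaled_spec
from omidriver.datamodel import Group, Layer, OmicsMatrix


@pytest.fixture(scope="session")
def small_cohort():
    """One reduced synthetic cohort shared by integration tests."""
    return generate_cohort(scaled_spec(seed=7))


@pytest.fixture()
def tiny_matrix():
    """3 genes x 4 samples (2 tumor / 2 normal) expression matrix."""
    samples = ["T1", "T2", "N1", "N2"]
    values = pd.DataFrame(
        [[2.0, 2.2, 0.1, -0.1],
         [-1.5, -1.7, 0.0, 0.2],
         [0.1, -0.2, 0.05, 0.0]],
        index=["G1", "G2", "G3"], columns=samples,
    )
    groups = pd.Series({"T1": Group.TUMOR, "T2": Group.TUMOR,
                        "N1": Group.NORMAL, "N2": Group.NORMAL})
    return OmicsMatrix(layer=Layer.EXPRESSION, values=values, groups=groups)


def make_matrix(values: np.ndarray, layer: Layer, n_tumor: int, n_normal: int,
                feature_prefix: str = "G") -> OmicsMatrix:
    samples = [f"T{i+1}" for i in range(n_tumor)] + [f"N{i+1}" for i in range(n_normal)]
    groups = pd.Series({s: (Group.TUMOR if s.startswith("T") else Group.NORMAL)
                        for s in samples})
    ids = [f"{feature_prefix}{i+1:04d}" for i in range(values.shape[0])]
    return OmicsMatrix(layer=layer,
                       values=pd.DataFrame(values, index=ids, columns=samples),
                       groups=groups)
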