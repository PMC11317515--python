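import numpy as np
import pandas as pd
import pytest

from proxistress import IntensityMatrix, Role, Batch, SampleDesign, SimConfig


@pytest.fixture
def small_design() -> SampleDesign:
    records = {}
    for role in (Role.FUSION_PROXIMITY, Role.FREE_LIGASE, Role.NEG_CONTROL):
        for rep in (1, 2, 3):
            records[f"{role.value}_r{rep}"] = (role, Batch.NONSTRESS, rep)
    return SampleDesign.from_records(records)


@pytest.fixture
def small_matrix(small_design) -> IntensityMatrix:
    rng = np.random.default_rng(42)
    samples = list(small_design.sample_names)
    values = pd.DataFrame(
        rng.normal(25, 2, size=(20, len(samples))),
        index=pd.Index([f"P{i:03d}" for i in range(20)], name="protein_id"),
        columns=samples,
    )
    return IntensityMatrix(values=values)


@pytest.fixture
def fast_sim_config() -> SimConfig:
    """Small config for quick end-to-end exercises."""
    return SimConfig(n_proteins=300, seed=123)
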