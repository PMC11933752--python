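import warnings

import numpy as np
import pandas as pd
import pytest

from nephronet.schema import CohortTable, Indicator, IndicatorSchema
from nephronet.simulate import SimConfig, generate_patients, generate_reference


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    return SimConfig(n_patients=300, seed=7)


@pytest.fixture(scope="session")
def reference_small(small_cfg):
    return generate_reference(small_cfg)


@pytest.fixture(scope="session")
def cohort_small(small_cfg):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_patients(small_cfg)


def tiny_schema(n: int = 3, kind: str = "continuous") -> IndicatorSchema:
    return IndicatorSchema(
        tuple(Indicator(f"x{i}", "renal", kind) for i in range(n))
    )


def tiny_table(data: np.ndarray | pd.DataFrame, kind: str = "continuous") -> CohortTable:
    df = pd.DataFrame(np.asarray(data, dtype=float))
    df.columns = [f"x{i}" for i in range(df.shape[1])]
    return CohortTable(df, tiny_schema(df.shape[1], kind))
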