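import numpy as np
import pandas as pd
import pytest

from asmbly.core_data import AsvTable, SampleMetadata


@pytest.fixture
def small_table():
    counts = np.array([
        [5, 3, 0, 2],
        [1, 0, 9, 0],
        [4, 4, 4, 4],
    ])
    return AsvTable(counts, ["s1", "s2", "s3"], ["a", "b", "c", "d"])


@pytest.fixture
def design_metadata():
    rows = []
    ids = []
    for comp in ("bulk_soil", "rhizosphere"):
        for stage in ("V2", "R2"):
            for rep in (1, 2):
                ids.append(f"{comp}_{stage}_{rep}")
                rows.append({"compartment": comp, "stage": stage,
                             "cultivar": "NNS", "replicate": rep})
    return SampleMetadata(pd.DataFrame(rows, index=ids))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
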