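import numpy as np
import pandas as pd
import pytest

from lomo import simulate as sim
from lomo.datasets import CELLTYPE, DONOR, SAMPLE, TIME, LongitudinalDataset


@pytest.fixture
def toy_bulk() -> LongitudinalDataset:
    """2 donors x 3 timepoints, 2 features with hand-checkable values."""
    ann = pd.DataFrame(
        {DONOR: ["A", "A", "A", "B", "B", "B"], TIME: [1.0, 2.0, 3.0] * 2},
        index=pd.Index([f"s{i}" for i in range(6)], name=SAMPLE),
    )
    mat = pd.DataFrame(
        [[1.0, 2.0, 3.0, 2.0, 2.0, 2.0], [10.0, 10.0, 10.0, 8.0, 10.0, 12.0]],
        index=pd.Index(["f1", "f2"], name="feature"),
        columns=ann.index,
    )
    return LongitudinalDataset(annotation=ann, matrix=mat)


@pytest.fixture(scope="session")
def designed_sc():
    """4 donors x 6 timepoints x 4 cell types with designed stability classes."""
    spec = sim.sc4x6x19(
        seed=11, n_features=40, n_celltypes=4,
        n_celltype_stable=4, n_global_stable=4, n_global_variable=4,
    )
    return sim.simulate_single_cell(spec)


@pytest.fixture(scope="session")
def designed_pb(designed_sc):
    from lomo.datasets import filter_low_expression, pseudobulk

    sc, truth = designed_sc
    return filter_low_expression(pseudobulk(sc)), truth
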