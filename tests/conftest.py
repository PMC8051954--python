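import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from adtopt.data_model import AntibodyPanel, CountMatrix, StainingCondition


@pytest.fixture
def small_matrix() -> CountMatrix:
    data = np.array(
        [
            [5, 0, 3, 1],
            [0, 2, 0, 0],
            [7, 1, 4, 2],
        ]
    )
    return CountMatrix(["CD3", "CD19", "CD45"], ["AAA", "CCC", "GGG", "TTT"], sp.csr_matrix(data))


@pytest.fixture
def small_panel() -> AntibodyPanel:
    table = pd.DataFrame(
        {
            "concentration_DF1": [1.0, 0.5, 2.0],
            "is_isotype_control": [False, False, False],
        },
        index=pd.Index(["CD3", "CD19", "CD45"], name="name"),
    )
    return AntibodyPanel(table)


@pytest.fixture
def condition_df1() -> StainingCondition:
    return StainingCondition("DF1", volume_ul=50.0, cells_stained=1e6, dilution_factor=1.0)
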