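import numpy as np
import pandas as pd
import pytest

from tapcnv.io import AmpliconPanel, CountMatrix, ReferenceSpec


@pytest.fixture
def small_panel() -> AmpliconPanel:
    """Two chromosomes, two amplicons each, one variant on the first amplicon."""
    amps = pd.DataFrame(
        {
            "amplicon_id": ["a1", "a2", "b1", "b2"],
            "chrom": ["1", "1", "2", "2"],
            "start": [1, 5001, 1, 5001],
            "end": [250, 5250, 250, 5250],
        }
    )
    variants = pd.DataFrame(
        {"variant_id": ["a1_v1"], "amplicon_id": ["a1"], "pos": [100]}
    )
    return AmpliconPanel(amps, variants)


@pytest.fixture
def counts_2x2() -> CountMatrix:
    return CountMatrix(["a1", "a2"], ["c1", "c2"], np.array([[5.0, 0.0], [3.0, 7.0]]))


@pytest.fixture
def diploid_reference() -> ReferenceSpec:
    return ReferenceSpec(["c1", "c2"], {})
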