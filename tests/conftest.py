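import numpy as np
import pandas as pd
import pytest

from sarcosig import GeneSignature


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_matrix(rng):
    """20 genes x 6 samples of log2-scale noise."""
    genes = [f"G{i + 1:04d}" for i in range(20)]
    samples = [f"S{i + 1}" for i in range(6)]
    return pd.DataFrame(
        7.0 + rng.standard_normal((20, 6)), index=genes, columns=samples
    )


@pytest.fixture
def small_signature():
    return GeneSignature(
        name="toy",
        entries={"G0001": 1, "G0003": 1, "G0005": -1, "G0007": 1, "G0009": -1},
    )
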