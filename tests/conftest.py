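import pandas as pd
import pytest

from microassembly import CommunityMatrix


@pytest.fixture
def toy_matrix():
    """3 samples x 2 taxa with known row sums (5, 5, 7)."""
    return CommunityMatrix(
        pd.DataFrame(
            [[5, 0], [2, 3], [0, 7]],
            index=["s1", "s2", "s3"],
            columns=["t1", "t2"],
        )
    )


@pytest.fixture
def toy_metadata():
    return pd.DataFrame(
        {
            "latitude": [-20.0, -25.0, -30.0],
            "longitude": [140.0, 145.0, 150.0],
            "region": ["arid", "arid", "humid"],
            "aridity_index": [0.10, 0.15, 0.80],
        },
        index=pd.Index(["s1", "s2", "s3"], name="sample_id"),
    )
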