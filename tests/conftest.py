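import pandas as pd
import pytest

from zdose.simulate import small_study


@pytest.fixture(scope="session")
def study():
    """Bundled small study: 2 autosomes + Z, 60 genes, one tissue."""
    return small_study(seed=7)


@pytest.fixture()
def samples_4v4():
    return pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(8)],
        "sex": ["F"] * 4 + ["M"] * 4,
        "tissue": "liver",
    })
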