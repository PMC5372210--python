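import numpy as np
import pandas as pd
import pytest

from qsrrkit import DescriptorMatrix, RetentionTable


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)


@pytest.fixture
def small_dm():
    """10 solutes x 3 well-conditioned descriptor columns."""
    r = np.random.default_rng(7)
    frame = pd.DataFrame(
        r.standard_normal((10, 3)),
        index=[f"S{i}" for i in range(10)],
        columns=["MD1", "MD2", "MD3"],
    )
    return DescriptorMatrix(frame)


@pytest.fixture
def small_rt(small_dm):
    """Retention driven by MD1 and MD2 plus noise, positive-shifted."""
    r = np.random.default_rng(8)
    y = 2.0 * small_dm.frame["MD1"] - 1.0 * small_dm.frame["MD2"]
    y = y + 0.05 * r.standard_normal(10)
    y = y - y.min() + 1.0
    return RetentionTable(pd.DataFrame({"tR_A": y}, index=small_dm.frame.index))
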