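import numpy as np
import pandas as pd
import pytest

from comir.thermo import SITE_COLUMNS


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_sites(rows):
    """Site table from (gene, mirna, score) triples; coordinates synthesized."""
    records = [
        (g, m, 8 * i, 8 * i + 7, "toolX", s) for i, (g, m, s) in enumerate(rows)
    ]
    return pd.DataFrame(records, columns=list(SITE_COLUMNS))
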