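import numpy as np
import pandas as pd
import pytest

from fflomics.de import GROUPS


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_counts(rng):
    """100-miRNA six-group NB count table with no planted structure."""
    mu = rng.lognormal(7.0, 1.0, 100)
    data = {g: rng.negative_binomial(20, 20 / (20 + mu)) for g in GROUPS}
    df = pd.DataFrame(data, index=[f"mir{i:03d}" for i in range(100)])
    df.index.name = "mirna"
    return df


def make_records(per_mirna: dict) -> pd.DataFrame:
    """DE-record table from {mirna: {contrast: direction-or-'none'}}.

    Any of the nine contrasts not mentioned defaults to non-significant.
    """
    from fflomics.de import ALL_CONTRASTS

    rows = []
    for mirna, contrasts in per_mirna.items():
        for c in ALL_CONTRASTS:
            d = contrasts.get(c, "none")
            sig = d != "none"
            rows.append(
                {
                    "mirna": mirna,
                    "contrast": c,
                    "log2fc": {"up": 2.0, "down": -2.0, "none": 0.1}[d],
                    "pvalue": 0.001 if sig else 0.5,
                    "qvalue": 0.004 if sig else 0.8,
                    "significant": sig,
                    "direction": d,
                }
            )
    return pd.DataFrame(rows)
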