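import numpy as np
import pytest

from psohfs import datasets, ranking


@pytest.fixture(scope="session")
def reference_ranking():
    """Bundled 27-syndrome relevance statistics (name, mcc, pe, fr, rank)."""
    return datasets.load_ranking_reference()


@pytest.fixture(scope="session")
def reference_records(reference_ranking):
    return [
        ranking.RankingRecord(row["name"], row["mcc"], row["pe"])
        for _, row in reference_ranking.iterrows()
    ]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
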