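import logging

import pytest
from hypothesis import settings

from foldspec.records import GeneRecord

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")

logging.getLogger("foldspec").setLevel(logging.ERROR)


@pytest.fixture
def up_records():
    """12 up-regulated genes with distinct fold changes 2..13."""
    return [GeneRecord(f"G{i:02d}", "up", float(i + 2)) for i in range(12)]


@pytest.fixture
def table1_partition():
    """A 789-gene 'up' partition mirroring the reference dataset's size.

    Fold changes equal the rank so quantile membership is transparent;
    quantiles 1-2 together hold the 263 weakest-responding genes.
    """
    from foldspec.intervals import rank_and_partition

    recs = [GeneRecord(f"U{i:04d}", "up", 1.5 + i * 0.1) for i in range(789)]
    return rank_and_partition(recs, 6)
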