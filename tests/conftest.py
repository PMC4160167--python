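import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from motifsieve import SequenceRecord, SequenceSet


def make_set(sequences, role="query", prefix="s"):
    """Build a SequenceSet from plain strings (lowercase = masked)."""
    return SequenceSet(
        [SequenceRecord.from_string(f"{prefix}{i}", s) for i, s in enumerate(sequences)],
        role=role,
    )


@pytest.fixture
def toy_query():
    # three sequences share LPPAP; the fourth is motif-free
    return make_set(["MKLPPAPQRS", "TTLPPAPWYV", "GGLPPAPHID", "MNHEQWYKFC"])


@pytest.fixture
def pruning_query():
    # RSTSL in three sequences plus RATSL in a fourth: the degenerate form
    # R.TSL gains only one occurrence over its best parent and must be pruned
    return make_set(["MMRSTSLMM", "KKRSTSLKK", "WWRSTSLWW", "HHRATSLHH"], prefix="t")
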