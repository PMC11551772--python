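import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from replidose.genome import Replicon
from replidose.mfa import WindowCounts

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def two_window_replicon():
    """A 2 kb circular replicon tiled by two 1 kb windows."""
    return Replicon("r", 2_000, True, ori_bp=0)


def make_counts(replicon, counts, window_bp=1_000, phase="exponential"):
    """WindowCounts from a plain list of per-window counts."""
    n = len(counts)
    starts = np.arange(n) * window_bp
    df = pd.DataFrame(
        {
            "replicon": replicon.name,
            "start": starts,
            "end": np.minimum(starts + window_bp, replicon.length_bp),
            "count": counts,
        }
    )
    return WindowCounts(df, window_bp, phase)


@pytest.fixture
def small_two_chromosome():
    """Two co-terminating circular replicons small enough for brute force:
    10 and 6 windows per arm at 1 kb."""
    return [
        Replicon("A", 20_000, True, ori_bp=5_000),
        Replicon("B", 12_000, True, ori_bp=3_000),
    ]
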