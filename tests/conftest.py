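import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20100401)


@pytest.fixture
def activity_csv(tmp_path):
    """Write a small activity CSV from a frame; returns the writer."""

    def write(frame: pd.DataFrame, name: str = "activity.csv"):
        path = tmp_path / name
        frame.to_csv(path, index=False)
        return path

    return write


def five_min_frame(hours: int, vertical, start="2010-04-01") -> pd.DataFrame:
    """Gap-free 5-min record frame; ``vertical`` is scalar or length 12*hours."""
    idx = pd.date_range(start, periods=12 * hours, freq="5min")
    v = np.broadcast_to(np.asarray(vertical), (idx.size,)).astype(int)
    return pd.DataFrame({"timestamp": idx, "vertical": v, "horizontal": v})
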