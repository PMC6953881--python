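import numpy as np
import pandas as pd
import pytest

from actidays.signal import EpochSeries, RawRecording


def make_epoch_series(enmo, epoch_len=5.0, wear=None, start="2010-03-01"):
    return EpochSeries(
        subject_id="T",
        epoch_len=epoch_len,
        start_time=pd.Timestamp(start),
        enmo=np.asarray(enmo, dtype=float),
        wear=wear,
    )


def make_constant_recording(vec, duration_s, sample_rate=10.0, start="2010-03-01"):
    n = int(round(duration_s * sample_rate))
    x, y, z = (np.full(n, v, dtype=float) for v in vec)
    return RawRecording(
        subject_id="T",
        sample_rate=sample_rate,
        start_time=pd.Timestamp(start),
        x=x,
        y=y,
        z=z,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
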