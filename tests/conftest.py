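import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from phaseslope import synthetic
from phaseslope.dam_io import ActivityMatrix
from phaseslope.protocol import standard_protocol

settings.register_profile("ci", max_examples=25, deadline=None,
                          derandomize=True)
settings.load_profile("ci")


def make_matrix(counts: np.ndarray, valid=None,
                start: str = "2022-01-03 08:00", monitor: str = "M1"
                ) -> ActivityMatrix:
    """Small activity matrix on a 1-min grid from a (minutes, flies) array."""
    counts = np.atleast_2d(np.asarray(counts, dtype=np.int64))
    idx = pd.date_range(start, periods=counts.shape[0], freq="1min")
    cols = [f"{monitor}:{c:02d}" for c in range(1, counts.shape[1] + 1)]
    frame = pd.DataFrame(counts, index=idx, columns=cols)
    if valid is None:
        valid = pd.Series(True, index=idx)
    else:
        valid = pd.Series(np.asarray(valid, dtype=bool), index=idx)
    return ActivityMatrix(frame, valid)


@pytest.fixture(scope="session")
def lltc_protocol():
    return standard_protocol("LLTC", days_ld=2, days_constant=3, days_tc=6,
                             shift_h=5.0)


@pytest.fixture(scope="session")
def control_population(lltc_protocol):
    cfg = synthetic.preset("control_LLTC")
    return synthetic.simulate_population(cfg, lltc_protocol, seed=11)
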