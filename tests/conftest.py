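import numpy as np
import pandas as pd
import pytest

from wmcda.cda.epochs import EpochSet
from wmcda._utils import CDA_CHANNELS


@pytest.fixture
def blank_epochs():
    """Factory for small all-zero epoch sets with CDA + EOG channels."""

    def make(n_trials=4, sfreq=500.0, tmin_ms=-200.0, tmax_ms=2000.0,
             channels=None, participants=None):
        channels = list(channels or (*CDA_CHANNELS, "VEOG", "HEOG"))
        n_samp = int(round((tmax_ms - tmin_ms) * sfreq / 1000.0))
        data = np.zeros((n_trials, len(channels), n_samp))
        meta = pd.DataFrame(
            {
                "participant": participants if participants is not None else [0] * n_trials,
                "cue_side": ["left", "right"] * (n_trials // 2) + ["left"] * (n_trials % 2),
                "set_size": 3,
                "stim_type": "CLR_REP",
            }
        )
        return EpochSet(data=data, sfreq=sfreq, tmin_ms=tmin_ms,
                        channels=channels, metadata=meta)

    return make
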