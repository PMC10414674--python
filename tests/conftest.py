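import numpy as np
import pandas as pd
import pytest

import remotefit as rf


@pytest.fixture
def meridian_track() -> rf.GpsTrack:
    """73 fixes at 0,5,...,360 s walking due north at exactly 1.5 m/s."""
    ts = np.arange(0.0, 361.0, 5.0)
    dlat = np.degrees(1.5 * ts / rf.geo_walk.EARTH_RADIUS_M)
    return rf.GpsTrack([rf.GpsFix(float(t), float(la), 0.0, 8.0) for t, la in zip(ts, dlat)])


@pytest.fixture
def small_rm() -> pd.DataFrame:
    """The 3-subject, 2-session worked table with ICC(2,1) = 8/9."""
    return pd.DataFrame(
        {
            "subject": ["a", "a", "b", "b", "c", "c"],
            "session": [1, 2, 1, 2, 1, 2],
            "score": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
        }
    )
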