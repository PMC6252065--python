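import numpy as np
import pandas as pd
import pytest
from datetime import date, datetime

from camtrapdiel.solar import SolarDay, sun_times


@pytest.fixture
def rng():
    return np.random.default_rng(20150410)


@pytest.fixture
def ni_spring_day():
    """Sun times for a mid-spring date at a Northern Irish latitude."""
    return sun_times(date(2015, 4, 17), 54.35, -6.65, 0.0)


@pytest.fixture
def simple_solar_day():
    """A hand-built solar day with round sunrise/sunset for boundary tests."""
    d = date(2015, 4, 17)
    return SolarDay(
        date=d,
        latitude=54.6,
        longitude=-5.9,
        utc_offset=0.0,
        sunrise=datetime(2015, 4, 17, 6, 0),
        sunset=datetime(2015, 4, 17, 20, 0),
    )


def make_detections(rows):
    """Detection table from (species, site, camera, iso_timestamp) tuples."""
    df = pd.DataFrame(
        [
            {
                "species": sp,
                "site_id": site,
                "camera_id": cam,
                "timestamp": pd.Timestamp(ts),
                "latitude": 54.6,
                "longitude": -5.9,
                "group_size": 1,
            }
            for sp, site, cam, ts in rows
        ]
    )
    return df.sort_values(["species", "camera_id", "timestamp"]).reset_index(drop=True)


@pytest.fixture
def detections_factory():
    return make_detections
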