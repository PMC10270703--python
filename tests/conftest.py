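import datetime as dt

import pytest

from wheatgpc.synthetic import constant_weather


@pytest.fixture(scope="session")
def three_phase_series():
    """Canonical constant-temperature season: 15 °C autumn, −2 °C winter
    (1 Dec – 20 Feb), 20 °C from 21 Feb onward."""
    return constant_weather(
        "fix", dt.date(2016, 9, 1), dt.date(2017, 7, 31),
        tmean=[(dt.date(2016, 9, 1), 15.0),
               (dt.date(2016, 12, 1), -2.0),
               (dt.date(2017, 2, 21), 20.0)])


@pytest.fixture(scope="session")
def warm_series():
    """Constant 20 °C all season (never dormant, but fine for GDD sums)."""
    return constant_weather("warm", dt.date(2016, 9, 1), dt.date(2017, 7, 31),
                            tmean=20.0)
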