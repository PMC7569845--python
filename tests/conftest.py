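import logging

import numpy as np
import pytest

from erokin import PRESETS, get_preset

PRESET_NAMES = tuple(PRESETS)


@pytest.fixture(params=PRESET_NAMES)
def preset(request):
    """Each formulation preset in turn."""
    return get_preset(request.param)


@pytest.fixture
def plga15():
    return get_preset("PLGA15")


@pytest.fixture(autouse=True)
def _quiet_clamp_warnings():
    """Keep expected near-asymptote clamp warnings out of test logs."""
    log = logging.getLogger("erokin.kinetics")
    prev = log.level
    log.setLevel(logging.ERROR)
    yield
    log.setLevel(prev)


@pytest.fixture
def weekly_times():
    return np.arange(0.0, 43.0, 7.0)


@pytest.fixture
def front_times():
    """15-point schedule over the 0-42 day degradation window."""
    return np.linspace(0.0, 42.0, 15)
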