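import numpy as np
import pytest

import netburst as nb


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_plate():
    """Two short synthetic wells (control preset, 120 s) for I/O tests."""
    from dataclasses import replace

    cfg = replace(nb.control_preset(seed=7), duration=120.0)
    plate, _ = nb.simulate_plate(cfg, 2, group_label="control")
    return plate
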