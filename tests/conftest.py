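import logging

import numpy as np
import pytest

from carposim.dynamics import assemble_forelimb, simulate_stride
from carposim.kinematics import build_drive
from carposim.synthetic_data import asti_2015_preset

logging.disable(logging.WARNING)


@pytest.fixture(scope="session")
def preset():
    return asti_2015_preset()


@pytest.fixture(scope="session")
def stride_sim(preset):
    """One full stride under the shipped accident-scenario preset.

    Expensive (~10^4 integration steps); shared by every test that inspects
    the preset stride.
    """
    scenario, metrics, cfg = preset
    drive = build_drive(metrics, scenario, T=cfg.T)
    model = assemble_forelimb(config=cfg)
    import time

    t0 = time.time()
    result = simulate_stride(model, drive)
    return {"model": model, "drive": drive, "result": result, "elapsed": time.time() - t0}


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)
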