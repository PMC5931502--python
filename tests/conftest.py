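import pytest

from sdgeno.calibration import calibrate_all
from sdgeno.synthetic import simulate_control_bundle


@pytest.fixture(scope="session")
def control_setup():
    """Control arrays (NTC/WT/MUT plasmid) with calibrations and bleed model.

    Shared across tests: simulating and calibrating a 7-array control set
    is the expensive common prefix of most analysis checks.
    """
    arrays, truths = simulate_control_bundle(seed=7, n_ntc=2, n_wt=3, n_mut=2)
    calibrations, bleed = calibrate_all(arrays)
    return {"arrays": arrays, "truths": truths, "calibrations": calibrations, "bleed": bleed}
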