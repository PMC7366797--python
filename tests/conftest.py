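import math

import pytest

from doseresp.datasets import load_printed_responses
from doseresp.response import ResponseValue


@pytest.fixture(scope="session")
def printed_responses():
    return load_printed_responses()


@pytest.fixture(scope="session")
def printed_rot_map(printed_responses):
    """Published rotational responses keyed (type, energy) -> {angle: ResponseValue}."""
    out = {}
    rot = printed_responses[printed_responses["geometry"] == "ROT"]
    for (dtype, energy), grp in rot.groupby(["dosemeter_type", "mean_energy_keV"]):
        out[(dtype, float(energy))] = {
            float(r.zenith_angle_deg): ResponseValue(
                r.mean_B, math.log(r.K) / 1.96, r.K, 4
            )
            for r in grp.itertuples()
        }
    return out
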