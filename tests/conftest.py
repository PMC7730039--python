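import numpy as np
import pytest

from osseoheal.config import RunConfig
from osseoheal.fixtures import make_fixture
from osseoheal.mechanoreg import run_healing


@pytest.fixture(scope="session")
def toy():
    """Compact single-chamber reference fixture."""
    return make_fixture("single_chamber")


@pytest.fixture(scope="session")
def toy_history():
    """Full 35-day healing run on the reference geometry, default config."""
    return run_healing(RunConfig(days=35))


@pytest.fixture(scope="session")
def analog_histories():
    """35-day runs of the scaled-down design analogs used for the
    flank-slope (A/E/F) and root/crest (B/G) comparisons."""
    out = {}
    for label in ("A", "E", "F", "B", "G"):
        cfg = RunConfig(implant=f"analog-{label}", days=35,
                        implant_element_factor=3.0, far_field_growth=1.15)
        out[label] = run_healing(cfg)
    return out


def first_resorption(history):
    """(day, centroids) of the earliest resorption-classified elements."""
    cent = history.mesh.element_centroids()[history.callus_elements]
    for rec in history.days:
        mask = rec.phenotype == "resorption"
        if mask.any():
            return rec.day, cent[mask]
    return None, np.zeros((0, 2))
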