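import numpy as np
import pytest

from mfrel import colloid_qc, synth
from mfrel.release_models import ReleaseCurve


@pytest.fixture()
def medium_25C():
    """Water-like dispersion medium at 25 C (defaults)."""
    return colloid_qc.MediumProperties()


@pytest.fixture(scope="session")
def pre_emulsion_records():
    """Packaged CTAB pre-emulsion characterization table."""
    return colloid_qc.load_pre_emulsion_table()


@pytest.fixture(scope="session")
def demo_curve():
    """Default synthetic Kink demo curve, seed 0."""
    return synth.gen_release_curve(synth.SyntheticSpec(seed=0))


@pytest.fixture(scope="session")
def noiseless_demo_curve():
    return synth.gen_release_curve(synth.SyntheticSpec(seed=0, noise_sd=0.0))


@pytest.fixture()
def line_curve():
    """A straight line sampled at 256 points (dimension-1 reference)."""
    t = np.linspace(0.0, 255.0, 256)
    return ReleaseCurve("line", t, 0.1 + 0.003 * t, units="ug_per_ml")
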