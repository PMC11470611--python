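import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repeatable", derandomize=True)
settings.load_profile("repeatable")

from esomech import holzapfel as hz
from esomech import synthetic as syn
from esomech.curves import AXIAL, CIRCUMFERENTIAL, BiaxialTest, StretchStressCurve


@pytest.fixture
def toy_test() -> BiaxialTest:
    """Three-sample record: lambda = 1.0, 1.2, 1.4; stresses 0, 10, 40 kPa."""
    lam = np.array([1.0, 1.2, 1.4])
    stress = np.array([0.0, 10.0, 40.0])
    return BiaxialTest(
        test_id="toy",
        axial=StretchStressCurve(lam, stress, AXIAL),
        circumferential=StretchStressCurve(lam, stress, CIRCUMFERENTIAL),
    )


@pytest.fixture(scope="session")
def ensemble_seed1():
    """Default 13-test synthetic ensemble, master seed 1."""
    return syn.generate_ensemble(seed=1)


@pytest.fixture(scope="session")
def clean_holzapfel_test() -> BiaxialTest:
    """Noiseless record forward-simulated from one known parameter set."""
    params = hz.HolzapfelParams(c=5.0, k1=2.0, k2=1.5, theta=0.8)
    lam = np.linspace(1.0, 1.5, 60)
    sig_tt, sig_zz = hz.equibiaxial_stresses(params, lam)
    return BiaxialTest(
        test_id="clean",
        axial=StretchStressCurve(lam, sig_zz, AXIAL),
        circumferential=StretchStressCurve(lam, sig_tt, CIRCUMFERENTIAL),
    )


CLEAN_PARAMS = hz.HolzapfelParams(c=5.0, k1=2.0, k2=1.5, theta=0.8)
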