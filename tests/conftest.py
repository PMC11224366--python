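import numpy as np
import pytest
import SimpleITK as sitk

from myometry import phantom as ph

sitk.ProcessObject_SetGlobalWarningDisplay(False)


@pytest.fixture(scope="session")
def minimal_ds():
    """Noiseless three-muscle phantom on a small grid."""
    return ph.generate(ph.minimal_spec())


@pytest.fixture(scope="session")
def minimal_noisy_ds():
    """Same geometry with 2% Dixon channel noise and STIR noise."""
    return ph.generate(ph.minimal_spec(noise_sd=0.02, seed=3, stir_noise_sd=5.0))


@pytest.fixture(scope="session")
def five_ds():
    """Noiseless five-pattern phantom (one muscle per FF distribution)."""
    return ph.generate(ph.five_pattern_spec())


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)
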