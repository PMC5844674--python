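import numpy as np
import pytest

from ventilam import (VentilatorWaveform, build_airway_tree, pressure_profile,
                      strain_for_airways, wall_sections)
from ventilam.fixtures import default_morphology


@pytest.fixture(scope="session")
def morphology():
    return default_morphology()


@pytest.fixture(scope="session")
def tree(morphology):
    return build_airway_tree(morphology, 7)


@pytest.fixture(scope="session")
def waveform():
    return VentilatorWaveform()


@pytest.fixture(scope="session")
def profile(tree, waveform):
    return pressure_profile(tree, waveform, p_outlet=0.0, n_samples=200)


@pytest.fixture(scope="session")
def sections(morphology):
    return wall_sections(morphology)


@pytest.fixture(scope="session")
def default_strains(profile, sections):
    """Epithelial strain per generation under the default breath."""
    peaks = profile.peak_pressures()
    return strain_for_airways({g: float(peaks[g]) for g in range(8)}, sections)
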