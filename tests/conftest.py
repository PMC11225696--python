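import numpy as np
import pytest

from nbo import synth
from nbo.stimspace import ANGRY_0, ANGRY_90, VERYHAPPY_0, VERYHAPPY_90


#: optima tabulation observed in the published 42-infant cohort
PAPER_OPTIMA_COUNTS = {
    ANGRY_0: 18,
    ANGRY_90: 9,
    VERYHAPPY_0: 7,
    VERYHAPPY_90: 8,
}


@pytest.fixture(scope="session")
def flat10_profile():
    """Noise-free infant with a flat -10 uV surface (analytic oracle: the
    block ERP is the template, so Nc negativity = depth/2 = 5)."""
    surface = synth.make_surface("flat", baseline_depth=-10.0)
    return synth.noise_free_profile(surface, seed=1)


@pytest.fixture(scope="session")
def corner_profile():
    """Noise-free corner-peak infant, deepest response at Angry-0."""
    surface = synth.make_surface(
        "corner-peak", peak_coord=ANGRY_0, contrast=6.0, baseline_depth=-4.0
    )
    return synth.noise_free_profile(surface, seed=2)


@pytest.fixture(scope="session")
def noisefree_block(flat10_profile):
    return synth.simulate_block(flat10_profile, ANGRY_0, 1)


def make_corner_profile(peak, seed, **kwargs):
    surface = synth.make_surface(
        "corner-peak", peak_coord=peak, contrast=6.0, baseline_depth=-4.0
    )
    if kwargs:
        return synth.InfantProfile(surface=surface, seed=seed, **kwargs)
    return synth.noise_free_profile(surface, seed)
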