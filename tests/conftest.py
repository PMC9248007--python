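import warnings

import numpy as np
import pytest

from endorkit.conformer_fit import ConformerEnsemble
from endorkit.endor_sim import simulate_mims_endor
from endorkit.spin_models import NucleusSpec
from endorkit.synthetic_data import build_conformer_pair, default_settings_list


@pytest.fixture(scope="session")
def f19() -> NucleusSpec:
    return NucleusSpec.from_isotope("19F")


@pytest.fixture(scope="session")
def ensemble() -> ConformerEnsemble:
    return build_conformer_pair()


@pytest.fixture(scope="session")
def settings_list():
    return default_settings_list(n_orientations=3000)


@pytest.fixture(scope="session")
def conformer_sims(ensemble, settings_list):
    """(stacked, flipped) simulated spectra for every acquisition setting."""
    stacked_sys, flipped_sys = ensemble.require_pair()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # ring-proton tails exceed the window
        return [
            (simulate_mims_endor(stacked_sys, st), simulate_mims_endor(flipped_sys, st))
            for st in settings_list
        ]


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
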