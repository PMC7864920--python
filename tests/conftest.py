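"""Shared fixtures: container scenes and pre-rendered panoramas.

Panoramas are session-scoped because rendering dominates the suite runtime;
all tests that only read them share one render per scene.
"""

import numpy as np
import pytest
from hypothesis import settings

import tankvision as tv

settings.register_profile("suite", max_examples=100, derandomize=True,
                          deadline=None)
settings.load_profile("suite")

GLOBAL_SEED = 1


@pytest.fixture(scope="session")
def petri_scene():
    return tv.build_preset("petri_lid")


@pytest.fixture(scope="session")
def cylinder_scene():
    return tv.build_preset("cylinder")


@pytest.fixture(scope="session")
def bulb_full_scene():
    return tv.build_preset("bulb_8cm_full")


@pytest.fixture(scope="session")
def bulb_low_scene():
    return tv.build_preset("bulb_10cm_low")


@pytest.fixture(scope="session")
def pano_petri(petri_scene):
    """Full-sphere perceived panorama of the Petri-dish lid."""
    return tv.render_panorama(petri_scene, None, resolution=(144, 72))


@pytest.fixture(scope="session")
def pano_bulb_full(bulb_full_scene):
    """Full-sphere perceived panorama of the water-filled glass bulb."""
    return tv.render_panorama(bulb_full_scene, None, resolution=(144, 72))


def _neuro_pano(scene):
    # window used by the forward-model simulations: both hemifields, the
    # elevation band around the arena
    return tv.render_panorama(scene, None, resolution=(144, 60),
                              az_range=(-180.0, 180.0), el_range=(-60.0, 60.0))


@pytest.fixture(scope="session")
def neuro_pano_petri(petri_scene):
    return _neuro_pano(petri_scene)


@pytest.fixture(scope="session")
def neuro_pano_bulb_full(bulb_full_scene):
    return _neuro_pano(bulb_full_scene)


@pytest.fixture(scope="session")
def neuro_pano_bulb_low(bulb_low_scene):
    return _neuro_pano(bulb_low_scene)


@pytest.fixture()
def rng():
    return np.random.default_rng(GLOBAL_SEED)
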