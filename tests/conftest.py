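"""Shared fixtures: one default phantom, computed once per session."""

import numpy as np
import pytest

import petquant as pq


@pytest.fixture(scope="session")
def spec():
    return pq.PhantomSpec()


@pytest.fixture(scope="session")
def labels(spec):
    return pq.make_label_phantom(spec)


@pytest.fixture(scope="session")
def truth(spec, labels):
    return pq.simulate_region_tacs(spec, labels)


@pytest.fixture(scope="session")
def noiseless_pet(labels, truth):
    """Blurred (6.5 mm PSF) but noise-free dynamic phantom."""
    return pq.render_dynamic_pet(labels, truth, noise_scale=0.0)


@pytest.fixture(scope="session")
def noisy_pet(labels, truth):
    return pq.render_dynamic_pet(labels, truth, seed=7)


@pytest.fixture(scope="session")
def static(noiseless_pet):
    return pq.time_weighted_average(noiseless_pet)


@pytest.fixture(scope="session")
def t1_proxy(labels):
    return pq.render_t1_proxy(labels)


@pytest.fixture(scope="session")
def head_mask(static):
    return pq.default_mask(static)


@pytest.fixture(scope="session")
def small_labels():
    """A cheap two-region slab phantom for brute-force oracles."""
    lab = np.zeros((16, 16, 16), dtype=np.int32)
    lab[4:12, 4:12, 4:12] = 1
    lab[6:10, 6:10, 6:10] = 2
    aff = np.diag([2.0, 2.0, 2.0, 1.0])
    return pq.LabelVolume(lab, aff, {1: "shell", 2: "core"})


def rigid(translations=(0, 0, 0), rotations=(0, 0, 0), center=(0, 0, 0)):
    return pq.RigidTransform(rotations=rotations, translations=translations,
                             center=center)
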