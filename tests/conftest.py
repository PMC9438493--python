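import numpy as np
import pytest

import dmphase as dp


@pytest.fixture(scope="session")
def toy():
    """Default P1 toy crystal (24 A cell, 80% solvent, 3 A, 2% noise)."""
    return dp.generate_toy_crystal(seed=1)


@pytest.fixture(scope="session")
def toy_noise_free():
    return dp.generate_toy_crystal(seed=1, noise_frac=0.0)


@pytest.fixture(scope="session")
def projector(toy):
    return dp.FourierProjector(toy.refl, toy.density.values.shape)


@pytest.fixture(scope="session")
def reference_provider(toy):
    from dmphase.synthetic_fixtures import reference_histogram_from_toy

    cache = {}

    def provider(sigma):
        if sigma not in cache:
            cache[sigma] = reference_histogram_from_toy(
                toy, dp.Apodization(sigma))
        return cache[sigma]

    return provider


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_small_reflections(n=8, d_min=2.5, spacegroup="P1"):
    """Tiny P1 reflection machinery for unit tests on 8^3-16^3 grids."""
    cell = dp.UnitCell(10.0, 10.0, 10.0)
    sg = dp.get_spacegroup(spacegroup)
    from dmphase.crystal_core import ReflectionData, generate_unique_reflections
    hkl = generate_unique_reflections(cell, sg, d_min)
    rng = np.random.default_rng(7)
    f = rng.uniform(1.0, 5.0, len(hkl))
    return ReflectionData(hkl, f, np.zeros(len(hkl)),
                          np.zeros(len(hkl), bool), cell, sg,
                          low_res_cutoff=None)
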