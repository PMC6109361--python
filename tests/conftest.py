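import numpy as np
import pytest

from mfsr.degrade import DegradeSpec, build_patchset, degrade_volume
from mfsr.network import ConvLayerSpec, MFCNSpec, mfu
from mfsr.phantom import PhantomSpec, make_cohort, make_phantom


@pytest.fixture(scope="session")
def default_spec():
    return PhantomSpec()


@pytest.fixture(scope="session")
def phantom(default_spec):
    return make_phantom(default_spec)


@pytest.fixture(scope="session")
def cohort(default_spec):
    return make_cohort(3, default_spec, seed=11)


@pytest.fixture(scope="session")
def slice_pairs(phantom):
    """Scale-2 degraded slice pairs of the default phantom."""
    return degrade_volume(phantom, DegradeSpec(factor=2))


@pytest.fixture(scope="session")
def mid_pair(slice_pairs):
    return slice_pairs[len(slice_pairs) // 2]


@pytest.fixture(scope="session")
def tiny_net_spec():
    """A small network exercising multi-layer sub-paths and all conv routes."""
    return MFCNSpec(
        units=(mfu("5/3", ["1/3"]), mfu("3/4", ["1/4", "1/4"])),
        recon=ConvLayerSpec(3, 1, relu=False),
    )


@pytest.fixture(scope="session")
def small_patchset(slice_pairs):
    return build_patchset(slice_pairs[:4], n_per_slice=40, patch_size=17, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
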