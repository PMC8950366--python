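import numpy as np
import pytest

from hemedist import LigandSpec, build_toy_complex


@pytest.fixture(scope="session")
def ligand_spec():
    return LigandSpec("OTA", "C4", "OTA")


@pytest.fixture(scope="session")
def toy_complex(ligand_spec):
    return build_toy_complex(30, ligand_spec, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
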