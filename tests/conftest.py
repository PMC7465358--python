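import pytest

from compret import RDKitBackend, RetroTemplate
from compret.fixtures import make_fig3a_network, make_fig3b_network
from compret.toy import ToyBackend


@pytest.fixture(scope="session")
def rdkit_backend():
    return RDKitBackend()


@pytest.fixture
def toy_backend():
    return ToyBackend()


@pytest.fixture
def fig3b():
    return make_fig3b_network()


@pytest.fixture
def fig3a():
    return make_fig3a_network()


@pytest.fixture(scope="session")
def ester_template():
    """Textbook ester-hydrolysis retro transform (ester -> acid + alcohol)."""
    return RetroTemplate(
        id="ester",
        name="ester hydrolysis",
        retro_transform="[C:1](=[O:2])[O:3][C:4]>>[C:1](=[O:2])[OH].[OH:3][C:4]",
        rank=1,
        frequency=100,
    )
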