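import pytest

from exoscreen import synthdata
from exoscreen.seqvariants import MIR1246, MotifWindow, RnaSequence


@pytest.fixture
def native():
    return RnaSequence("0", MIR1246)


@pytest.fixture
def window():
    return MotifWindow(12, 15, "GGAG")


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """One full synthetic input bundle shared by pipeline-level tests."""
    outdir = tmp_path_factory.mktemp("bundle")
    spec = synthdata.SynthSpec(seed=11)
    paths = synthdata.generate_bundle(spec, outdir)
    return spec, paths
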