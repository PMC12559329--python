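import pytest

from nickloop import LoopSpec, generate_plasmid, make_heteroduplex
from nickloop.pipeline import make_standard_substrate

CAG_LOOP = "CAG" * 4


@pytest.fixture(scope="session")
def small_substrate():
    """300-nt plasmid with a (CAG)4 top-strand loop at position 100."""
    plasmid = generate_plasmid(300, 0.5, seed=11, name="mini")
    return make_heteroduplex(plasmid, LoopSpec("top", 100, CAG_LOOP))


@pytest.fixture(scope="session")
def standard_substrate():
    """The 3.2 kb standard looped substrate used by the demo scenarios."""
    return make_standard_substrate()
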