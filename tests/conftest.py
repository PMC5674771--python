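import random

import pytest

from rnamct import ReferenceBackend, parse_dotbracket


@pytest.fixture
def reference_backend():
    return ReferenceBackend()


@pytest.fixture
def worked_target():
    """The 13-nt stem-loop used as the worked example throughout: three
    base pairs (2,13), (3,11), (4,10) and seven free bases."""
    return parse_dotbracket(".(((.....)).)")


@pytest.fixture
def hairpin_target():
    return parse_dotbracket("((((....))))")


@pytest.fixture
def rng():
    return random.Random(12345)
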