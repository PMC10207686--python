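import pytest

import bbereduce as bb


@pytest.fixture
def toy_chain():
    """3-variable network with x1/x2 backward-equivalent and a 110↔111 cycle."""
    return bb.fixture_toy_chain()


@pytest.fixture
def tlr5():
    """5-variable receptor cascade: TLR5 input feeding four genes."""
    return bb.fixture_tlr5_cascade()


@pytest.fixture
def four_steady():
    """3-variable network with 4 steady states, 2 surviving reduction."""
    return bb.fixture_four_steady_states()


@pytest.fixture
def tlr5_is_partition(tlr5):
    """Input-separated start: {{TLR5}, {TICAM1, MyD88, IRAK4, PIK3AP1}}."""
    return bb.input_separated_partition(tlr5)


@pytest.fixture
def merge_x1x2(toy_chain):
    return bb.canonical_partition([["x1", "x2"], ["x3"]], toy_chain.variables)
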