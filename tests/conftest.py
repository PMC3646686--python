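import pytest

from pathdissect import Network, fixtures


@pytest.fixture
def example_net():
    """The seven-node worked-example influence network with its annotation."""
    return fixtures.make_example_influence_network()


@pytest.fixture
def diamond():
    """A -> {B, C} -> D, all activating."""
    net = Network("diamond")
    for u, v in [("A", "B"), ("A", "C"), ("B", "D"), ("C", "D")]:
        net.add_edge(u, v, interaction="activates", sign=+1)
    return net


def make_chain(*node_ids, sign=+1):
    net = Network("chain")
    for u, v in zip(node_ids, node_ids[1:]):
        net.add_edge(u, v, interaction="activates" if sign > 0 else "inhibits", sign=sign)
    return net
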