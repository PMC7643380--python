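import numpy as np
import pytest

from longnet import ConnectivityLayer, MultilayerNetwork


def labels(n: int) -> list[str]:
    return [f"n{i:03d}" for i in range(n)]


def make_network(weight_stack, network_names=None) -> MultilayerNetwork:
    """Multilayer network from an (L, N, N) array; one network label for all
    nodes unless ``network_names`` gives per-node names."""
    stack = np.asarray(weight_stack, dtype=float)
    node_labels = labels(stack.shape[1])
    layers = [ConnectivityLayer(w, node_labels) for w in stack]
    if network_names is None:
        net_map = {n: "FPCN" for n in node_labels}
    else:
        net_map = dict(zip(node_labels, network_names))
    return MultilayerNetwork(layers, node_labels, net_map)


def random_network(n_nodes: int, n_layers: int, seed: int) -> MultilayerNetwork:
    """Dense symmetric uniform(0,1) weights, zero diagonal."""
    rng = np.random.default_rng(seed)
    stack = []
    for _ in range(n_layers):
        w = rng.uniform(0.0, 1.0, (n_nodes, n_nodes))
        w = (w + w.T) / 2.0
        np.fill_diagonal(w, 0.0)
        stack.append(w)
    return make_network(stack)


def planted_network(
    block_assignment,
    n_layers: int,
    seed: int,
    mu_within: float = 0.6,
    mu_between: float = 0.05,
    noise_sd: float = 0.02,
) -> MultilayerNetwork:
    """Same planted block structure repeated in every layer, noisy weights."""
    from longnet import layer_from_partition

    rng = np.random.default_rng(seed)
    g = np.asarray(block_assignment)
    node_labels = labels(g.shape[0])
    layers = [
        layer_from_partition(g, mu_within, mu_between, noise_sd, rng, node_labels)
        for _ in range(n_layers)
    ]
    return MultilayerNetwork(layers, node_labels, {n: "FPCN" for n in node_labels})


@pytest.fixture
def two_block_16node():
    return np.repeat([0, 1], 8)
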