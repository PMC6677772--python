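import numpy as np
import pytest

from neuritekit.morphology import NeuronNode, NeuronTree, read_swc


@pytest.fixture
def chain3() -> NeuronTree:
    """Straight 3-node chain along x."""
    return read_swc("1 1 0 0 0 1 -1\n2 3 1 0 0 1 1\n3 3 2 0 0 1 2\n")


@pytest.fixture
def ytree() -> NeuronTree:
    """Root chain 1-2-3 branching at 3 into tips 4 and 5."""
    return read_swc(
        "1 1 0 0 0 1 -1\n"
        "2 3 1 0 0 1 1\n"
        "3 3 2 0 0 1 2\n"
        "4 3 3 1 0 1 3\n"
        "5 3 3 -1 0 1 3\n"
    )


def random_tree(rng: np.random.Generator, n_nodes: int = 30) -> NeuronTree:
    """Random tree with arbitrary topology and coordinates (no geometry model)."""
    nodes = [NeuronNode(1, 1, *rng.uniform(0, 50, 3), float(rng.uniform(0.5, 2)), -1)]
    for i in range(2, n_nodes + 1):
        parent = int(rng.integers(1, i))
        nodes.append(
            NeuronNode(i, 3, *rng.uniform(0, 50, 3), float(rng.uniform(0.2, 2)), parent)
        )
    return NeuronTree(nodes)


def full_binary_tree(depth: int, step: float = 5.0) -> NeuronTree:
    """Soma, a trunk, then a full binary subtree: 2**depth tips.

    With t tips this yields t - 1 branch points and hence 2t - 1 segments.
    """
    nodes = [
        NeuronNode(1, 1, 0.0, 0.0, 0.0, 1.0, -1),
        NeuronNode(2, 3, step, 0.0, 0.0, 1.0, 1),
    ]
    next_id = 3
    frontier = [(2, step, 0.0)]  # (node id, x, y)
    for d in range(depth):
        new_frontier = []
        for pid, x, y in frontier:
            for dy in (step, -step):
                nid = next_id
                next_id += 1
                ny = y + dy / (d + 1)
                nodes.append(NeuronNode(nid, 3, x + step, ny, 0.0, 1.0, pid))
                new_frontier.append((nid, x + step, ny))
        frontier = new_frontier
    return NeuronTree(nodes)
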