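"""Shared fixtures: seeded RNGs and programmatically built tables/masks."""

import numpy as np
import pytest

from interreg import NetworkSpec, Node, NodeTable


@pytest.fixture
def rng():
    return np.random.default_rng(20230917)


def make_spec(n: int, name: str = "net") -> NetworkSpec:
    return NetworkSpec(name, tuple(f"r{i}" for i in range(n)))


def random_node_table(
    spec: NetworkSpec, rng: np.random.Generator, T: int = 50, subject: str = "s0"
) -> NodeTable:
    """A complete node table with independent random series and coordinates."""
    nodes = []
    for a, b in spec.ordered_pairs():
        nodes.append(
            Node(
                source_region=a,
                target_region=b,
                voxel=tuple(int(v) for v in rng.integers(0, 20, size=3)),
                score=float(rng.uniform(0, 10)),
                series=rng.standard_normal(T),
            )
        )
    return NodeTable(network_name=spec.network_name, subject_id=subject, nodes=nodes)


def constant_series_table(spec: NetworkSpec, T: int = 30) -> NodeTable:
    """Every node carries one identical series (degenerate maximum case)."""
    base = np.sin(np.linspace(0, 7, T))
    nodes = [
        Node(a, b, (0, 0, i), 1.0, base.copy())
        for i, (a, b) in enumerate(spec.ordered_pairs())
    ]
    return NodeTable(network_name=spec.network_name, subject_id="s0", nodes=nodes)
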