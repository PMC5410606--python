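"""Edge taxonomy and the four connectivity measures R1, R12, R2 and RI.

Once a network's nodes V_xy are identified, every pair of nodes defines an
edge e whose value is the Pearson correlation of the two node series.  In
the *context* of a region pair {a, b}, the (N-1)^2 edges running between
region a's nodes and region b's nodes partition into three classes:

* **primary** (1 edge): e(V_ab, V_ba) — both nodes were defined by the pair
  itself.  Its value is R1.
* **primary-secondary** (2(N-2) edges): e(V_ab, V_bi) and e(V_aj, V_ba) for
  third regions i, j — one endpoint is a primary node of the pair.  Their
  mean is R12.
* **secondary** ((N-2)^2 edges): e(V_aj, V_bi) with both endpoints defined
  by third regions.  Their mean is R2.

Edges within one region — among {V_ax : x != a} — are intra-regional; their
mean (default) or raw sum is RI.  Edge labels are a function of the network
alone: they never depend on the subject, and an edge that belongs to the
sets of context {a, b} carries no label in any other context.

The class counts give the conservation identity used as a self-check
throughout the test suite: the sum of all (N-1)^2 inter-region edge values
equals R1 + 2(N-2)*R12 + (N-2)^2*R2.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.spatial.distance import pdist

from .io_model import MeasureSet, NetworkSpec, NodeTable, RunConfig, pair_key
from .node_identification import pairwise_voxel_correlation

__all__ = [
    "EdgeClassification",
    "EdgeRecord",
    "classify_edges",
    "edge_records",
    "node_edge_matrix",
    "node_label",
    "EdgeValues",
    "r1",
    "r12",
    "r2",
    "r2_by_subtraction",
    "ri",
    "network_summary",
    "region_profile",
    "intra_region_node_distance",
]

NodeKey = tuple[str, str]
EdgeKey = tuple[NodeKey, NodeKey]


def _edge(k1: NodeKey, k2: NodeKey) -> EdgeKey:
    """Canonical (sorted) edge key; edges are unordered node pairs."""
    return (k1, k2) if k1 <= k2 else (k2, k1)


@dataclass(frozen=True)
class EdgeClassification:
    """The edge sets of one region-pair context {a, b}."""

    context: tuple[str, str]
    primary: tuple[EdgeKey, ...]
    primary_secondary: tuple[EdgeKey, ...]
    secondary: tuple[EdgeKey, ...]

    def all_inter(self) -> tuple[EdgeKey, ...]:
        return self.primary + self.primary_secondary + self.secondary


def classify_edges(spec: NetworkSpec) -> dict[tuple[str, str], EdgeClassification]:
    """Enumerate the primary / primary-secondary / secondary edge sets for
    every unordered region-pair context of the network.

    For every context the three sets partition all (N-1)^2 node pairs
    between the two regions, with cardinalities 1, 2(N-2) and (N-2)^2.
    """
    out: dict[tuple[str, str], EdgeClassification] = {}
    for a, b in spec.unordered_pairs():
        others = [r for r in spec.regions if r not in (a, b)]
        primary = (_edge((a, b), (b, a)),)
        prim_sec = tuple(_edge((a, b), (b, i)) for i in others) + tuple(
            _edge((a, j), (b, a)) for j in others
        )
        secondary = tuple(_edge((a, j), (b, i)) for j in others for i in others)
        out[pair_key(a, b)] = EdgeClassification(
            context=pair_key(a, b),
            primary=primary,
            primary_secondary=prim_sec,
            secondary=secondary,
        )
    return out


@dataclass(frozen=True)
class EdgeRecord:
    """One node-pair correlation with its class label per region-pair context.

    Labels depend only on the network, never on the subject: in the context
    of its own region pair an inter-region edge is ``R1``, ``R12`` or
    ``R2``; within one region it is ``RI``; in every other context it
    carries no label (``none``).
    """

    node1: NodeKey
    node2: NodeKey
    r: float
    labels: dict  # context pair -> "R1" | "R12" | "R2" | "RI" | "none"


def edge_records(table: NodeTable, spec: NetworkSpec) -> list[EdgeRecord]:
    """All unordered node-pair edges of a table with values and labels."""
    ev = EdgeValues(table)
    cls = classify_edges(spec)
    label_of: dict[EdgeKey, dict] = {}
    for ctx, c in cls.items():
        for name, edges in (("R1", c.primary), ("R12", c.primary_secondary),
                            ("R2", c.secondary)):
            for e in edges:
                label_of.setdefault(e, {})[ctx] = name
    for region in spec.regions:
        for e in intra_edges(spec, region):
            label_of.setdefault(e, {})[region] = "RI"
    records = []
    keys = [n.key for n in table.nodes]
    for i, k1 in enumerate(keys):
        for k2 in keys[i + 1:]:
            e = _edge(k1, k2)
            labels = dict(label_of.get(e, {}))
            for ctx in cls:
                labels.setdefault(ctx, "none")
            records.append(EdgeRecord(e[0], e[1], ev.value(k1, k2), labels))
    return records


def intra_edges(spec: NetworkSpec, region: str) -> tuple[EdgeKey, ...]:
    """The (N-1)(N-2)/2 unordered pairs among region ``region``'s own nodes."""
    if region not in spec.regions:
        raise KeyError(f"unknown region {region!r}")
    keys = [(region, x) for x in spec.regions if x != region]
    return tuple(_edge(k1, k2) for k1, k2 in combinations(keys, 2))


def node_label(key: NodeKey) -> str:
    return f"{key[0]}->{key[1]}"


def node_edge_matrix(table: NodeTable) -> tuple[list[str], np.ndarray]:
    """Full node-by-node Pearson correlation matrix of one node table.

    Returns ``(labels, matrix)`` with labels ``"x->y"`` in table order; the
    matrix is symmetric with unit diagonal.
    """
    if len(table) < 2:
        raise ValueError("need at least 2 nodes")
    S = np.vstack([n.series for n in table.nodes])
    C = pairwise_voxel_correlation(S, S)
    C = (C + C.T) / 2.0
    np.fill_diagonal(C, 1.0)
    return [node_label(n.key) for n in table.nodes], C


class EdgeValues:
    """Edge-value lookup backed by the node-by-node correlation matrix."""

    def __init__(self, table: NodeTable):
        self.table = table
        self.labels, self.matrix = node_edge_matrix(table)
        self._index = {n.key: i for i, n in enumerate(table.nodes)}

    def value(self, k1: NodeKey, k2: NodeKey) -> float:
        try:
            i, j = self._index[k1], self._index[k2]
        except KeyError as e:
            raise KeyError(f"missing node {e.args[0]} in table") from None
        return float(self.matrix[i, j])

    def mean_over(self, edges: tuple[EdgeKey, ...]) -> float:
        return float(np.mean([self.value(k1, k2) for k1, k2 in edges]))

    def sum_over(self, edges: tuple[EdgeKey, ...]) -> float:
        return float(np.sum([self.value(k1, k2) for k1, k2 in edges]))


def r1(edges: EdgeValues, a: str, b: str) -> float:
    """Primary connectivity: the single edge e(V_ab, V_ba)."""
    return edges.value((a, b), (b, a))


def r12(edges: EdgeValues, spec: NetworkSpec, a: str, b: str) -> float:
    """Primary-to-secondary connectivity: mean of the 2(N-2) edges joining a
    primary node of {a, b} to a secondary node of the other region."""
    cls = classify_edges(spec)[pair_key(a, b)]
    return edges.mean_over(cls.primary_secondary)


def r2(edges: EdgeValues, spec: NetworkSpec, a: str, b: str) -> float:
    """Secondary connectivity: mean of the (N-2)^2 edges joining secondary
    nodes of the two regions."""
    cls = classify_edges(spec)[pair_key(a, b)]
    return edges.mean_over(cls.secondary)


def r2_by_subtraction(edges: EdgeValues, spec: NetworkSpec, a: str, b: str) -> float:
    """R2 computed as (total inter-region correlation − primary −
    primary-secondary sums) / (N-2)^2 — algebraically identical to
    :func:`r2` and kept as an internal cross-check."""
    cls = classify_edges(spec)[pair_key(a, b)]
    n2 = spec.n - 2
    total = edges.sum_over(cls.all_inter())
    return (total - edges.sum_over(cls.primary) - edges.sum_over(cls.primary_secondary)) / n2**2


def ri(edges: EdgeValues, spec: NetworkSpec, a: str, mode: str = "mean") -> float:
    """Intra-regional connectivity over the (N-1)(N-2)/2 node pairs of one
    region: their mean (default, comparable in scale to R1/R12/R2) or their
    raw sum."""
    pairs = intra_edges(spec, a)
    if mode == "mean":
        return edges.mean_over(pairs)
    if mode == "raw_sum":
        return edges.sum_over(pairs)
    raise ValueError("mode must be 'mean' or 'raw_sum'")


def network_summary(
    table: NodeTable, spec: NetworkSpec, config: RunConfig | None = None
) -> MeasureSet:
    """Compute every per-pair and per-region measure plus network averages."""
    config = config or RunConfig()
    table.validate_complete(spec)
    edges = EdgeValues(table)
    r1d, r12d, r2d = {}, {}, {}
    for a, b in spec.unordered_pairs():
        k = pair_key(a, b)
        r1d[k] = r1(edges, a, b)
        r12d[k] = r12(edges, spec, a, b)
        r2d[k] = r2(edges, spec, a, b)
    rid = {a: ri(edges, spec, a, mode=config.ri_mode) for a in spec.regions}
    return MeasureSet(
        network_name=spec.network_name,
        subject_id=table.subject_id,
        r1=r1d,
        r12=r12d,
        r2=r2d,
        ri=rid,
        ri_mode=config.ri_mode,
    )


def region_profile(region: str, measures: MeasureSet, spec: NetworkSpec) -> dict[str, float]:
    """Per-region breakdown of each measure.

    For R1/R12/R2 the profile is the mean over the N-1 region pairs that
    contain ``region`` (pair-level averaging); for RI it is the region's own
    intra-regional value.
    """
    if region not in spec.regions:
        raise KeyError(f"unknown region {region!r}")
    pairs = [pair_key(region, x) for x in spec.regions if x != region]
    return {
        "R1": float(np.mean([measures.r1[k] for k in pairs])),
        "R12": float(np.mean([measures.r12[k] for k in pairs])),
        "R2": float(np.mean([measures.r2[k] for k in pairs])),
        "RI": measures.ri[region],
    }


def intra_region_node_distance(region: str, table: NodeTable) -> float:
    """Mean Euclidean distance, in voxel units, between the nodes of one
    region, over all unordered node pairs."""
    coords = np.array([n.voxel for n in table.nodes if n.source_region == region], dtype=float)
    if len(coords) < 2:
        raise ValueError(f"fewer than 2 nodes in region {region!r}")
    return float(pdist(coords).mean())
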