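"""Per-node network features, keystone potential and modularity clustering.

Keystone potential condenses three unweighted-topology features into one
score per taxon:

    KP = (relative node degree * local transitivity) / betweenness centrality

High KP marks nodes that are locally well embedded (their neighbors are
mutually connected) while carrying little shortest-path brokerage — the
signature reported for putative keystone taxa in co-occurrence networks.
A taxon is called a keystone when its KP exceeds median + f * MAD of the
KP distribution over all prevalent taxa (default f = 5, unscaled MAD).

Feature topology uses every consensus edge regardless of sign; community
clustering runs greedy (Clauset-Newman-Moore) modularity maximization on
the positive subnetwork with mean correlation strengths as weights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .consensus import ConsensusNetwork, positive_subnetwork

__all__ = [
    "NodeFeatures",
    "NetworkSummary",
    "KeystoneCall",
    "KeystoneCalls",
    "ClusterAssignment",
    "node_features",
    "keystone_potential",
    "call_keystones",
    "network_summary",
    "cluster_positive_network",
    "write_node_features",
]


@dataclass
class NodeFeatures:
    taxon: str
    degree: int
    nd: float  # degree / n_nodes
    t: float  # local transitivity; nan when degree < 2
    t_defined: bool
    bc: float  # unnormalized shortest-path betweenness
    cc: float  # closeness within the reachable component
    kp: float = math.nan


@dataclass
class NetworkSummary:
    modularity: float  # Newman weighted modularity of the partition (positive net)
    cohesion: int  # vertex connectivity of the largest connected component


@dataclass
class KeystoneCall:
    taxon: str
    kp: float
    cutoff: float
    is_keystone: bool


@dataclass
class KeystoneCalls:
    cutoff: float
    calls: list[KeystoneCall]

    @property
    def keystones(self) -> list[str]:
        return [c.taxon for c in self.calls if c.is_keystone]


@dataclass
class ClusterAssignment:
    assignments: dict[str, int]
    n_clusters: int

    def members(self, cluster: int) -> list[str]:
        return [t for t, c in self.assignments.items() if c == cluster]


def _topology(net: ConsensusNetwork) -> nx.Graph:
    """Unweighted simple graph over all consensus edges, sign ignored."""
    g = nx.Graph()
    g.add_nodes_from(net.graph.nodes)
    g.add_edges_from(net.graph.edges)
    return g


def node_features(net: ConsensusNetwork) -> dict[str, NodeFeatures]:
    """Degree, relative degree, local transitivity, betweenness, closeness.

    Relative node degree is degree / (total number of nodes).  Local
    transitivity (clustering coefficient) is undefined for degree < 2 and
    flagged as such.  Betweenness is unnormalized shortest-path counts
    with even splitting over equal-length paths; closeness is computed
    within each node's reachable component.
    """
    g = _topology(net)
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    n = g.number_of_nodes()
    clustering = nx.clustering(g)
    bc = nx.betweenness_centrality(g, normalized=False)
    cc = nx.closeness_centrality(g, wf_improved=False)
    out: dict[str, NodeFeatures] = {}
    for node in g.nodes:
        deg = g.degree(node)
        defined = deg >= 2
        out[node] = NodeFeatures(
            taxon=node,
            degree=deg,
            nd=deg / n,
            t=float(clustering[node]) if defined else math.nan,
            t_defined=defined,
            bc=float(bc[node]),
            cc=float(cc[node]),
        )
    return out


def keystone_potential(features: dict[str, NodeFeatures]) -> dict[str, float]:
    """KP = (nd * t) / bc with finite-value floor rules, filled in place.

    Nodes with degree < 2 have undefined transitivity and get KP = 0.
    A zero betweenness is replaced by half the smallest positive
    betweenness in the network, keeping KP finite while preserving the
    ranking; if no node has positive betweenness all KP are set to 0.
    """
    positive_bc = [f.bc for f in features.values() if f.bc > 0]
    floor = min(positive_bc) / 2.0 if positive_bc else None
    kps: dict[str, float] = {}
    for taxon, f in features.items():
        if not f.t_defined or floor is None:
            kp = 0.0
        else:
            bc_eff = f.bc if f.bc > 0 else floor
            kp = (f.nd * f.t) / bc_eff
        f.kp = kp
        kps[taxon] = kp
    return kps


def call_keystones(
    kps: dict[str, float], mad_factor: float = 5.0
) -> KeystoneCalls:
    """Robust-outlier keystone calls: KP > median + mad_factor * MAD.

    MAD is the unscaled median absolute deviation (no normal-consistency
    constant); the comparison is strict, so a constant KP distribution
    yields no keystones.
    """
    values = np.array(list(kps.values()), dtype=float)
    if values.size == 0 or not np.isfinite(values).any():
        raise ValueError("need at least one finite keystone potential")
    med = float(np.median(values))
    mad = float(np.median(np.abs(values - med)))
    cutoff = med + mad_factor * mad
    calls = [
        KeystoneCall(taxon=t, kp=v, cutoff=cutoff, is_keystone=v > cutoff)
        for t, v in kps.items()
    ]
    return KeystoneCalls(cutoff=cutoff, calls=calls)


def network_summary(
    net: ConsensusNetwork, partition: ClusterAssignment
) -> NetworkSummary:
    """Weighted modularity of the partition and cohesion of the network.

    Modularity is Newman's weighted modularity of ``partition`` on the
    positive subnetwork (weights = mean_rho); an edgeless positive
    network is assigned modularity 0.  Cohesion is the vertex
    connectivity of the largest connected component of the sign-ignored
    graph.
    """
    pos = positive_subnetwork(net).graph
    missing = [node for node in pos.nodes if node not in partition.assignments]
    if missing:
        raise ValueError(f"partition does not cover nodes: {missing[:5]}")
    for u, v, d in pos.edges(data=True):
        d["weight"] = d["mean_rho"]
    if pos.number_of_edges() == 0:
        modularity = 0.0
    else:
        communities: dict[int, set[str]] = {}
        for node, c in partition.assignments.items():
            if node in pos:
                communities.setdefault(c, set()).add(node)
        modularity = float(
            nx.community.modularity(pos, list(communities.values()), weight="weight")
        )
    full = _topology(net)
    if full.number_of_nodes() == 0:
        cohesion = 0
    else:
        lcc = max(nx.connected_components(full), key=len)
        sub = full.subgraph(lcc)
        cohesion = int(nx.node_connectivity(sub)) if sub.number_of_nodes() > 1 else 0
    return NetworkSummary(modularity=modularity, cohesion=cohesion)


def cluster_positive_network(net: ConsensusNetwork) -> ClusterAssignment:
    """Greedy modularity (Clauset-Newman-Moore) clusters of the positive net.

    Uses mean correlation strength as edge weight.  Isolated nodes form
    singleton clusters.  Cluster ids are assigned by decreasing size,
    ties broken by the lexicographically smallest member, so the labeling
    is deterministic.
    """
    pos = positive_subnetwork(net).graph
    for u, v, d in pos.edges(data=True):
        d["weight"] = d["mean_rho"]
    if pos.number_of_edges() == 0:
        comms = [{node} for node in pos.nodes]
    else:
        comms = [
            set(c)
            for c in nx.community.greedy_modularity_communities(pos, weight="weight")
        ]
    comms.sort(key=lambda c: (-len(c), min(c)))
    assignments = {node: i for i, c in enumerate(comms) for node in c}
    return ClusterAssignment(assignments=assignments, n_clusters=len(comms))


def write_node_features(
    features: dict[str, NodeFeatures],
    calls: KeystoneCalls | None,
    clusters: ClusterAssignment | None,
    path: str | Path,
) -> None:
    """Per-node TSV: taxon, degree, nd, t, bc, cc, kp, is_keystone, cluster."""
    keystone = {c.taxon: c.is_keystone for c in calls.calls} if calls else {}
    rows = []
    for taxon, f in features.items():
        rows.append(
            {
                "taxon": taxon,
                "degree": f.degree,
                "nd": f.nd,
                "t": f.t,
                "bc": f.bc,
                "cc": f.cc,
                "kp": f.kp,
                "is_keystone": keystone.get(taxon, False),
                "cluster": clusters.assignments.get(taxon) if clusters else None,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
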