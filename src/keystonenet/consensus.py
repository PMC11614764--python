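"""Consensus correlation networks from repeated subsampling.

A single correlation network from one dataset is fragile: edges can hinge
on a handful of samples.  The workflow here draws many random subsamples
(without replacement), estimates a SparCC correlation matrix plus
permutation p-values on each, and keeps only edges that are significant
(p <= alpha) in at least a required number of runs.  The consensus edge
weight is the mean correlation strength over exactly the runs in which
the edge was significant.  All prevalent taxa remain as nodes, so taxa
without any robust correlation appear as isolated nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .profiles import AbundanceTable
from .sparcc import SparccParams, permutation_pvalues, sparcc

__all__ = [
    "NetworkRun",
    "ConsensusNetwork",
    "run_subsamples",
    "build_consensus",
    "positive_subnetwork",
    "write_edge_list",
    "read_edge_list",
    "write_graphml",
]


@dataclass
class NetworkRun:
    """Correlation matrix and p-values estimated on one subsample."""

    run_index: int
    sample_ids: list[str]
    taxa: list[str]
    rho: np.ndarray
    p: np.ndarray


@dataclass
class ConsensusNetwork:
    """Undirected signed weighted graph of robustly significant correlations.

    Edge attributes: ``mean_rho`` (mean correlation strength over the runs
    in which the edge was significant) and ``support`` (number of such
    runs).  Nodes are all prevalent taxa, including isolated ones.
    """

    graph: nx.Graph
    provenance: dict = field(default_factory=dict)

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges(self) -> list[tuple[str, str, float, int]]:
        return [
            (u, v, d["mean_rho"], d["support"])
            for u, v, d in self.graph.edges(data=True)
        ]


def run_subsamples(
    table: AbundanceTable,
    n_runs: int = 1000,
    subsample_size: int = 50,
    params: SparccParams | None = None,
    seed: int | None = None,
) -> list[NetworkRun]:
    """Estimate rho and permutation p-values on repeated random subsamples.

    Each run draws ``subsample_size`` samples uniformly without
    replacement and runs SparCC plus its permutation null on the globally
    prevalent taxon set (taxa absent from a particular draw are handled
    by the Dirichlet pseudocount).  Per-run random streams are spawned
    from one seed, so results do not depend on execution order.
    """
    params = params or SparccParams()
    if subsample_size > table.n_samples:
        raise ValueError(
            f"subsample_size {subsample_size} exceeds {table.n_samples} samples"
        )
    root = np.random.SeedSequence(seed)
    children = root.spawn(n_runs)
    runs: list[NetworkRun] = []
    for r, child in enumerate(children):
        rng = np.random.default_rng(child)
        idx = rng.choice(table.n_samples, size=subsample_size, replace=False)
        sample_ids = [table.sample_ids[i] for i in idx]
        counts = table.counts[idx]
        est = sparcc(counts, params, seed=rng.integers(2**31))
        est.taxa = table.taxon_labels
        pv = permutation_pvalues(counts, est, params, seed=rng.integers(2**31))
        runs.append(
            NetworkRun(
                run_index=r,
                sample_ids=sample_ids,
                taxa=table.taxon_labels,
                rho=est.rho,
                p=pv.p,
            )
        )
    return runs


def build_consensus(
    runs: list[NetworkRun],
    alpha: float = 0.05,
    min_support: int | None = None,
    min_support_fraction: float = 0.20,
) -> ConsensusNetwork:
    """Assemble the consensus network from per-subsample runs.

    An edge is kept iff it attains p <= alpha (inclusive) in at least
    ``min_support`` runs (inclusive; default ceil(0.20 * n_runs), so the
    canonical 1000-run setting requires 200).  Its weight is the mean rho
    over exactly the significant runs.  Invariant under run order.
    """
    if not runs:
        raise ValueError("need at least one run")
    n_runs = len(runs)
    if min_support is None:
        min_support = int(np.ceil(min_support_fraction * n_runs))
    taxa = runs[0].taxa
    rho = np.stack([r.rho for r in runs])
    p = np.stack([r.p for r in runs])
    sig = p <= alpha
    support = sig.sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean_rho = np.where(
            support > 0, (rho * sig).sum(axis=0) / np.maximum(support, 1), 0.0
        )
    g = nx.Graph()
    g.add_nodes_from(taxa)
    d = len(taxa)
    iu, ju = np.triu_indices(d, k=1)
    for i, j in zip(iu, ju):
        if support[i, j] >= min_support:
            g.add_edge(
                taxa[i],
                taxa[j],
                mean_rho=float(mean_rho[i, j]),
                support=int(support[i, j]),
            )
    provenance = {
        "n_runs": n_runs,
        "subsample_size": len(runs[0].sample_ids),
        "alpha": alpha,
        "min_support": int(min_support),
    }
    return ConsensusNetwork(graph=g, provenance=provenance)


def positive_subnetwork(net: ConsensusNetwork) -> ConsensusNetwork:
    """Keep only edges with strictly positive mean correlation strength."""
    g = nx.Graph()
    g.add_nodes_from(net.graph.nodes)
    for u, v, d in net.graph.edges(data=True):
        if d["mean_rho"] > 0:
            g.add_edge(u, v, **d)
    prov = dict(net.provenance)
    prov["sign"] = "positive"
    return ConsensusNetwork(graph=g, provenance=prov)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def write_edge_list(net: ConsensusNetwork, path: str | Path) -> None:
    """Edge-list TSV (taxon_a, taxon_b, mean_rho, support) plus a node list.

    Isolated nodes are preserved in a sibling ``.nodes.tsv`` file so the
    full node set round-trips.
    """
    path = Path(path)
    rows = [
        {"taxon_a": u, "taxon_b": v, "mean_rho": d["mean_rho"], "support": d["support"]}
        for u, v, d in net.graph.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["taxon_a", "taxon_b", "mean_rho", "support"]).to_csv(
        path, sep="\t", index=False
    )
    nodes_path = path.with_suffix(path.suffix + ".nodes.tsv")
    pd.DataFrame({"taxon": net.nodes}).to_csv(nodes_path, sep="\t", index=False)


def read_edge_list(path: str | Path) -> ConsensusNetwork:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    g = nx.Graph()
    nodes_path = path.with_suffix(path.suffix + ".nodes.tsv")
    if nodes_path.exists():
        g.add_nodes_from(pd.read_csv(nodes_path, sep="\t")["taxon"].astype(str))
    for _, row in df.iterrows():
        g.add_edge(
            str(row["taxon_a"]),
            str(row["taxon_b"]),
            mean_rho=float(row["mean_rho"]),
            support=int(row["support"]),
        )
    return ConsensusNetwork(graph=g)


def write_graphml(net: ConsensusNetwork, path: str | Path) -> None:
    g = net.graph.copy()
    for u, v, d in g.edges(data=True):
        d["weight"] = d["mean_rho"]
    nx.write_graphml(g, path)
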