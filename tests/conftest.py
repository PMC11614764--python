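import networkx as nx
import numpy as np
import pytest

from keystonenet.consensus import ConsensusNetwork
from keystonenet.lineage import TaxonLineage
from keystonenet.profiles import AbundanceTable


def make_network(edges, nodes=None) -> ConsensusNetwork:
    """Build a ConsensusNetwork from (u, v, mean_rho[, support]) tuples."""
    g = nx.Graph()
    if nodes:
        g.add_nodes_from(nodes)
    for edge in edges:
        u, v, rho = edge[:3]
        support = edge[3] if len(edge) > 3 else 1
        g.add_edge(u, v, mean_rho=float(rho), support=int(support))
    return ConsensusNetwork(graph=g)


def species_lineage(genus: str, species: str) -> TaxonLineage:
    return TaxonLineage.from_string(
        f"k__Bacteria|p__P|c__C|o__O|f__F|g__{genus}|s__{genus}_{species}"
    )


@pytest.fixture
def small_table() -> AbundanceTable:
    """4 samples x 4 species spanning two genera."""
    taxa = [
        species_lineage("Alpha", "one"),
        species_lineage("Alpha", "two"),
        species_lineage("Beta", "one"),
        species_lineage("Beta", "two"),
    ]
    counts = np.array(
        [
            [10, 5, 0, 3],
            [0, 7, 2, 1],
            [4, 0, 0, 9],
            [8, 2, 6, 0],
        ]
    )
    return AbundanceTable(["s1", "s2", "s3", "s4"], taxa, counts, "species")
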