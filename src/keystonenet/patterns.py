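"""Sign structure and neighborhood statistics of consensus networks.

These analyses probe the ecological reading of the networks: the balance
of positive vs negative correlations overall and within vs between
genera, how first neighbors of keystone taxa differ from other taxa, and
whether a stronger keystone-to-genus correlation predicts weaker
correlations among that genus's species (the "dampening" regression).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .consensus import ConsensusNetwork
from .lineage import TaxonLineage

__all__ = [
    "SignSummary",
    "GenusSignPartition",
    "NeighborStats",
    "RegressionResult",
    "sign_fractions",
    "within_between_genus",
    "keystone_neighbor_stats",
    "keystone_genus_regression",
    "genus_of",
]


@dataclass
class SignSummary:
    scope: str
    n_edges: int
    fraction_positive: float
    fraction_negative: float


@dataclass
class GenusSignPartition:
    within: SignSummary
    between: SignSummary
    per_genus_within: dict[str, tuple[float, int]]  # genus -> (mean |rho|, n species)


@dataclass
class NeighborStats:
    group: str
    n_nodes: int
    mean_degree: float  # nan when the group is empty
    mean_abs_rho: float


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    p_value: float
    adj_r_squared: float
    n_points: int


def _signed_edges(net: ConsensusNetwork, nodes: set[str] | None = None):
    for u, v, d in net.graph.edges(data=True):
        if d["mean_rho"] == 0:
            continue  # an exact zero carries no sign information
        if nodes is not None and u not in nodes and v not in nodes:
            continue
        yield u, v, d["mean_rho"]


def sign_fractions(
    net: ConsensusNetwork, node_subset: list[str] | None = None, scope: str = "all"
) -> SignSummary:
    """Fractions of positive and negative edges (in scope, zeros excluded).

    With ``node_subset`` given, only edges incident to at least one node
    of the subset are counted.
    """
    nodes = set(node_subset) if node_subset is not None else None
    signs = [rho > 0 for _, _, rho in _signed_edges(net, nodes)]
    if not signs:
        raise ValueError(f"no signed edges in scope {scope!r}")
    n = len(signs)
    pos = sum(signs) / n
    return SignSummary(
        scope=scope, n_edges=n, fraction_positive=pos, fraction_negative=1.0 - pos
    )


def genus_of(label: str) -> str | None:
    """Genus name encoded in a pipe-delimited taxon label, if resolvable."""
    try:
        return TaxonLineage.from_string(label).genus
    except Exception:
        return None


def within_between_genus(
    species_net: ConsensusNetwork, genus_map: dict[str, str] | None = None
) -> GenusSignPartition:
    """Partition species-level edges by shared genus; summarize each side.

    ``genus_map`` maps node label -> genus; by default the genus is read
    from the lineage-encoded node labels.  Also reports, per genus with
    at least one within-genus edge, the mean absolute correlation
    strength of those edges and the genus size (number of species nodes).
    """
    if genus_map is None:
        genus_map = {n: genus_of(n) for n in species_net.nodes}
    genus_sizes: dict[str, int] = {}
    for n in species_net.nodes:
        g = genus_map.get(n)
        if g is not None:
            genus_sizes[g] = genus_sizes.get(g, 0) + 1
    within_signs: list[bool] = []
    between_signs: list[bool] = []
    per_genus: dict[str, list[float]] = {}
    for u, v, rho in _signed_edges(species_net):
        gu, gv = genus_map.get(u), genus_map.get(v)
        if gu is not None and gu == gv:
            within_signs.append(rho > 0)
            per_genus.setdefault(gu, []).append(abs(rho))
        else:
            between_signs.append(rho > 0)

    def _summary(signs: list[bool], scope: str) -> SignSummary:
        if not signs:
            return SignSummary(scope, 0, math.nan, math.nan)
        pos = sum(signs) / len(signs)
        return SignSummary(scope, len(signs), pos, 1.0 - pos)

    per_genus_within = {
        g: (float(np.mean(vals)), genus_sizes.get(g, 0))
        for g, vals in per_genus.items()
    }
    return GenusSignPartition(
        within=_summary(within_signs, "within-genus"),
        between=_summary(between_signs, "between-genus"),
        per_genus_within=per_genus_within,
    )


def keystone_neighbor_stats(
    net: ConsensusNetwork, keystones: list[str]
) -> tuple[NeighborStats, NeighborStats]:
    """Compare first neighbors of keystones with the remaining taxa.

    Non-keystone nodes are split into those adjacent to at least one
    keystone and the rest.  Each group reports its mean degree and the
    mean |rho| of its incident edges; edges touching a keystone are
    excluded from the |rho| average so the keystone's own couplings do
    not confound the comparison.  Empty groups are flagged with NaN
    means rather than raising.
    """
    if not keystones:
        raise ValueError("need at least one keystone")
    kset = set(keystones)
    g = net.graph
    neighbors = {v for k in kset if k in g for v in g.neighbors(k)} - kset
    rest = set(g.nodes) - kset - neighbors

    def _stats(group: set[str], name: str) -> NeighborStats:
        if not group:
            return NeighborStats(name, 0, math.nan, math.nan)
        degs = [g.degree(n) for n in group]
        rhos = [
            abs(d["mean_rho"])
            for n in group
            for _, v, d in g.edges(n, data=True)
            if v not in kset
        ]
        return NeighborStats(
            name,
            len(group),
            float(np.mean(degs)),
            float(np.mean(rhos)) if rhos else math.nan,
        )

    return _stats(neighbors, "keystone-first-neighbors"), _stats(rest, "other-taxa")


def keystone_genus_regression(
    genus_net: ConsensusNetwork,
    species_net: ConsensusNetwork,
    genus_keystones: list[str],
    species_genus_map: dict[str, str] | None = None,
    genus_name_map: dict[str, str] | None = None,
) -> RegressionResult:
    """OLS of within-genus correlation strength on keystone edge strength.

    For every edge from a keystone genus to a non-keystone genus g that
    has at least one within-genus species edge, pairs x = |mean_rho| of
    the keystone-genus edge with y = mean |rho| of g's within-genus
    species edges (one point per keystone-genus edge).  Fits y = a + b x
    by ordinary least squares and returns the slope, its two-sided
    p-value and the adjusted R^2.
    """
    if species_genus_map is None:
        species_genus_map = {n: genus_of(n) for n in species_net.nodes}
    if genus_name_map is None:
        genus_name_map = {n: genus_of(n) for n in genus_net.nodes}
    within = within_between_genus(species_net, species_genus_map).per_genus_within
    kset = set(genus_keystones)
    xs: list[float] = []
    ys: list[float] = []
    for u, v, rho in _signed_edges(genus_net):
        if (u in kset) == (v in kset):
            continue  # need exactly one keystone endpoint
        other = v if u in kset else u
        gname = genus_name_map.get(other) or other
        if gname not in within:
            continue
        xs.append(abs(rho))
        ys.append(within[gname][0])
    if len(xs) < 3:
        raise ValueError(f"regression needs >= 3 points, got {len(xs)}")
    x = sm.add_constant(np.asarray(xs))
    fit = sm.OLS(np.asarray(ys), x).fit()
    return RegressionResult(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        p_value=float(fit.pvalues[1]),
        adj_r_squared=float(fit.rsquared_adj),
        n_points=len(xs),
    )
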