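"""Topology metrics, degree-distribution fit and module detection.

All metrics operate on the undirected, unweighted skeleton of a network
(edge presence only; negative edges included).  Diameter and average
separation are computed on the largest connected component.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
from networkx.algorithms.community import greedy_modularity_communities, modularity
from scipy import stats

from coocnet.io_model import (
    AbundanceTable,
    CooccurrenceNetwork,
    UNCLASSIFIED,
    rank_of,
)


@dataclass
class TopologyReport:
    edge_count: int
    diameter: float          # nan for empty/edgeless networks
    clustering_coefficient: float
    average_separation: float
    mean_betweenness: float
    modularity: float
    module_assignment: dict[str, int] = field(default_factory=dict)
    n_components: int = 0
    largest_component_size: int = 0


def _skeleton(net: CooccurrenceNetwork | nx.Graph) -> nx.Graph:
    graph = net.graph if isinstance(net, CooccurrenceNetwork) else net
    g = nx.Graph()
    g.add_nodes_from(sorted(graph.nodes))
    g.add_edges_from(sorted((min(a, b), max(a, b)) for a, b in graph.edges))
    return g


def topology_report(net: CooccurrenceNetwork | nx.Graph) -> TopologyReport:
    """Scalar topology metrics and the greedy-modularity partition.

    Betweenness is the unnormalized vertex betweenness (count of shortest
    paths through each vertex, unordered pairs).  Modules come from greedy
    agglomerative modularity maximization; determinism is ensured by feeding
    vertices and edges in sorted order.
    """
    g = _skeleton(net)
    m = g.number_of_edges()
    if m == 0:
        return TopologyReport(0, float("nan"), 0.0, float("nan"), 0.0, 0.0,
                              {v: 0 for v in g.nodes}, 0, 0)
    components = sorted(nx.connected_components(g), key=lambda c: (-len(c), sorted(c)))
    lcc = g.subgraph(components[0])
    communities = greedy_modularity_communities(g)
    q = modularity(g, communities)
    assignment = {
        v: idx
        for idx, comm in enumerate(sorted(communities, key=lambda c: sorted(c)))
        for v in comm
    }
    betweenness = nx.betweenness_centrality(g, normalized=False)
    return TopologyReport(
        edge_count=m,
        diameter=float(nx.diameter(lcc)),
        clustering_coefficient=float(nx.transitivity(g)),
        average_separation=float(nx.average_shortest_path_length(lcc)),
        mean_betweenness=float(np.mean(list(betweenness.values()))),
        modularity=float(q),
        module_assignment=assignment,
        n_components=len(components),
        largest_component_size=len(components[0]),
    )


def scale_free_fit(net: CooccurrenceNetwork | nx.Graph) -> tuple[float, float, float]:
    """OLS fit of log10(degree frequency) on log10(degree).

    Returns ``(r_squared, p_value, slope)``; a power-law degree distribution
    gives a straight line with negative slope.  With a single distinct
    degree (regular graph) the fit is undefined and a nan triple is
    returned.
    """
    g = _skeleton(net)
    degrees = np.array([d for _, d in g.degree if d > 0])
    values, counts = np.unique(degrees, return_counts=True)
    if values.size < 2:
        return (float("nan"), float("nan"), float("nan"))
    x, y = np.log10(values), np.log10(counts)
    if values.size == 2:
        # two points determine a line exactly; no residual to test
        slope = (y[1] - y[0]) / (x[1] - x[0])
        return (1.0, float("nan"), float(slope))
    fit = stats.linregress(x, y)
    return (float(fit.rvalue ** 2), float(fit.pvalue), float(fit.slope))


def abundance_degree_association(
    net: CooccurrenceNetwork,
    table: AbundanceTable | None = None,
) -> tuple[float, float]:
    """Spearman correlation between vertex degree and mean relative abundance.

    Abundances come from the vertex ``mean_abundance`` attribute, or from
    ``table`` when given.  Returns ``(rho, p)``; ``nan`` pair when either
    variable is constant.
    """
    g = net.graph
    if g.number_of_nodes() < 3:
        raise ValueError("need at least 3 vertices")
    vertices = sorted(g.nodes)
    degrees = [g.degree[v] for v in vertices]
    if table is not None:
        mean_abund = table.mean_relative_abundance()
        abundances = [mean_abund.get(v, 0.0) for v in vertices]
    else:
        abundances = [g.nodes[v].get("mean_abundance", 0.0) for v in vertices]
    if len(set(degrees)) < 2 or len(set(abundances)) < 2:
        return (float("nan"), float("nan"))
    rho, p = stats.spearmanr(degrees, abundances)
    return (float(rho), float(p))


def module_composition(
    net: CooccurrenceNetwork,
    taxonomy: Mapping[str, Sequence[str]] | None = None,
    module_assignment: Mapping[str, int] | None = None,
    rank: str = "class",
    top_n_modules: int = 8,
) -> dict:
    """Per-module taxon (class-level) and environment profiles.

    Returns a dict with per-module relative taxon composition, per-module
    environment vertex fractions, module sizes ranked descending, and the
    fraction of vertices covered by the ``top_n_modules`` largest modules.
    """
    if module_assignment is None:
        module_assignment = topology_report(net).module_assignment
    modules: dict[int, list[str]] = {}
    for v, m in module_assignment.items():
        modules.setdefault(m, []).append(v)

    def lineage_label(v: str) -> str:
        if taxonomy and v in taxonomy:
            return rank_of(taxonomy[v], rank)
        tax = net.graph.nodes.get(v, {}).get("taxonomy", UNCLASSIFIED)
        parts = str(tax).split(";")
        from coocnet.io_model import TAXONOMIC_RANKS
        idx = TAXONOMIC_RANKS.index(rank)
        return parts[idx] if idx < len(parts) and parts[idx] else UNCLASSIFIED

    taxon_profiles: dict[int, dict[str, float]] = {}
    env_profiles: dict[int, dict[str, float]] = {}
    for m, members in modules.items():
        labels = [lineage_label(v) for v in members]
        taxon_profiles[m] = {
            lab: labels.count(lab) / len(labels) for lab in sorted(set(labels))
        }
        env_counts: dict[str, int] = {}
        for v in members:
            for env in net.graph.nodes.get(v, {}).get("environments", ()):
                env_counts[env] = env_counts.get(env, 0) + 1
        env_profiles[m] = {
            env: c / len(members) for env, c in sorted(env_counts.items())
        }
    sizes = sorted(((m, len(vs)) for m, vs in modules.items()),
                   key=lambda t: (-t[1], t[0]))
    total = sum(s for _, s in sizes)
    covered = sum(s for _, s in sizes[:top_n_modules])
    return {
        "taxon_profiles": taxon_profiles,
        "environment_profiles": env_profiles,
        "module_sizes": sizes,
        "top_modules_vertex_fraction": covered / total if total else float("nan"),
    }
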