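"""Generalist/specialist edge ecology across environment subnetworks.

An edge present in two or more subnetworks is a *generalist* edge; an edge
present in exactly one subnetwork is a *specialist* edge, subdivided by
whether both its endpoint vertices appear (as network vertices) in at least
two subnetworks (specialist edge linking a generalist vertex pair) or not
(specialist edge linking a specialist vertex pair).  The module also
implements omission scores (how much one environment's samples drive an
edge's correlation), Jaccard environment similarity, hub detection and
clustering, and negative-edge profiling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from coocnet.io_model import (
    AbundanceTable,
    CooccurrenceNetwork,
    canonical_pair,
    rank_of,
)
from coocnet.netinfer import _rowwise_spearman, bh_adjust, spearman_score

GENERALIST = "generalist"
SPECIALIST_GENERALIST_PAIR = "specialist_generalist_pair"
SPECIALIST_SPECIALIST_PAIR = "specialist_specialist_pair"
EDGE_CLASSES = (GENERALIST, SPECIALIST_GENERALIST_PAIR, SPECIALIST_SPECIALIST_PAIR)


# ---------------------------------------------------------------------------
# edge classification
# ---------------------------------------------------------------------------

@dataclass
class EdgeClassification:
    #: per canonical edge: class label
    class_of: dict[tuple[str, str], str]
    #: per canonical edge: environments whose subnetwork contains it
    environments_of: dict[tuple[str, str], tuple[str, ...]]
    #: per subnetwork: proportion of each class among its edges
    proportions: dict[str, dict[str, float]]


def classify_edges(
    subnets: Mapping[str, CooccurrenceNetwork]
) -> EdgeClassification:
    """Classify every edge of the union of subnetworks.

    A vertex is *general* when it appears as a network vertex in >= 2
    subnetworks.  Per-subnetwork class proportions are reported over each
    subnetwork's own edges.
    """
    if len(subnets) < 2:
        raise ValueError("need at least 2 subnetworks")
    vertex_envs: dict[str, set[str]] = {}
    edge_envs: dict[tuple[str, str], set[str]] = {}
    for env, net in subnets.items():
        for v in net.graph.nodes:
            vertex_envs.setdefault(v, set()).add(env)
        for a, b in net.graph.edges:
            edge_envs.setdefault(canonical_pair(a, b), set()).add(env)

    class_of: dict[tuple[str, str], str] = {}
    for key, envs in edge_envs.items():
        if len(envs) >= 2:
            class_of[key] = GENERALIST
        elif all(len(vertex_envs[v]) >= 2 for v in key):
            class_of[key] = SPECIALIST_GENERALIST_PAIR
        else:
            class_of[key] = SPECIALIST_SPECIALIST_PAIR

    proportions: dict[str, dict[str, float]] = {}
    for env, net in subnets.items():
        keys = [canonical_pair(a, b) for a, b in net.graph.edges]
        total = len(keys)
        proportions[env] = {
            cls: (sum(1 for k in keys if class_of[k] == cls) / total if total else 0.0)
            for cls in EDGE_CLASSES
        }
    return EdgeClassification(
        class_of=class_of,
        environments_of={k: tuple(sorted(v)) for k, v in edge_envs.items()},
        proportions=proportions,
    )


# ---------------------------------------------------------------------------
# omission scores
# ---------------------------------------------------------------------------

@dataclass
class OmissionResult:
    edge: tuple[str, str]
    environment: str
    original_rho: float
    omission_rho: float
    ratio: float            # |omission_rho| / |original_rho|
    p: float
    p_adjusted: float = float("nan")
    local: bool = False


def omission_score(
    table: AbundanceTable,
    edge: tuple[str, str],
    environment: str,
    n_random: int = 1000,
    seed: int = 0,
) -> OmissionResult:
    """Quantify how much one environment's samples drive an edge's correlation.

    The omission score (OS) is the Spearman correlation of the pair's
    relative abundances over all samples *except* the environment's.  The
    ratio |OS| / |original rho| measures environmental dependence, and the
    nonparametric p-value is the fraction of ``n_random`` random same-sized
    sample removals whose |OS| is strictly smaller than the environment's
    |OS| (ties count against locality).  The ``local`` flag combines
    ``ratio < 1`` with BH-adjusted p < 0.05 and is set by the caller after
    adjustment (:func:`omission_analysis`).
    """
    index = {e: i for i, e in enumerate(table.esv_ids)}
    try:
        i, j = index[edge[0]], index[edge[1]]
    except KeyError as exc:
        raise KeyError(f"edge ESV {exc.args[0]!r} not in pooled table") from None
    env_mask = np.array(
        [table.environment_of.get(s) == environment for s in table.sample_ids]
    )
    group_size = int(env_mask.sum())
    if group_size == 0:
        raise ValueError(f"environment {environment!r} has no samples")
    n = table.n_samples
    if n - group_size < 3:
        raise ValueError("removal leaves fewer than 3 samples")

    rel = table.relative_abundance()
    x, y = rel[i], rel[j]
    original = spearman_score(x, y)
    if not np.isfinite(original) or original == 0:
        return OmissionResult(canonical_pair(*edge), environment, float(original),
                              float("nan"), float("nan"), float("nan"))
    omission = spearman_score(x[~env_mask], y[~env_mask])
    group_os = abs(omission)

    rng = np.random.default_rng(seed)
    keep_size = n - group_size
    keep_x = np.empty((n_random, keep_size))
    keep_y = np.empty((n_random, keep_size))
    for r in range(n_random):
        keep = rng.choice(n, size=keep_size, replace=False)
        keep_x[r] = x[keep]
        keep_y[r] = y[keep]
    random_os = np.abs(_rowwise_spearman(keep_x, keep_y))
    p = float(np.sum(random_os < group_os)) / n_random
    return OmissionResult(
        edge=canonical_pair(*edge),
        environment=environment,
        original_rho=float(original),
        omission_rho=float(omission),
        ratio=group_os / abs(original),
        p=p,
    )


def omission_analysis(
    table: AbundanceTable,
    edges_with_envs: Sequence[tuple[tuple[str, str], str]],
    n_random: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> list[OmissionResult]:
    """Omission scores for a batch of (edge, environment) queries, BH-adjusted.

    An edge/environment pair is flagged ``local`` (region-specific) when its
    ratio is below 1 and its BH-adjusted p-value is below ``alpha``.
    """
    results = [
        omission_score(table, edge, env, n_random=n_random, seed=seed + k)
        for k, (edge, env) in enumerate(edges_with_envs)
    ]
    defined = [r for r in results if np.isfinite(r.p)]
    if defined:
        adjusted = bh_adjust([r.p for r in defined])
        for r, padj in zip(defined, adjusted):
            r.p_adjusted = float(padj)
            r.local = bool(r.ratio < 1.0 and r.p_adjusted < alpha)
    return results


# ---------------------------------------------------------------------------
# environment similarity
# ---------------------------------------------------------------------------

def jaccard_distance(a: set, b: set) -> float:
    union = a | b
    if not union:
        return 0.0
    return 1.0 - len(a & b) / len(union)


def environment_similarity(
    subnets: Mapping[str, CooccurrenceNetwork]
) -> tuple[list[str], np.ndarray, dict[str, int]]:
    """Jaccard distances between subnetwork edge sets + two-group clustering.

    Returns ``(environment order, distance matrix, environment -> group)``
    with groups from an average-linkage hierarchical clustering cut at two
    clusters.  An edgeless subnetwork is at distance 1 from every other.
    """
    if len(subnets) < 2:
        raise ValueError("need at least 2 subnetworks")
    envs = sorted(subnets)
    sets = {env: subnets[env].edge_keys() for env in envs}
    k = len(envs)
    dist = np.zeros((k, k))
    for a in range(k):
        for b in range(a + 1, k):
            sa, sb = sets[envs[a]], sets[envs[b]]
            d = 1.0 if (not sa or not sb) else jaccard_distance(sa, sb)
            dist[a, b] = dist[b, a] = d
    z = linkage(squareform(dist, checks=False), method="average")
    groups = fcluster(z, t=2, criterion="maxclust")
    return envs, dist, {env: int(g) for env, g in zip(envs, groups)}


# ---------------------------------------------------------------------------
# edge-type taxon profiles and correlations
# ---------------------------------------------------------------------------

def edge_type_taxa_profile(
    classification: EdgeClassification,
    table: AbundanceTable,
    taxonomy: Mapping[str, Sequence[str]] | None = None,
    top_n: int = 50,
    rank: str = "class",
) -> dict[str, dict]:
    """Per-edge-class profiles of the ``top_n`` most abundant endpoint ESVs.

    Endpoint ESVs of each class's edges are ranked by mean relative
    abundance (ties broken by ESV id); the taxon composition of the kept set
    is tabulated at the requested rank.
    """
    mean_abund = table.mean_relative_abundance()
    out: dict[str, dict] = {}
    for cls in EDGE_CLASSES:
        members = sorted({
            v for key, c in classification.class_of.items() if c == cls for v in key
        })
        ranked = sorted(members, key=lambda v: (-mean_abund.get(v, 0.0), v))[:top_n]
        comp: dict[str, int] = {}
        for v in ranked:
            label = rank_of(taxonomy[v], rank) if taxonomy and v in taxonomy else "unclassified"
            comp[label] = comp.get(label, 0) + 1
        out[cls] = {"top_esvs": ranked, "taxon_counts": dict(sorted(comp.items()))}
    return out


def edge_type_correlations(
    proportions: Mapping[str, Mapping[str, float]],
    edge_counts: Mapping[str, int] | None = None,
) -> dict[tuple[str, str], tuple[float, float]]:
    """Pairwise Spearman correlations between per-subnetwork class proportions.

    Also correlates each class proportion with the subnetwork edge count
    when ``edge_counts`` is given.  Requires >= 4 subnetworks; a constant
    vector yields a nan entry.
    """
    envs = sorted(proportions)
    if len(envs) < 4:
        raise ValueError("need at least 4 subnetworks")
    series: dict[str, list[float]] = {
        cls: [proportions[e][cls] for e in envs] for cls in EDGE_CLASSES
    }
    if edge_counts is not None:
        series["edge_count"] = [float(edge_counts[e]) for e in envs]
    names = list(series)
    out: dict[tuple[str, str], tuple[float, float]] = {}
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            xa, xb = series[names[a]], series[names[b]]
            if len(set(xa)) < 2 or len(set(xb)) < 2:
                out[(names[a], names[b])] = (float("nan"), float("nan"))
            else:
                rho, p = stats.spearmanr(xa, xb)
                out[(names[a], names[b])] = (float(rho), float(p))
    return out


# ---------------------------------------------------------------------------
# hubs
# ---------------------------------------------------------------------------

def identify_hubs(net: CooccurrenceNetwork, k: int = 10) -> list[str]:
    """The ``k`` highest-degree vertices (ties at the boundary broken by id)."""
    if net.n_vertices == 0:
        raise ValueError("empty network")
    ranked = sorted(net.graph.degree, key=lambda t: (-t[1], t[0]))
    return [v for v, _ in ranked[:k]]


def hub_presence_clustering(
    hubs_per_subnet: Mapping[str, Sequence[str]]
) -> dict:
    """Hub x subnetwork presence matrix, two-group clustering, specialist hubs.

    Subnetworks are clustered by average linkage on Jaccard distances of
    their hub sets; hubs present in exactly one subnetwork are *specialist
    hubs*.
    """
    if len(hubs_per_subnet) < 2:
        raise ValueError("need at least 2 subnetworks")
    envs = sorted(hubs_per_subnet)
    all_hubs = sorted({h for hubs in hubs_per_subnet.values() for h in hubs})
    presence = np.array([
        [1 if h in set(hubs_per_subnet[e]) else 0 for e in envs] for h in all_hubs
    ], dtype=int)
    k = len(envs)
    dist = np.zeros((k, k))
    for a in range(k):
        for b in range(a + 1, k):
            d = jaccard_distance(set(hubs_per_subnet[envs[a]]),
                                 set(hubs_per_subnet[envs[b]]))
            dist[a, b] = dist[b, a] = d
    z = linkage(squareform(dist, checks=False), method="average")
    groups = fcluster(z, t=2, criterion="maxclust")
    specialist = [h for h, row in zip(all_hubs, presence) if row.sum() == 1]
    return {
        "hubs": all_hubs,
        "environments": envs,
        "presence": presence,
        "distance": dist,
        "groups": {e: int(g) for e, g in zip(envs, groups)},
        "specialist_hubs": specialist,
    }


# ---------------------------------------------------------------------------
# negative edges
# ---------------------------------------------------------------------------

def negative_edge_profile(
    subnets: Mapping[str, CooccurrenceNetwork],
    taxonomy: Mapping[str, Sequence[str]] | None = None,
    rank: str = "class",
) -> dict[str, dict]:
    """Counts, percentages and endpoint-class composition of negative edges.

    The composition counts *both* endpoints of every negative edge at the
    requested rank.  A subnetwork without edges gets a nan percentage.
    """
    out: dict[str, dict] = {}
    for env in sorted(subnets):
        net = subnets[env]
        total = net.n_edges
        negatives = [
            canonical_pair(a, b)
            for a, b, d in net.graph.edges(data=True)
            if d.get("sign", 0) < 0
        ]
        comp: dict[str, int] = {}
        for key in negatives:
            for v in key:
                label = (rank_of(taxonomy[v], rank)
                         if taxonomy and v in taxonomy else "unclassified")
                comp[label] = comp.get(label, 0) + 1
        out[env] = {
            "n_edges": total,
            "n_negative": len(negatives),
            "percentage": (100.0 * len(negatives) / total) if total else float("nan"),
            "composition": dict(sorted(comp.items())),
        }
    return out
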