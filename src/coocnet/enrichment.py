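"""Overrepresentation statistics for taxon-pair edge counts.

The urn model for taxon-pair overrepresentation: the population is the set
of all unordered vertex pairs of the network (``N``), the success states are
the pairs with one endpoint in taxon A and one in taxon B (``K``; for
``A = B`` the pairs within A), ``n`` edges are drawn, and the upper-tail
hypergeometric probability of the ``k`` observed A-B edges tests edge
placement against a uniform null conditional on network size.  This null
does not condition on the degree sequence.  Mutual-exclusion (negative-edge)
overrepresentation within a taxon pair is a binomial upper tail with the
network-wide negative-edge frequency as background.  Adjustment uses the
Benjamini-Yekutieli (BY) procedure.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from coocnet.io_model import CooccurrenceNetwork, UNCLASSIFIED, rank_of


@dataclass
class PairEnrichment:
    taxon_a: str
    taxon_b: str
    observed_edges: int        # k
    possible_pairs: int        # K
    total_edges: int           # n
    total_possible_pairs: int  # N
    p: float
    p_lower: float             # under-representation (lower tail)
    p_adjusted: float = float("nan")


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if k > K:
        raise ValueError(f"observed {k} exceeds possible pairs {K} (bookkeeping bug)")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def taxon_pair_overrepresentation(
    net: CooccurrenceNetwork,
    taxonomy: Mapping[str, Sequence[str]] | None = None,
    rank: str = "class",
    adjust: bool = True,
) -> list[PairEnrichment]:
    """Hypergeometric overrepresentation of edges between taxon labels.

    Every vertex is mapped to its label at ``rank`` (``unclassified`` when
    missing).  Only label pairs with at least one observed edge or at least
    one possible pair are reported; BY adjustment is applied to the
    upper-tail p-values.
    """
    vertices = sorted(net.graph.nodes)
    if not vertices:
        return []

    def label(v: str) -> str:
        if taxonomy and v in taxonomy:
            return rank_of(taxonomy[v], rank)
        tax = str(net.graph.nodes[v].get("taxonomy", UNCLASSIFIED)).split(";")
        from coocnet.io_model import TAXONOMIC_RANKS
        idx = TAXONOMIC_RANKS.index(rank)
        return tax[idx] if idx < len(tax) and tax[idx] else UNCLASSIFIED

    labels = {v: label(v) for v in vertices}
    sizes: dict[str, int] = {}
    for lab in labels.values():
        sizes[lab] = sizes.get(lab, 0) + 1
    V = len(vertices)
    N = comb(V, 2)
    n_edges = net.n_edges

    observed: dict[tuple[str, str], int] = {}
    for a, b in net.graph.edges:
        la, lb = sorted((labels[a], labels[b]))
        observed[(la, lb)] = observed.get((la, lb), 0) + 1

    results: list[PairEnrichment] = []
    label_list = sorted(sizes)
    for ai, la in enumerate(label_list):
        for lb in label_list[ai:]:
            K = (comb(sizes[la], 2) if la == lb else sizes[la] * sizes[lb])
            if K == 0:
                continue
            k = observed.get((la, lb), 0)
            results.append(PairEnrichment(
                taxon_a=la, taxon_b=lb,
                observed_edges=k, possible_pairs=K,
                total_edges=n_edges, total_possible_pairs=N,
                p=hypergeom_upper_tail(k, N, K, n_edges),
                p_lower=float(stats.hypergeom.cdf(k, N, K, n_edges)),
            ))
    if adjust and results:
        adjusted = by_adjust([r.p for r in results])
        for r, padj in zip(results, adjusted):
            r.p_adjusted = float(padj)
    return results


def exclusion_copresence_test(m: int, k: int, background_q: float) -> tuple[float, float]:
    """Binomial test of mutual exclusion vs co-presence within a taxon pair.

    ``m`` edges between the pair's taxa, of which ``k`` are negative;
    ``background_q`` is the network-wide negative-edge frequency.  Returns
    ``(p_exclusion, p_copresence)``: the upper tail P(X >= k) tests
    exclusion overrepresentation, the lower tail P(X <= k) tests co-presence
    overrepresentation.
    """
    if not 0 <= k <= m:
        raise ValueError("need 0 <= k <= m")
    if not 0.0 <= background_q <= 1.0:
        raise ValueError("background frequency must be in [0, 1]")
    upper = float(stats.binom.sf(k - 1, m, background_q))
    lower = float(stats.binom.cdf(k, m, background_q))
    return upper, lower


def by_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Yekutieli step-up adjustment (harmonic-sum inflation, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    return multipletests(p, method="fdr_by")[1]
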