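"""Gene-set over-representation and enrichment-map clustering.

Each gene set is tested with a hypergeometric upper tail
P(X ≥ k), X ~ Hypergeom(N, K, n) for k of the n identified genes falling
in a set of size K within a universe of N; p-values are BH-corrected
across all sets in the query.  Enriched sets passing FDR and p cutoffs
become nodes of an enrichment map whose edges connect sets with member
Jaccard similarity ≥ 0.25; connected components are the reported
clusters.  The signed odds-ratio score (k/K)/(n/N) is negated for sets
enriched in a decreasing-direction query so up- and down-responses can
share one axis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io_formats import GeneSetCollection


@dataclass
class GeneSetEnrichmentResult:
    """One gene set's over-representation test."""

    set_name: str
    overlap: int  # k
    set_size: int  # K
    identified_size: int  # n
    universe_size: int  # N
    p_value: float
    q_value: float = float("nan")
    odds_ratio_score: float = float("nan")
    direction: str = "increasing"
    members: frozenset[str] = frozenset()
    overlap_genes: frozenset[str] = frozenset()


def hypergeom_enrich(
    identified: Iterable[str],
    gene_sets: GeneSetCollection,
    universe: Iterable[str] | None = None,
    direction: str = "increasing",
) -> list[GeneSetEnrichmentResult]:
    """Hypergeometric over-representation of ``identified`` in every set.

    The universe defaults to the collection's own; sets are restricted to
    it and identified genes outside it are dropped.  The upper tail
    includes k itself, so k = 0 gives p = 1.
    """
    uni = frozenset(universe) if universe is not None else gene_sets.universe
    restricted = gene_sets.restrict(uni)
    ident = frozenset(identified) & uni
    N, n = len(uni), len(ident)
    results = []
    for name in sorted(restricted.sets):
        members = restricted.sets[name]
        K = len(members)
        hits = members & ident
        k = len(hits)
        p = 1.0 if n == 0 else float(hypergeom.sf(k - 1, N, K, n))
        score = odds_ratio_score(k, K, n, N, direction) if n else float("nan")
        results.append(
            GeneSetEnrichmentResult(
                set_name=name,
                overlap=k,
                set_size=K,
                identified_size=n,
                universe_size=N,
                p_value=p,
                odds_ratio_score=score,
                direction=direction,
                members=members,
                overlap_genes=hits,
            )
        )
    if results:
        qs = multipletests([r.p_value for r in results], method="fdr_bh")[1]
        for r, q in zip(results, qs):
            r.q_value = float(q)
    return results


def odds_ratio_score(k: int, K: int, n: int, N: int, direction: str) -> float:
    """(k/K) / (n/N), negated when the query is the decreasing direction."""
    if n <= 0 or N <= 0 or K <= 0:
        raise ValueError("K, n and N must be positive")
    score = (k / K) / (n / N)
    return -score if direction == "decreasing" else score


def jaccard(a: frozenset[str], b: frozenset[str]) -> float:
    if not a and not b:
        return 0.0
    return len(a & b) / len(a | b)


@dataclass
class EnrichmentMapGraph:
    """Enriched sets as nodes, Jaccard-similar pairs as edges."""

    graph: nx.Graph
    clusters: dict[str, int]  # set_name → component label

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str, float]]:
        return sorted((min(u, v), max(u, v), d["jaccard"]) for u, v, d in self.graph.edges(data=True))


def build_enrichment_map(
    results: Sequence[GeneSetEnrichmentResult],
    fdr_cutoff: float = 0.01,
    p_cutoff: float = 0.005,
    jaccard_cutoff: float = 0.25,
) -> EnrichmentMapGraph:
    """Filter enriched sets and connect those sharing members.

    Nodes are results with q < ``fdr_cutoff`` and p < ``p_cutoff``; edges
    join pairs with member Jaccard ≥ ``jaccard_cutoff``; clusters are the
    connected components, labelled numerically in sorted-node order.
    """
    passing = [r for r in results if r.q_value < fdr_cutoff and r.p_value < p_cutoff]
    g = nx.Graph()
    for r in passing:
        g.add_node(r.set_name, q=r.q_value, p=r.p_value, score=r.odds_ratio_score)
    for i, a in enumerate(passing):
        for b in passing[i + 1 :]:
            j = jaccard(a.members, b.members)
            if j >= jaccard_cutoff:
                g.add_edge(a.set_name, b.set_name, jaccard=j)
    clusters: dict[str, int] = {}
    for label, component in enumerate(
        sorted(nx.connected_components(g), key=lambda c: sorted(c)), start=1
    ):
        for node in component:
            clusters[node] = label
    return EnrichmentMapGraph(graph=g, clusters=clusters)
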