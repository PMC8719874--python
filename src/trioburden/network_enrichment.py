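"""Deleteriousness-stratified interaction-network enrichment.

Genes hit by de novo or transmitted-mosaic mutations are partitioned by
their best deleteriousness score at the conventional scaled-score cutoff of
15 (top ~3% of possible substitutions), and each partition is tested for an
excess of interaction edges among its members on a user-supplied network.
The null distribution of the edge count comes from resampling node sets of
equal size - either uniformly, or matched on degree (quintile bins) to
respect the tendency of well-studied hub genes to interact. Connected
components of the induced subgraph give the reported clusters, and a mean
coding-length check guards against long genes driving cluster membership.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .genome import GeneModel


def cadd_scaled_score(rank_fraction: float) -> float:
    """Scaled deleteriousness score: -10 * log10(rank fraction).

    The top 10% of ranked substitutions scores 10, the top 1% scores 20,
    the top 0.1% scores 30.
    """
    if not 0.0 < rank_fraction <= 1.0:
        raise ValueError("rank fraction must be in (0, 1]")
    return -10.0 * float(np.log10(rank_fraction))


@dataclass(frozen=True)
class GeneHit:
    """A mutated gene carrying its best score and mutation multiplicity."""

    gene: str
    score: float
    multiplicity: int = 1


def partition_by_deleteriousness(
    mutations: Iterable[tuple[str, float]], threshold: float = 15.0
) -> tuple[list[GeneHit], list[GeneHit]]:
    """Split mutated genes into high/low deleteriousness sets.

    Each gene appears once, carrying the maximum score over its mutations
    and the mutation count as multiplicity; scores strictly above the
    threshold go to the high set.
    """
    best: dict[str, GeneHit] = {}
    for gene, score in mutations:
        prev = best.get(gene)
        if prev is None:
            best[gene] = GeneHit(gene, float(score), 1)
        else:
            best[gene] = GeneHit(gene, max(prev.score, float(score)), prev.multiplicity + 1)
    high = sorted((h for h in best.values() if h.score > threshold), key=lambda h: h.gene)
    low = sorted((h for h in best.values() if h.score <= threshold), key=lambda h: h.gene)
    return high, low


@dataclass(frozen=True)
class EdgeEnrichmentResult:
    hit_set_size: int
    observed_edges: int
    expected_edges: float
    p_value: float
    n_permutations: int
    null_model: str
    seed: int
    dropped_genes: tuple[str, ...] = ()


def _degree_bins(graph: nx.Graph, n_bins: int = 5) -> dict[str, int]:
    """Assign every node a degree-quintile bin index."""
    nodes = sorted(graph.nodes)
    degrees = np.array([graph.degree[n] for n in nodes])
    order = np.argsort(degrees, kind="stable")
    bins = np.empty(len(nodes), dtype=int)
    bins[order] = np.minimum(np.arange(len(nodes)) * n_bins // max(len(nodes), 1), n_bins - 1)
    return {n: int(b) for n, b in zip(nodes, bins)}


def count_induced_edges(graph: nx.Graph, nodes: Iterable[str]) -> int:
    node_set = set(nodes)
    return sum(1 for a, b in graph.edges(node_set) if a in node_set and b in node_set)


def edge_enrichment(
    graph: nx.Graph,
    hit_set: Iterable[str],
    n_permutations: int = 9_999,
    null: str = "degree-matched",
    seed: int = 0,
) -> EdgeEnrichmentResult:
    """Permutation test for an excess of edges among a hit set.

    Observed = edges with both endpoints in the hit set. The null resamples
    node sets of the same size, uniformly or within degree-quintile bins;
    p = (1 + #{null >= observed}) / (n_permutations + 1), so p is never 0
    and has resolution 1/(n_permutations+1).
    """
    if null not in ("uniform", "degree-matched"):
        raise ValueError("null must be 'uniform' or 'degree-matched'")
    if n_permutations < 999:
        raise ValueError("use at least 999 permutations")
    hits = sorted(set(hit_set))
    dropped = tuple(h for h in hits if h not in graph)
    hits = [h for h in hits if h in graph]
    if len(hits) > graph.number_of_nodes():
        raise ValueError("hit set larger than the node set")
    observed = count_induced_edges(graph, hits)
    rng = np.random.default_rng(seed)
    nodes = sorted(graph.nodes)
    k = len(hits)
    if k < 2 or graph.number_of_edges() == 0:
        return EdgeEnrichmentResult(
            hit_set_size=k, observed_edges=observed, expected_edges=0.0, p_value=1.0,
            n_permutations=n_permutations, null_model=null, seed=seed, dropped_genes=dropped,
        )

    if null == "degree-matched":
        bins = _degree_bins(graph)
        by_bin: dict[int, list[str]] = {}
        for n in nodes:
            by_bin.setdefault(bins[n], []).append(n)
        need = {b: 0 for b in by_bin}
        for h in hits:
            need[bins[h]] += 1

        def draw() -> list[str]:
            sample: list[str] = []
            for b, cnt in need.items():
                if cnt:
                    sample.extend(rng.choice(by_bin[b], size=cnt, replace=False))
            return sample
    else:

        def draw() -> list[str]:
            return list(rng.choice(nodes, size=k, replace=False))

    null_counts = np.empty(n_permutations, dtype=np.int64)
    for i in range(n_permutations):
        null_counts[i] = count_induced_edges(graph, draw())
    p = (1.0 + int((null_counts >= observed).sum())) / (n_permutations + 1.0)
    return EdgeEnrichmentResult(
        hit_set_size=k,
        observed_edges=observed,
        expected_edges=float(null_counts.mean()),
        p_value=p,
        n_permutations=n_permutations,
        null_model=null,
        seed=seed,
        dropped_genes=dropped,
    )


def extract_clusters(
    graph: nx.Graph, hit_set: Iterable[str], min_size: int = 3
) -> list[list[str]]:
    """Connected components of the hit-set-induced subgraph, size >= min_size.

    Ordered by size descending, ties broken lexicographically by the
    smallest member symbol; members are sorted within each cluster.
    """
    sub = graph.subgraph([h for h in set(hit_set) if h in graph])
    clusters = [sorted(c) for c in nx.connected_components(sub) if len(c) >= min_size]
    clusters.sort(key=lambda c: (-len(c), c[0]))
    return clusters


def cluster_length_check(
    clusters: Sequence[Sequence[str]],
    genes: Mapping[str, GeneModel],
) -> list[float]:
    """Mean coding length per cluster, in kilobases.

    Members without a gene model are excluded with a warning-style skip (a
    cluster with no modelled member yields NaN).
    """
    means: list[float] = []
    for cluster in clusters:
        lengths = [genes[g].coding_length for g in cluster if g in genes]
        means.append(float(np.mean(lengths)) / 1000.0 if lengths else float("nan"))
    return means
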