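"""Link communities over the consistent/emergent pair network.

Edges of the phenotype network are clustered hierarchically on the
inclusive-neighborhood Jaccard similarity of adjacent edges; the dendrogram
is cut at the height maximizing the partition density

    D = (2 / M) * sum_c m_c * (m_c - (n_c - 1)) / ((n_c - 2) * (n_c - 1)),

where m_c and n_c are a community's edge and node counts (the term is 0 when
n_c = 2).  Node memberships may overlap; edge communities partition the edge
set.  Clusters are then filtered for functional coherence (>= theta of a
cluster's phenotypes share evidence for one FunSys) and checked for disease
overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .cohort_io import DiseaseAnnotations
from .funsys_enrichment import EnrichmentRecord, PairFunSysLabel

logger = logging.getLogger(__name__)

Edge = tuple[str, str]


@dataclass
class LinkCommunitySolution:
    communities: list[frozenset[Edge]]
    M: int
    D: float
    cut_height: float

    def community_nodes(self, i: int) -> frozenset[str]:
        return frozenset(n for e in self.communities[i] for n in e)

    def sizes(self) -> list[tuple[int, int]]:
        """(m_c, n_c) per community."""
        return [(len(c), len({n for e in c for n in e})) for c in self.communities]


@dataclass
class CoherentCluster:
    cluster_id: str
    phenotypes: frozenset[str]
    m_c: int
    coherent_funsys: dict[str, float]  # funsys -> coverage fraction
    theta: float
    diseases: dict[str, int] = field(default_factory=dict)  # disease -> missing count

    @property
    def is_coherent(self) -> bool:
        return bool(self.coherent_funsys)

    @property
    def overlaps_disease(self) -> bool:
        return bool(self.diseases)


def _canonical_edge(e: Edge) -> Edge:
    a, b = e
    return (a, b) if a <= b else (b, a)


def edge_similarity(graph: nx.Graph, e1: Edge, e2: Edge) -> float:
    """Inclusive-neighborhood Jaccard similarity of two adjacent edges.

    For edges (i, k), (j, k) sharing node k, S = |n+(i) & n+(j)| / |n+(i) | n+(j)|
    with n+(x) = {x} + neighbors(x).  Non-adjacent edges have similarity 0.
    """
    s1, s2 = set(e1), set(e2)
    shared = s1 & s2
    if len(shared) == 2:
        raise ValueError("parallel edges are not allowed (simple graph required)")
    if len(shared) != 1:
        return 0.0
    (i,) = s1 - shared
    (j,) = s2 - shared
    ni = {i} | set(graph.neighbors(i))
    nj = {j} | set(graph.neighbors(j))
    return len(ni & nj) / len(ni | nj)


def partition_density(communities: Sequence[frozenset[Edge]], M: int) -> float:
    total = 0.0
    for c in communities:
        m = len(c)
        n = len({x for e in c for x in e})
        if n <= 2:
            continue
        total += m * (m - (n - 1)) / ((n - 2) * (n - 1))
    return (2.0 / M) * total


def link_communities(
    graph: nx.Graph, method: str = "average"
) -> LinkCommunitySolution:
    """Cluster the graph's edges and cut at maximum partition density.

    Average linkage by default; ``method='single'`` is available.  When two
    cut heights tie on D, the lower (finer) cut wins.
    """
    edges = sorted(_canonical_edge(e) for e in graph.edges())
    M = len(edges)
    if M < 2:
        raise ValueError("link clustering requires at least 2 edges")
    dist = np.ones((M, M))
    np.fill_diagonal(dist, 0.0)
    # adjacency via shared nodes: only adjacent edge pairs can have S > 0
    incident: dict[str, list[int]] = {}
    for i, e in enumerate(edges):
        for n in e:
            incident.setdefault(n, []).append(i)
    nbr_cache = {n: {n} | set(graph.neighbors(n)) for n in graph.nodes}
    for node, idxs in incident.items():
        for a_pos in range(len(idxs)):
            for b_pos in range(a_pos + 1, len(idxs)):
                i, j = idxs[a_pos], idxs[b_pos]
                (x,) = set(edges[i]) - {node}
                (y,) = set(edges[j]) - {node}
                if x == y:  # parallel edges cannot occur in nx.Graph
                    continue
                ni, nj = nbr_cache[x], nbr_cache[y]
                s = len(ni & nj) / len(ni | nj)
                d = 1.0 - s
                if d < dist[i, j]:
                    dist[i, j] = dist[j, i] = d
    Z = linkage(squareform(dist, checks=False), method=method)
    heights = [0.0] + sorted(set(np.maximum(Z[:, 2], 0.0)))
    best: tuple[float, float, np.ndarray] | None = None
    for h in heights:
        assignment = fcluster(Z, t=h, criterion="distance")
        comms: dict[int, list[Edge]] = {}
        for lbl, e in zip(assignment, edges):
            comms.setdefault(int(lbl), []).append(e)
        D = partition_density([frozenset(c) for c in comms.values()], M)
        if best is None or D > best[0] + 1e-12:
            best = (D, h, assignment)
    D, h, assignment = best
    comms: dict[int, list[Edge]] = {}
    for lbl, e in zip(assignment, edges):
        comms.setdefault(int(lbl), []).append(e)
    communities = sorted(
        (frozenset(c) for c in comms.values()), key=lambda c: sorted(c)
    )
    trivial = sum(1 for c in communities if len(c) == 1)
    if trivial:
        logger.info("link communities: %d single-edge (trivial) communities retained", trivial)
    return LinkCommunitySolution(communities=communities, M=M, D=float(D), cut_height=float(h))


def coherent_clusters(
    solution: LinkCommunitySolution,
    phenotype_enrichment: Mapping[str, Sequence[EnrichmentRecord]],
    pair_labels: Mapping[Edge, Sequence[PairFunSysLabel]],
    theta: float = 0.70,
) -> list[CoherentCluster]:
    """Score every community for functional coherence.

    A phenotype carries evidence for FunSys F when it is individually
    significant for F, or is an endpoint of an in-cluster edge labelled
    consistent/emergent for F.  Coverage = evidence phenotypes / cluster
    size; the cluster is coherent for every F with coverage >= theta.
    """
    sig_by_pheno = {
        t: frozenset(r.funsys for r in recs if r.significant)
        for t, recs in phenotype_enrichment.items()
    }
    out: list[CoherentCluster] = []
    for ci, comm in enumerate(solution.communities):
        nodes = sorted({n for e in comm for n in e})
        evidence: dict[str, set[str]] = {}  # funsys -> phenotypes with evidence
        for n in nodes:
            for f in sig_by_pheno.get(n, ()):
                evidence.setdefault(f, set()).add(n)
        for e in comm:
            for lab in pair_labels.get(_canonical_edge(e), ()):
                evidence.setdefault(lab.funsys, set()).update(e)
        coverages = {
            f: len(ph & set(nodes)) / len(nodes) for f, ph in evidence.items()
        }
        coherent = {f: c for f, c in sorted(coverages.items()) if c >= theta}
        out.append(
            CoherentCluster(
                cluster_id=f"C{ci + 1}",
                phenotypes=frozenset(nodes),
                m_c=len(comm),
                coherent_funsys=coherent,
                theta=theta,
            )
        )
    return out


def cluster_disease_overlap(
    cluster: CoherentCluster | frozenset[str],
    disease_annotations: DiseaseAnnotations,
    allowed_missing: int = 1,
) -> dict[str, int]:
    """Diseases covering the cluster up to ``allowed_missing`` phenotypes.

    Returns disease id -> number of cluster phenotypes missing from the
    disease's annotation set.
    """
    phenos = cluster.phenotypes if isinstance(cluster, CoherentCluster) else cluster
    out: dict[str, int] = {}
    for disease, terms in disease_annotations.items():
        missing = len(phenos - terms)
        if missing <= allowed_missing:
            out[disease] = missing
    return out


def attach_disease_overlap(
    clusters: Sequence[CoherentCluster],
    disease_annotations: DiseaseAnnotations,
    allowed_missing: int = 1,
) -> list[CoherentCluster]:
    for c in clusters:
        c.diseases = cluster_disease_overlap(c, disease_annotations, allowed_missing)
    return list(clusters)


def sort_clusters_for_report(
    clusters: Sequence[CoherentCluster],
) -> list[CoherentCluster]:
    """Report order: coherent+disease, coherent only, disease only, neither."""
    def rank(c: CoherentCluster) -> tuple:
        return (
            0 if (c.is_coherent and c.overlaps_disease) else
            1 if c.is_coherent else
            2 if c.overlaps_disease else 3,
            -c.m_c,
            sorted(c.phenotypes),
        )
    return sorted(clusters, key=rank)
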