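"""Protein clusters from an alignment graph via Markov clustering (MCL).

The alignment-graph nodes are proteins; edges carry ``-log10(E)`` weights
so that strong alignments dominate the random walk.  MCL alternates
expansion (matrix power) and inflation (entrywise power followed by
column renormalisation) on a column-stochastic transition matrix with
self-loops until the matrix stops changing; attractor rows then define
the clusters.  Clusters with fewer than two proteins are discarded:
two sequences "share a protein" when each contains a member of the same
retained cluster.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

import networkx as nx
import numpy as np
import scipy.sparse as sp

from .align import AlignmentHit, EVALUE_FLOOR

__all__ = [
    "ProteinClusterSet",
    "build_protein_graph",
    "markov_cluster",
]


@dataclass
class ProteinClusterSet:
    """Disjoint protein clusters plus per-sequence membership maps.

    ``n`` is the number of retained clusters (the population size of the
    hypergeometric shared-cluster test); ``per_sequence_clusters`` maps a
    contig/genome id to the set of cluster indices its proteins occupy.
    """

    clusters: list[frozenset[str]]
    membership: dict[str, int]
    per_sequence_clusters: dict[str, frozenset[int]]
    converged: bool = True

    @property
    def n(self) -> int:
        return len(self.clusters)

    @classmethod
    def from_clusters(
        cls,
        clusters: Iterable[Iterable[str]],
        parent_of: Mapping[str, str] | None = None,
        converged: bool = True,
    ) -> "ProteinClusterSet":
        clist = [frozenset(c) for c in clusters]
        membership: dict[str, int] = {}
        for idx, members in enumerate(clist):
            for pid in members:
                if pid in membership:
                    raise ValueError(f"protein {pid!r} assigned to two clusters")
                membership[pid] = idx
        per_seq: dict[str, set[int]] = {}
        if parent_of:
            for pid, idx in membership.items():
                parent = parent_of.get(pid)
                if parent is not None:
                    per_seq.setdefault(parent, set()).add(idx)
        return cls(
            clusters=clist,
            membership=membership,
            per_sequence_clusters={k: frozenset(v) for k, v in per_seq.items()},
            converged=converged,
        )

    def clusters_of(self, seq_id: str) -> frozenset[int]:
        return self.per_sequence_clusters.get(seq_id, frozenset())

    def to_table(self, parent_of: Mapping[str, str] | None = None) -> list[tuple[int, str, str]]:
        """(cluster_id, protein_id, parent_sequence_id) rows for TSV export."""
        rows = []
        for idx, members in enumerate(self.clusters):
            for pid in sorted(members):
                parent = (parent_of or {}).get(pid, "")
                rows.append((idx, pid, parent))
        return rows


def build_protein_graph(
    hits: Iterable[AlignmentHit],
    evalue_floor: float = EVALUE_FLOOR,
) -> nx.Graph:
    """Weighted undirected protein-similarity graph.

    One node per protein appearing in a hit; reciprocal/duplicate hits
    are merged keeping the smaller E-value; self-hits are dropped.  Edge
    weight is ``-log10(E)`` (larger = stronger), with E-values floored.
    """
    graph = nx.Graph()
    for h in hits:
        if h.query_id == h.subject_id:
            continue
        ev = max(h.evalue, evalue_floor)
        w = -math.log10(ev)
        if graph.has_edge(h.query_id, h.subject_id):
            if w > graph[h.query_id][h.subject_id]["weight"]:
                graph[h.query_id][h.subject_id]["weight"] = w
        else:
            graph.add_edge(h.query_id, h.subject_id, weight=w)
    return graph


def _column_normalize(m: sp.csc_matrix) -> sp.csc_matrix:
    sums = np.asarray(m.sum(axis=0)).ravel()
    sums[sums == 0] = 1.0
    return m @ sp.diags(1.0 / sums)


def _mcl_iterations(
    matrix: sp.csc_matrix,
    inflation: float,
    expansion: int,
    max_iter: int,
    prune: float = 1e-8,
) -> Iterator[sp.csc_matrix]:
    """Yield the column-stochastic matrix after each expand+inflate step."""
    m = _column_normalize(matrix.tocsc())
    for _ in range(max_iter):
        m = m ** expansion if expansion != 2 else m @ m
        m = m.power(inflation)
        m = _column_normalize(m)
        m.data[m.data < prune] = 0.0
        m.eliminate_zeros()
        m = _column_normalize(m)
        yield m.tocsc()


def _interpret_clusters(m: sp.csc_matrix, attractor_tol: float = 1e-5) -> list[set[int]]:
    """Clusters from a converged MCL matrix: an attractor is a node with
    positive mass on its own row; its cluster is the support of that row.
    Attractors whose clusters overlap are merged."""
    m = m.tocsr()
    diag = m.diagonal()
    attractors = np.nonzero(diag > attractor_tol)[0]
    raw: list[set[int]] = []
    for a in attractors:
        row = m.getrow(a)
        members = set(row.indices[row.data > attractor_tol])
        members.add(int(a))
        raw.append(members)
    # merge overlapping attractor systems
    merged: list[set[int]] = []
    for cluster in raw:
        overlapping = [c for c in merged if c & cluster]
        for c in overlapping:
            cluster |= c
            merged.remove(c)
        merged.append(cluster)
    assigned = set().union(*merged) if merged else set()
    for node in range(m.shape[0]):
        if node not in assigned:
            merged.append({node})
    return merged


def markov_cluster(
    graph: nx.Graph,
    inflation: float = 2.0,
    expansion: int = 2,
    max_iter: int = 100,
    tol: float = 1e-6,
    parent_of: Mapping[str, str] | None = None,
    min_cluster_size: int = 2,
) -> ProteinClusterSet:
    """Run MCL on a weighted protein graph and return retained clusters.

    Self-loops equal to each node's maximum incident weight are added to
    stabilise attractors.  Clusters smaller than ``min_cluster_size``
    (singletons by default) are discarded after convergence.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    nodes = sorted(graph.nodes())
    index = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    rows, cols, data = [], [], []
    for u, v, d in graph.edges(data=True):
        w = float(d.get("weight", 1.0))
        rows += [index[u], index[v]]
        cols += [index[v], index[u]]
        data += [w, w]
    adj = sp.csc_matrix((data, (rows, cols)), shape=(n, n))
    loop = np.asarray(adj.max(axis=0).todense()).ravel() if data else np.zeros(n)
    loop[loop <= 0] = 1.0
    adj = adj + sp.diags(loop)

    prev = None
    converged = False
    final = None
    for m in _mcl_iterations(adj, inflation, expansion, max_iter):
        final = m
        if prev is not None:
            delta = abs(m - prev).max() if (m - prev).nnz else 0.0
            if delta < tol:
                converged = True
                break
        prev = m
    if not converged:
        warnings.warn("MCL did not converge within max_iter; using current matrix")

    clusters_idx = _interpret_clusters(final)
    clusters = [
        frozenset(nodes[i] for i in c) for c in clusters_idx if len(c) >= min_cluster_size
    ]
    clusters.sort(key=lambda c: sorted(c))
    return ProteinClusterSet.from_clusters(clusters, parent_of=parent_of, converged=converged)
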